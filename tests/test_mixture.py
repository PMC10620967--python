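"""Tests for EM fitting, classification, redundancy and model selection."""

import numpy as np
import pytest

from cytotype.mixture import (
    MixtureError,
    MixtureModel,
    classify,
    fit_gmm,
    percentile_interval,
    redundancy_test,
    select_model,
)


def _grid_search_loglik_k2(values, n_grid=12):
    """Brute-force dense grid likelihood for a 2-component mixture.

    Independent oracle for small n: scans (mean1, mean2, sd, sd, weight)
    over data-driven grids and returns the best total log-likelihood.
    """
    values = np.asarray(values, dtype=float)
    mean_grid = np.linspace(values.min(), values.max(), n_grid)
    sd_grid = np.geomspace(0.05 * values.std() + 1e-6, 2 * values.std(), 8)
    w_grid = np.linspace(0.1, 0.9, 9)
    best = -np.inf
    x = values[:, None]
    for i, m1 in enumerate(mean_grid):
        for m2 in mean_grid[i:]:
            for s1 in sd_grid:
                for s2 in sd_grid:
                    d1 = np.exp(-0.5 * ((x[:, 0] - m1) / s1) ** 2) / s1
                    d2 = np.exp(-0.5 * ((x[:, 0] - m2) / s2) ** 2) / s2
                    for w in w_grid:
                        mix = w * d1 + (1 - w) * d2
                        ll = np.sum(np.log(mix / np.sqrt(2 * np.pi) + 1e-300))
                        best = max(best, ll)
    return best


class TestFitGmm:
    def test_k1_equals_sample_moments(self):
        """The k=1 EM fixed point is the closed-form Normal MLE."""
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 0.7, 300)
        model = fit_gmm(x, 1, seed=0)
        assert model.means[0] == pytest.approx(x.mean(), abs=1e-9)
        assert model.sds[0] == pytest.approx(x.std(), abs=1e-9)
        assert model.weights[0] == 1.0

    def test_loglik_is_monotone_nondecreasing(self, eight_group_sample):
        """EM never decreases the log-likelihood (within 1e-8)."""
        x, _ = eight_group_sample
        model = fit_gmm(x, 8, seed=1)
        trace = model.loglik_trace
        assert np.all(np.diff(trace) > -1e-8)

    def test_table_means_recovered_within_three_se(
            self, eight_group_sample, group_means):
        """Each fitted component mean lands within 3 MC SEs of its generator.

        The SEs are the replicate SDs of the fitted means over 30
        independent draws of the same size (brute-force Monte Carlo,
        computed up front); overlap between neighbouring components makes
        them up to 2.3x larger than the naive sd/sqrt(n w).
        """
        mc_se = np.array([0.0025, 0.0129, 0.0221, 0.0318,
                          0.0114, 0.0088, 0.0214, 0.0113])
        x, _ = eight_group_sample
        model = fit_gmm(x, 8, seed=2)
        assert np.all(np.abs(model.means - group_means) < 3 * mc_se)

    def test_symmetric_two_component_weights(self):
        """Equal-weight components at 0 and 10 recover weights 0.5 +- 0.03."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        model = fit_gmm(x, 2, seed=3)
        assert model.weights == pytest.approx([0.5, 0.5], abs=0.03)
        assert model.means == pytest.approx([0, 10], abs=0.15)

    def test_em_beats_dense_grid_oracle(self):
        """For n <= 50, k = 2, EM reaches at least the grid-search optimum."""
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(2.5, 0.3, 25), rng.normal(6.0, 0.5, 25)])
        model = fit_gmm(x, 2, seed=4)
        assert model.loglik >= _grid_search_loglik_k2(x) - 1e-3

    def test_permutation_invariance(self, eight_group_sample):
        """Shuffling the input leaves the fitted model identical."""
        x, _ = eight_group_sample
        rng = np.random.default_rng(5)
        a = fit_gmm(x, 8, seed=6)
        b = fit_gmm(rng.permutation(x), 8, seed=6)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.sds, b.sds)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.loglik == b.loglik

    def test_components_sorted_and_weights_normalized(self, eight_group_sample):
        x, _ = eight_group_sample
        model = fit_gmm(x, 8, seed=7)
        assert np.all(np.diff(model.means) > 0)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn_reference(self, eight_group_sample, group_means):
        """Independent cross-check against scikit-learn's GMM on the same data."""
        sklearn = pytest.importorskip("sklearn.mixture")
        x, _ = eight_group_sample
        ours = fit_gmm(x, 8, seed=8)
        ref = sklearn.GaussianMixture(8, n_init=5, random_state=0,
                                      tol=1e-6, max_iter=2000).fit(x[:, None])
        ref_means = np.sort(ref.means_.ravel())
        assert ours.means == pytest.approx(ref_means, abs=0.05)
        assert ours.loglik >= ref.score(x[:, None]) * len(x) - 1.0

    @pytest.mark.parametrize("k,n", [(0, 10), (5, 5), (3, 2)])
    def test_bad_k_rejected(self, k, n):
        with pytest.raises(MixtureError):
            fit_gmm(np.arange(n, dtype=float), k)

    def test_duplicate_heavy_data_rejected_for_large_k(self):
        with pytest.raises(MixtureError):
            fit_gmm(np.array([1.0, 1.0, 1.0, 2.0]), 3)


class TestClassify:
    @pytest.fixture()
    def separated(self):
        return MixtureModel(k=2, means=[0.0, 10.0], sds=[1.0, 1.0],
                            weights=[0.5, 0.5], loglik=0.0, n_iter=1,
                            converged=True, n_obs=10)

    def test_value_at_component_mean_goes_there(self, separated):
        _, labels = classify(separated, [0.0, 10.0])
        assert labels.tolist() == [0, 1]

    def test_equidistant_tie_goes_to_lower_mean(self, separated):
        _, labels = classify(separated, [5.0])
        assert labels.tolist() == [0]

    def test_responsibility_rows_sum_to_one(self, eight_group_sample):
        x, _ = eight_group_sample
        model = fit_gmm(x, 8, seed=9)
        resp, labels = classify(model, x)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((resp >= 0) & (resp <= 1))
        assert np.array_equal(labels, resp.argmax(axis=1))

    def test_simulated_labels_mostly_correct(self, eight_group_sample):
        """Max-posterior labels agree with the generating component >= 90%."""
        x, truth = eight_group_sample
        model = fit_gmm(x, 8, seed=10)
        _, labels = classify(model, x)
        assert (labels == truth).mean() >= 0.90


class TestRedundancyAndSelection:
    def _model(self, means, sds, weights):
        weights = np.asarray(weights, float)
        return MixtureModel(k=len(means), means=means, sds=sds,
                            weights=weights / weights.sum(), loglik=0.0,
                            n_iter=1, converged=True, n_obs=100)

    def test_separated_components_not_redundant(self):
        model = self._model([0.0, 10.0, 20.0], [1, 1, 1], [0.3, 0.3, 0.4])
        assert redundancy_test(model) == []

    def test_tiny_nested_component_flagged(self):
        model = self._model([5.0, 5.1], [2.0, 0.1], [0.995, 0.005])
        assert redundancy_test(model) == [1]

    def test_small_but_protruding_component_not_flagged(self):
        model = self._model([5.0, 30.0], [2.0, 0.1], [0.995, 0.005])
        assert redundancy_test(model) == []

    def test_single_candidate_returned_unchanged(self):
        model = self._model([0.0, 10.0], [1, 1], [0.5, 0.5])
        chosen, report = select_model([model])
        assert chosen is model
        assert report["chosen"].tolist() == [True]

    def test_bimodal_data_selects_two_components(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 400), rng.normal(12, 1, 400)])
        candidates = [fit_gmm(x, k, seed=k) for k in (1, 2)]
        chosen, _ = select_model(candidates)
        assert chosen.k == 2

    def test_all_redundant_falls_back_to_smallest_k(self):
        good = self._model([0.0, 10.0], [1, 1], [0.5, 0.5])
        bad = self._model([0.0, 5.0, 5.05], [1.0, 2.0, 0.05],
                          [0.495, 0.495, 0.01])
        with pytest.warns(UserWarning, match="redundant"):
            chosen, _ = select_model([bad])
        assert chosen is bad


class TestPercentileInterval:
    def test_closed_form_matches_numeric_inversion(self):
        """mean + z_p sd agrees with numeric quantile inversion to 1e-6."""
        from scipy.optimize import brentq
        from scipy.stats import norm
        for mean, sd in [(2.587, 0.036), (8.196, 0.132), (0.0, 1.0)]:
            lo, hi = percentile_interval(mean, sd)
            lo_num = brentq(lambda q: norm.cdf(q, mean, sd) - 0.01,
                            mean - 10 * sd, mean + 10 * sd, xtol=1e-12)
            hi_num = brentq(lambda q: norm.cdf(q, mean, sd) - 0.99,
                            mean - 10 * sd, mean + 10 * sd, xtol=1e-12)
            assert lo == pytest.approx(lo_num, abs=1e-6)
            assert hi == pytest.approx(hi_num, abs=1e-6)
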