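"""Tests for histogram building, peak evaluation, genome size and QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytotype.cytometry import (
    CytometryError,
    EventSet,
    build_histogram,
    compute_gs,
    detect_peaks,
    estimate_peak_stats,
    evaluate_events,
    qc_filter,
)
from cytotype.simulate import simulate_events


def _events(values, sample_id="s"):
    return EventSet(sample_id=sample_id, values=np.asarray(values, dtype=float))


class TestBuildHistogram:
    def test_counts_are_conserved(self):
        ev = simulate_events(8.196, n_particles=3500, debris_fraction=0.1, seed=0)
        hist = build_histogram(ev, n_bins=256)
        assert hist.counts.sum() == 3500
        assert hist.n_bins == 256

    def test_single_repeated_value_fills_one_bin(self):
        hist = build_histogram(_events([200.0] * 50))
        assert (hist.counts > 0).sum() == 1
        assert hist.counts.max() == 50

    def test_two_separated_peaks_give_two_maxima(self):
        """Simulated two-peak analysis shows two local maxima above background,
        verified by a direct scan of the bin counts."""
        ev = simulate_events(8.196, cv_sample=1.5, n_particles=3500,
                             debris_fraction=0, seed=1)
        hist = build_histogram(ev, n_bins=128)
        c = hist.counts
        thresh = 0.2 * c.max()
        local_maxima = [
            i for i in range(1, len(c) - 1)
            if c[i] >= thresh and c[i] >= c[i - 1] and c[i] > c[i + 1]
        ]
        assert len(local_maxima) == 2

    def test_empty_and_bad_bins_rejected(self):
        with pytest.raises(CytometryError):
            build_histogram(_events([]))
        with pytest.raises(CytometryError):
            build_histogram(_events([1.0]), n_bins=8)


class TestDetectPeaks:
    def test_two_peak_analysis_yields_two_windows(self):
        ev = simulate_events(8.196, cv_sample=1.5, cv_standard=2.0,
                             n_particles=3500, debris_fraction=0.15, seed=2)
        windows = detect_peaks(build_histogram(ev))
        assert len(windows) == 2
        (lo1, hi1), (lo2, hi2) = windows
        assert hi1 <= lo2  # disjoint, ordered by channel
        assert lo1 <= 200 < hi1  # standard peak
        assert lo2 <= 200 * 8.196 / 3.38 < hi2  # sample peak

    def test_flat_histogram_has_no_peaks(self):
        """Exactly uniform counts contain no local maximum."""
        windows = detect_peaks(build_histogram(_events(np.arange(1, 5121) / 10.0)))
        assert windows == []

    def test_mixture_of_peaks_all_found(self):
        """Three sample peaks plus the standard -> four windows."""
        rng = np.random.default_rng(3)
        chunks = [rng.normal(c, c * 0.015, 900) for c in (200, 320, 410, 500)]
        ev = _events(np.concatenate(chunks))
        windows = detect_peaks(build_histogram(ev, n_bins=256))
        assert len(windows) == 4


class TestEstimatePeakStats:
    def test_constant_events_have_zero_cv(self):
        est = estimate_peak_stats(_events([200.0] * 60), (150, 250))
        assert est.mean_fluorescence == 200.0
        assert est.cv == 0.0

    def test_population_sd_convention(self):
        """{198, 200, 202}: population SD 1.633, CV 0.8165%."""
        est = estimate_peak_stats(_events([198.0, 200.0, 202.0]), (150, 250),
                                  min_events=3)
        assert est.mean_fluorescence == pytest.approx(200.0)
        assert est.cv == pytest.approx(100 * np.sqrt(8 / 3) / 200, rel=1e-9)

    def test_configured_cv_recovered(self):
        """Estimated CV of a pure simulated peak is within 3 SE of 2.0%."""
        ev = simulate_events(3.38, cv_sample=2.0, cv_standard=2.0,
                             n_particles=20000, debris_fraction=0, seed=4)
        est = estimate_peak_stats(ev, (0, np.inf))
        se = 2.0 / np.sqrt(2 * 20000)
        assert est.cv == pytest.approx(2.0, abs=3 * se)

    def test_too_few_events_rejected(self):
        with pytest.raises(CytometryError, match="discarded"):
            estimate_peak_stats(_events([200.0] * 10), (150, 250), min_events=50)


class TestComputeGs:
    def test_equal_peaks_return_the_standard_constant(self):
        assert compute_gs(200.0, 200.0, 3.38) == 3.38

    def test_linearity_in_the_ratio(self):
        assert compute_gs(400.0, 200.0, 3.38) == pytest.approx(6.76)
        assert compute_gs(485.0, 200.0, 3.38) == pytest.approx(8.1965)

    @given(st.floats(1.0, 1000.0), st.floats(1.0, 1000.0), st.floats(0.1, 50.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reciprocity(self, a, b, g):
        """compute_gs(a, b, g) * compute_gs(b, a, g) == g^2."""
        assert compute_gs(a, b, g) * compute_gs(b, a, g) == pytest.approx(
            g * g, rel=1e-9)

    @pytest.mark.parametrize("args", [(0, 200, 3.38), (200, -1, 3.38), (200, 200, 0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(CytometryError):
            compute_gs(*args)


class TestEvaluateAndQc:
    def test_genome_size_recovered_within_three_se(self):
        """End-to-end single-analysis GS error stays within 3 MC SEs."""
        true_gs = 8.196
        errors = []
        for seed in range(8):
            ev = simulate_events(true_gs, cv_sample=1.5, cv_standard=1.5,
                                 n_particles=3500, debris_fraction=0.1,
                                 seed=seed, sample_id=f"s{seed}")
            m = evaluate_events(ev)
            errors.append(m.genome_size - true_gs)
        # SE of one GS estimate ~ gs * cv/100 * sqrt(2/n_peak)
        se = true_gs * 0.015 * np.sqrt(2 / 1500)
        assert np.abs(np.mean(errors)) < 3 * se / np.sqrt(len(errors))

    def test_standard_peak_is_the_one_near_reference(self):
        """GS < standard puts the sample peak below the reference channel."""
        ev = simulate_events(2.587, cv_sample=1.5, n_particles=3500,
                             debris_fraction=0, seed=6)
        m = evaluate_events(ev)
        assert m.standard_peak.mean_fluorescence == pytest.approx(200, rel=0.05)
        assert m.sample_peak.mean_fluorescence < m.standard_peak.mean_fluorescence
        assert m.genome_size == pytest.approx(2.587, abs=0.05)

    def test_coincident_peaks_warn_and_return_standard_gs(self):
        ev = simulate_events(3.38, cv_sample=1.5, n_particles=3500,
                             debris_fraction=0, seed=7)
        m = evaluate_events(ev)
        assert "single peak" in m.qc_reason
        assert m.genome_size == pytest.approx(3.38, abs=0.02)

    def test_strict_cv_boundary(self):
        """CVs (2.49, 2.49) pass; (1.0, 2.5) fail: strictly below 2.5."""
        def fake(cv_sample, cv_standard, sid):
            ev = simulate_events(8.196, cv_sample=cv_sample,
                                 cv_standard=cv_standard, n_particles=3500,
                                 debris_fraction=0, seed=8, sample_id=sid)
            return evaluate_events(ev)

        import dataclasses
        m = fake(1.5, 1.5, "a")
        ok = dataclasses.replace(
            m, sample_peak=dataclasses.replace(m.sample_peak, cv=2.49),
            standard_peak=dataclasses.replace(m.standard_peak, cv=2.49))
        bad = dataclasses.replace(
            m, sample_id="b",
            sample_peak=dataclasses.replace(m.sample_peak, cv=1.0),
            standard_peak=dataclasses.replace(m.standard_peak, cv=2.5))
        passed, failed = qc_filter([ok, bad])
        assert [x.sample_id for x in passed] == ["a"]
        assert [x.sample_id for x in failed] == ["b"]

    def test_qc_partition_is_conserved(self):
        """|passed| + |failed| == |input| for any mix of analyses."""
        measurements = []
        rng = np.random.default_rng(9)
        for i in range(30):
            cv = 4.0 if i < 8 else 1.5
            ev = simulate_events(8.196, cv_sample=cv, cv_standard=cv,
                                 n_particles=1000, debris_fraction=0.1,
                                 seed=int(rng.integers(2**31)), sample_id=f"s{i}")
            measurements.append(evaluate_events(ev))
        passed, failed = qc_filter(measurements)
        assert len(passed) + len(failed) == 30
        assert {m.sample_id for m in passed} | {m.sample_id for m in failed} == {
            m.sample_id for m in measurements}

    def test_injected_failures_are_filtered(self):
        """15 of 100 analyses with ~4-6% CV -> 85 pass the 2.5% filter."""
        measurements = []
        rng = np.random.default_rng(10)
        for i in range(100):
            inflated = i < 15
            cv = float(rng.uniform(4, 6)) if inflated else 1.5
            ev = simulate_events(8.196, cv_sample=cv, cv_standard=cv,
                                 n_particles=2000, debris_fraction=0.05,
                                 seed=int(rng.integers(2**31)), sample_id=f"s{i}")
            measurements.append(evaluate_events(ev))
        passed, _ = qc_filter(measurements)
        assert len(passed) == 85
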