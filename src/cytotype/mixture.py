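"""Finite Gaussian mixture modelling of genome sizes.

Quality-filtered 2C genome sizes of a polyploid complex form a multimodal
1D distribution; each mode is a candidate cytotype.  This module fits
k-component univariate Gaussian mixtures by expectation-maximisation,
classifies observations by posterior responsibility, and compares candidate
component counts with a redundancy criterion: an extra component that is
very small and lies entirely inside another fitted component adds no
interpretable group, so the largest k without such components is retained.

Numerical conventions: components are stored sorted by mean; fitting is
performed on a sorted copy of the data, which makes the result exactly
invariant to permutations of the input; component SDs are floored at
``SD_FLOOR`` and runs that collapse below it are discarded and restarted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Smallest admissible component SD in pg.  Instrument CVs bound real
#: genome-size dispersion well away from zero; anything tighter is a
#: degenerate spike on near-duplicate values.
SD_FLOOR = 1e-4

#: Iteration cap for EM.
DEFAULT_MAX_ITER = 1_000_000

#: Absolute log-likelihood change declaring convergence.
DEFAULT_TOL = 1e-8


class MixtureError(ValueError):
    """Invalid input to mixture fitting."""


class _Collapse(Exception):
    """A component degenerated during EM; the run is abandoned."""


@dataclass(frozen=True)
class MixtureModel:
    """A fitted k-component 1D Gaussian mixture (components sorted by mean)."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int
    loglik_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("means", "sds", "weights"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.means) == len(self.sds) == len(self.weights) == self.k):
            raise MixtureError("parameter arrays must have length k")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise MixtureError("weights must sum to 1")
        if np.any(self.sds < SD_FLOOR):
            raise MixtureError(f"component SDs must be >= {SD_FLOOR}")

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2 * self.loglik

    def log_density(self, values: np.ndarray) -> np.ndarray:
        """Per-observation, per-component weighted log density, shape (n, k)."""
        x = np.asarray(values, dtype=float)[:, None]
        return (np.log(self.weights)
                - 0.5 * np.log(2.0 * np.pi) - np.log(self.sds)
                - 0.5 * ((x - self.means) / self.sds) ** 2)

    def score(self, values: np.ndarray) -> float:
        """Total log-likelihood of ``values`` under the model."""
        return float(logsumexp(self.log_density(values), axis=1).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(self.k),
            "mean": self.means, "sd": self.sds, "weight": self.weights,
        })


def percentile_interval(mean: float, sd: float,
                        percentiles: tuple[float, float] = (1.0, 99.0)) -> tuple[float, float]:
    """Closed-form Normal percentile interval ``mean + z_p * sd``."""
    lo_z, hi_z = (norm.ppf(p / 100.0) for p in percentiles)
    return (mean + lo_z * sd, mean + hi_z * sd)


def _em_run(values: np.ndarray, means: np.ndarray, sds: np.ndarray,
            weights: np.ndarray, max_iter: int, tol: float
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    """One EM run from a given initialisation; raises _Collapse on degeneracy."""
    x = values[:, None]
    n = values.size
    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    half_log_2pi = 0.5 * np.log(2.0 * np.pi)
    for it in range(1, max_iter + 1):
        # manual log-sum-exp: ~3x faster than scipy.special.logsumexp here
        z = (x - means) / sds
        log_dens = (np.log(weights) - half_log_2pi - np.log(sds)) - 0.5 * z * z
        mx = log_dens.max(axis=1, keepdims=True)
        p = np.exp(log_dens - mx)
        norm = p.sum(axis=1, keepdims=True)
        ll = float((np.log(norm) + mx).sum())
        trace.append(ll)
        resp = p / norm
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise _Collapse("empty component")
        weights = nk / n
        means = resp.T @ values / nk
        var = (resp * (x - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(~np.isfinite(sds)) or np.any(sds < SD_FLOOR):
            raise _Collapse("component SD fell below the floor")
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    order = np.argsort(means)
    return means[order], sds[order], weights[order], trace[-1], it, converged, trace


def _kmeans_init(values: np.ndarray, k: int, fallback_sd: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded 1D k-means++ initialisation: centres, within-cluster SDs, weights."""
    centres = np.empty(k)
    centres[0] = values[rng.integers(values.size)]
    for j in range(1, k):
        d2 = np.min((values[:, None] - centres[None, :j]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centres[j] = values[rng.integers(values.size)]
        else:
            centres[j] = values[rng.choice(values.size, p=d2 / total)]
    centres = np.sort(centres)
    labels = np.zeros(values.size, dtype=int)
    for _ in range(50):
        labels = np.argmin(np.abs(values[:, None] - centres), axis=1)
        new = np.array([
            values[labels == j].mean() if np.any(labels == j) else centres[j]
            for j in range(k)
        ])
        new = np.sort(new)
        if np.allclose(new, centres):
            break
        centres = new
    sds = np.array([
        values[labels == j].std() if (labels == j).sum() > 1 else fallback_sd
        for j in range(k)
    ])
    counts = np.maximum(np.bincount(labels, minlength=k), 1).astype(float)
    return centres, np.maximum(sds, fallback_sd / 10), counts / counts.sum()


def fit_gmm(
    values,
    k: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_restarts: int = 10,
    seed: int | None = None,
) -> MixtureModel:
    """Fit a k-component 1D Gaussian mixture by best-of-restarts EM.

    The first start uses k evenly spaced sample quantiles as means, uniform
    weights, and the pooled SD divided by k as every component's SD; the
    remaining ``n_restarts - 1`` starts come from seeded 1D k-means++
    (centres, within-cluster SDs and cluster weights).  Quantile means
    track the probability mass, k-means the support — together they cover
    both balanced and strongly skewed group frequencies.
    Restarts use the two-phase short-run strategy: every start runs EM for
    at most ``short_iter`` iterations, and only the start with the best
    log-likelihood continues to full convergence (absolute log-likelihood
    change below ``tol``, capped at ``max_iter`` total iterations).  Runs
    whose components collapse (SD below :data:`SD_FLOOR` or empty) are
    logged and discarded.  Deterministic given ``seed``.
    """
    values = np.sort(np.asarray(values, dtype=float).ravel())
    if k < 1:
        raise MixtureError("k must be >= 1")
    if values.size <= k:
        raise MixtureError(f"need more than k={k} observations, got {values.size}")
    if np.unique(values).size < k:
        raise MixtureError(f"k={k} exceeds the number of distinct values")
    if max_iter < 1:
        raise MixtureError("max_iter must be >= 1")
    rng = np.random.default_rng(seed)

    quantiles = np.quantile(values, (np.arange(k) + 0.5) / k)
    pooled_sd = max(float(values.std()), 10 * SD_FLOOR)
    # per-component scale: a global-SD init would flatten the first E-step's
    # responsibilities and lose the quantile structure before EM can use it
    init_sd = max(pooled_sd / k, 10 * SD_FLOOR)
    short_iter = min(500, max_iter)
    best: tuple | None = None
    for restart in range(n_restarts):
        if restart == 0:
            means0 = quantiles.copy()
            sds0 = np.full(k, init_sd)
            weights0 = np.full(k, 1.0 / k)
        else:
            means0, sds0, weights0 = _kmeans_init(values, k, init_sd, rng)
        try:
            result = _em_run(values, means0, sds0, weights0, short_iter, tol)
        except _Collapse as exc:
            logger.info("EM restart %d discarded: %s", restart, exc)
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise MixtureError("every EM restart collapsed; data may contain "
                           "near-duplicate values — reduce k")
    means, sds, weights, ll, n_iter, converged, trace = best
    if not converged and max_iter > n_iter:
        try:
            means, sds, weights, ll, extra, converged, trace2 = _em_run(
                values, means, sds, weights, max_iter - n_iter, tol)
            n_iter += extra
            trace = trace + trace2
        except _Collapse as exc:  # pragma: no cover - needs adversarial data
            logger.warning("continuation of the best EM run collapsed (%s); "
                           "returning the short-phase fit", exc)
    return MixtureModel(k=k, means=means, sds=sds, weights=weights / weights.sum(),
                        loglik=ll, n_iter=n_iter, converged=converged,
                        n_obs=values.size, loglik_trace=np.asarray(trace))


def classify(model: MixtureModel, values) -> tuple[np.ndarray, np.ndarray]:
    """Posterior responsibilities and max-posterior component labels.

    Returns ``(responsibilities, labels)`` where responsibilities has shape
    (n, k) with rows summing to 1 and labels are component indices.  Ties go
    to the lower-mean component (components are mean-sorted, and ``argmax``
    takes the first maximum).
    """
    values = np.asarray(values, dtype=float).ravel()
    log_dens = model.log_density(values)
    resp = np.exp(log_dens - logsumexp(log_dens, axis=1, keepdims=True))
    return resp, resp.argmax(axis=1)


def redundancy_test(
    model: MixtureModel,
    w_min: float = 0.02,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> list[int]:
    """Indices of redundant components.

    A component is redundant iff its weight is below ``w_min`` AND its
    percentile interval lies entirely inside another component's interval —
    i.e. it is very small and adds no separable genome-size group.
    """
    intervals = [percentile_interval(m, s, percentiles)
                 for m, s in zip(model.means, model.sds)]
    redundant = []
    for j in range(model.k):
        if model.weights[j] >= w_min:
            continue
        lo_j, hi_j = intervals[j]
        for i in range(model.k):
            if i == j:
                continue
            lo_i, hi_i = intervals[i]
            if lo_i <= lo_j and hi_j <= hi_i:
                redundant.append(j)
                break
    return redundant


def select_model(
    candidates: list[MixtureModel],
    w_min: float = 0.02,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> tuple[MixtureModel, pd.DataFrame]:
    """Choose the largest k whose fit has no redundant components.

    Returns the chosen model and a per-candidate report (k, loglik, AIC,
    BIC, redundant-component count, chosen flag); AIC/BIC are diagnostics
    only.  If every candidate carries redundant components the smallest k
    is returned with a warning.
    """
    if not candidates:
        raise MixtureError("select_model needs at least one candidate")
    ordered = sorted(candidates, key=lambda m: m.k)
    n_redundant = {id(m): len(redundancy_test(m, w_min, percentiles)) for m in ordered}
    admissible = [m for m in ordered if n_redundant[id(m)] == 0]
    if admissible:
        chosen = admissible[-1]
    else:
        chosen = ordered[0]
        warnings.warn("every candidate mixture has redundant components; "
                      f"falling back to the smallest k = {chosen.k}", stacklevel=2)
    report = pd.DataFrame({
        "k": [m.k for m in ordered],
        "loglik": [m.loglik for m in ordered],
        "aic": [m.aic for m in ordered],
        "bic": [m.bic for m in ordered],
        "n_redundant": [n_redundant[id(m)] for m in ordered],
        "chosen": [m is chosen for m in ordered],
    })
    return chosen, report


def responsibilities_to_frame(sample_ids, resp: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    frame = pd.DataFrame(resp, columns=[f"resp_{j}" for j in range(resp.shape[1])])
    frame.insert(0, "sample_id", list(sample_ids))
    frame["component"] = labels
    return frame
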