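"""Evaluation of flow-cytometric (FCM) analyses.

Each analysis is the fluorescence histogram of one plant co-stained with an
internal standard of known DNA content.  The module builds histograms,
detects fluorescent peaks, estimates per-peak mean fluorescence and
coefficient of variation (CV), converts the sample/standard fluorescence
ratio into a 2C genome size in picograms, and applies the CV-based quality
filter.

Conventions
-----------
* Channel values are on an arbitrary linear scale; only the ratio of peak
  means carries information (the genome-size formula is scale-free).
* Histogram bins and peak windows are half-open ``[low, high)``.
* The SD inside a peak window is the population SD (divide by n), so
  ``cv = 100 * sd / mean``.
* The internal standard peak is identified as the detected peak closest to
  the configured reference channel.  When only a single peak is found the
  sample is taken to co-locate with the standard (genome size equal to the
  standard) and a warning is attached, since a genuine sample near the
  standard's genome size cannot be distinguished from a failed analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

#: 2C genome size of the internal standard (Bellis perennis), in pg.
DEFAULT_STANDARD_GS = 3.38

#: Channel at which the internal standard peak is placed / looked for.
DEFAULT_REFERENCE_CHANNEL = 200.0

#: Analyses with any retained peak CV at or above this percentage are rejected.
DEFAULT_CV_MAX = 2.5


class CytometryError(ValueError):
    """Invalid input to an FCM evaluation step."""


@dataclass(frozen=True)
class EventSet:
    """Per-particle fluorescence values of one FCM analysis.

    Parameters
    ----------
    sample_id:
        Identifier of the measured plant.
    values:
        Fluorescence channel value of every recorded particle (linear scale,
        non-negative).
    labels:
        Optional ground-truth per-event labels (``"sample"``, ``"standard"``,
        ``"debris"``) carried by simulated data; ``None`` for real data.
    """

    sample_id: str
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise CytometryError("event values must be one-dimensional")
        if values.size and values.min() < 0:
            raise CytometryError("fluorescence values must be non-negative")
        object.__setattr__(self, "values", values)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != values.shape:
                raise CytometryError("labels must match values in length")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Histogram:
    """Binned event counts with half-open bin intervals."""

    counts: np.ndarray
    edges: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class PeakEstimate:
    """Summary statistics of one fluorescent peak.

    ``cv`` is 100 * population SD / mean of the events inside ``window``.
    """

    mean_fluorescence: float
    cv: float
    event_count: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        low, high = self.window
        if not low < high:
            raise CytometryError("peak window must satisfy low < high")
        if self.cv < 0:
            raise CytometryError("cv cannot be negative")


@dataclass
class SampleMeasurement:
    """One plant's evaluated FCM analysis."""

    sample_id: str
    sample_peak: PeakEstimate | None
    standard_peak: PeakEstimate | None
    genome_size: float
    qc_pass: bool
    qc_reason: str = ""
    population_id: str | None = None


def build_histogram(events: EventSet, n_bins: int = 256) -> Histogram:
    """Bin an event set over ``[0, max)`` with ``n_bins`` equal-width bins.

    The upper edge sits just above the largest value so every event falls in
    a half-open bin and counts always sum to the number of events.
    """
    if n_bins < 32:
        raise CytometryError(f"n_bins must be >= 32, got {n_bins}")
    if len(events) == 0:
        raise CytometryError("cannot histogram an empty EventSet")
    top = float(events.values.max())
    if top <= 0:
        top = 1.0
    edges = np.linspace(0.0, top * (1.0 + 1e-9), n_bins + 1)
    counts, _ = np.histogram(events.values, bins=edges)
    return Histogram(counts=counts.astype(np.int64), edges=edges)


def detect_peaks(
    histogram: Histogram,
    min_prominence: float = 0.05,
    min_events: int = 50,
    drop_fraction: float = 0.1,
    max_halfwidth: int = 25,
) -> list[tuple[float, float]]:
    """Locate fluorescent peaks and return their channel windows.

    Detection runs on a lightly smoothed copy of the counts (5-bin moving
    average) so Poisson noise on a broad peak cannot split it into two
    apexes; peak statistics downstream still use the raw events.  A bin is
    an apex if its smoothed prominence exceeds ``min_prominence`` times the
    maximum smoothed count and it is at least 4 bins from a higher apex.
    Each window extends from the apex in both directions until the smoothed
    histogram falls below ``drop_fraction`` of the apex count or
    ``max_halfwidth`` bins are reached; overlapping windows of neighbouring
    apexes are cut at the count minimum between them.  Windows holding
    fewer than ``min_events`` raw events are discarded.  The decaying
    debris shoulder at the low channels has no interior local maximum, so
    the prominence rule excludes it.  Returns half-open ``(low, high)``
    channel intervals ordered by channel.
    """
    counts = histogram.counts
    if counts.size == 0 or counts.max() == 0:
        return []
    smooth = np.convolve(np.pad(counts.astype(float), 2, mode="edge"),
                         np.full(5, 0.2), mode="valid")
    # pad the right edge only: a spike in the last bin (all events at the
    # channel maximum) is a peak, but the debris decay into bin 0 is not
    padded = np.concatenate((smooth, [0.0]))
    apexes, _ = find_peaks(padded, prominence=min_prominence * smooth.max(),
                           distance=4)
    apexes = apexes[apexes < counts.size]

    spans: list[list[int]] = []
    for apex in apexes:
        thresh = drop_fraction * smooth[apex]
        lo = apex
        while lo > 0 and smooth[lo - 1] > thresh and apex - (lo - 1) <= max_halfwidth:
            lo -= 1
        hi = apex
        n = counts.size
        while hi < n - 1 and smooth[hi + 1] > thresh and (hi + 1) - apex <= max_halfwidth:
            hi += 1
        spans.append([lo, hi, apex])

    # enforce disjoint windows: cut overlapping neighbours at the valley
    for left, right in zip(spans, spans[1:]):
        if left[1] >= right[0]:
            valley = left[2] + int(np.argmin(smooth[left[2]: right[2] + 1]))
            left[1] = min(left[1], valley - 1)
            right[0] = max(right[0], valley)

    windows = []
    for lo, hi, _apex in spans:
        if hi < lo:
            continue
        if counts[lo: hi + 1].sum() < min_events:
            continue
        windows.append((float(histogram.edges[lo]), float(histogram.edges[hi + 1])))
    return sorted(windows)


def estimate_peak_stats(
    events: EventSet,
    window: tuple[float, float],
    min_events: int = 50,
) -> PeakEstimate:
    """Mean fluorescence and CV of the events inside a half-open window."""
    low, high = window
    values = events.values[(events.values >= low) & (events.values < high)]
    if values.size < min_events:
        raise CytometryError(
            f"peak window [{low:.3g}, {high:.3g}) of {events.sample_id} holds "
            f"{values.size} events (< {min_events}); peak discarded"
        )
    mean = float(values.mean())
    sd = float(values.std())  # population SD
    return PeakEstimate(
        mean_fluorescence=mean,
        cv=100.0 * sd / mean,
        event_count=int(values.size),
        window=(float(low), float(high)),
    )


def compute_gs(sample_mean: float, standard_mean: float,
               standard_gs: float = DEFAULT_STANDARD_GS) -> float:
    """2C genome size in pg from the sample/standard fluorescence ratio.

    GS = (sample mean fluorescence / standard mean fluorescence) x standard
    genome size.  Linear in the sample mean; scale-free in the channel units.
    """
    if sample_mean <= 0 or standard_mean <= 0 or standard_gs <= 0:
        raise CytometryError("peak means and the standard genome size must be positive")
    return sample_mean / standard_mean * standard_gs


def evaluate_events(
    events: EventSet,
    standard_gs: float = DEFAULT_STANDARD_GS,
    reference_channel: float = DEFAULT_REFERENCE_CHANNEL,
    n_bins: int = 256,
    min_prominence: float = 0.05,
    min_events: int = 50,
    cv_max: float = DEFAULT_CV_MAX,
    population_id: str | None = None,
) -> SampleMeasurement:
    """Evaluate one analysis end to end: peaks, CVs, genome size, QC verdict.

    The standard peak is the detected peak nearest ``reference_channel``;
    the sample peak is the largest remaining peak.
    """
    histogram = build_histogram(events, n_bins=n_bins)
    windows = detect_peaks(histogram, min_prominence=min_prominence, min_events=min_events)

    estimates: list[PeakEstimate] = []
    for window in windows:
        try:
            estimates.append(estimate_peak_stats(events, window, min_events=min_events))
        except CytometryError as exc:
            logger.info("%s", exc)

    if not estimates:
        return SampleMeasurement(
            sample_id=events.sample_id, sample_peak=None, standard_peak=None,
            genome_size=float("nan"), qc_pass=False,
            qc_reason="no peaks detected", population_id=population_id,
        )

    standard = min(estimates, key=lambda p: abs(p.mean_fluorescence - reference_channel))
    others = [p for p in estimates if p is not standard]
    note = ""
    if others:
        sample = max(others, key=lambda p: p.event_count)
    else:
        sample = standard
        note = "single peak: sample assumed to coincide with the standard; "
        logger.warning(
            "%s: only one peak detected; sample and standard peaks overlap "
            "(genome size near the standard's %.2f pg)", events.sample_id, standard_gs,
        )

    gs = compute_gs(sample.mean_fluorescence, standard.mean_fluorescence, standard_gs)
    cvs = (sample.cv, standard.cv)
    qc_pass = all(cv < cv_max for cv in cvs)
    if qc_pass:
        reason = note + "ok"
    else:
        reason = note + f"peak CV {max(cvs):.2f}% >= {cv_max}%"
    return SampleMeasurement(
        sample_id=events.sample_id, sample_peak=sample, standard_peak=standard,
        genome_size=gs, qc_pass=qc_pass, qc_reason=reason, population_id=population_id,
    )


def qc_filter(
    measurements: Iterable[SampleMeasurement],
    cv_max: float = DEFAULT_CV_MAX,
) -> tuple[list[SampleMeasurement], list[SampleMeasurement]]:
    """Partition measurements into (passed, failed) by the strict CV rule.

    A measurement passes iff both retained peak CVs are strictly below
    ``cv_max`` and a genome size was obtained.  The returned lists always
    partition the input.
    """
    if cv_max <= 0:
        raise CytometryError("cv_max must be positive")
    passed: list[SampleMeasurement] = []
    failed: list[SampleMeasurement] = []
    for m in measurements:
        if m.sample_peak is None or m.standard_peak is None or not np.isfinite(m.genome_size):
            failed.append(replace(m, qc_pass=False,
                                  qc_reason=m.qc_reason or "no evaluable peaks"))
            continue
        cvs = (m.sample_peak.cv, m.standard_peak.cv)
        if all(cv < cv_max for cv in cvs):
            passed.append(replace(m, qc_pass=True))
        else:
            failed.append(replace(
                m, qc_pass=False,
                qc_reason=f"peak CV {max(cvs):.2f}% >= {cv_max}%"))
    return passed, failed


# ---------------------------------------------------------------------------
# tabular I/O

def measurements_to_frame(measurements: Sequence[SampleMeasurement]) -> pd.DataFrame:
    """Flatten measurements into the measurements CSV layout."""
    rows = []
    for m in measurements:
        rows.append({
            "sample_id": m.sample_id,
            "population_id": m.population_id,
            "sample_mean": m.sample_peak.mean_fluorescence if m.sample_peak else np.nan,
            "sample_cv": m.sample_peak.cv if m.sample_peak else np.nan,
            "standard_mean": m.standard_peak.mean_fluorescence if m.standard_peak else np.nan,
            "standard_cv": m.standard_peak.cv if m.standard_peak else np.nan,
            "genome_size": m.genome_size,
            "qc_pass": m.qc_pass,
            "qc_reason": m.qc_reason,
        })
    return pd.DataFrame(rows)


def frame_to_measurements(frame: pd.DataFrame,
                          cv_max: float = DEFAULT_CV_MAX) -> list[SampleMeasurement]:
    """Rebuild measurements from a pre-evaluated per-sample table.

    Accepts FloMax-style exports with columns ``sample_id, sample_mean,
    sample_cv, standard_mean, standard_cv`` (optionally ``population_id``);
    genome size and QC are recomputed if absent.
    """
    required = {"sample_id", "sample_mean", "sample_cv", "standard_mean", "standard_cv"}
    missing = required - set(frame.columns)
    if missing:
        raise CytometryError(f"measurement table lacks columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        span = max(1.0, 0.1 * row.sample_mean)
        sample = PeakEstimate(row.sample_mean, row.sample_cv, -1,
                              (row.sample_mean - span, row.sample_mean + span))
        span = max(1.0, 0.1 * row.standard_mean)
        standard = PeakEstimate(row.standard_mean, row.standard_cv, -1,
                                (row.standard_mean - span, row.standard_mean + span))
        gs = getattr(row, "genome_size", None)
        if gs is None or not np.isfinite(gs):
            gs = compute_gs(row.sample_mean, row.standard_mean)
        qc = bool(max(row.sample_cv, row.standard_cv) < cv_max)
        out.append(SampleMeasurement(
            sample_id=str(row.sample_id), sample_peak=sample, standard_peak=standard,
            genome_size=float(gs), qc_pass=qc,
            qc_reason="ok" if qc else f"peak CV >= {cv_max}%",
            population_id=str(getattr(row, "population_id", "")) or None,
        ))
    return out


def read_events_csv(path: str | Path) -> dict[str, EventSet]:
    """Read a long-format events CSV (sample_id, channel_value[, truth_label])."""
    frame = pd.read_csv(path)
    if not {"sample_id", "channel_value"} <= set(frame.columns):
        raise CytometryError("events CSV needs columns sample_id, channel_value")
    out: dict[str, EventSet] = {}
    for sample_id, chunk in frame.groupby("sample_id", sort=False):
        labels = chunk["truth_label"].to_numpy() if "truth_label" in chunk else None
        out[str(sample_id)] = EventSet(
            sample_id=str(sample_id),
            values=chunk["channel_value"].to_numpy(dtype=float),
            labels=labels,
        )
    return out
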