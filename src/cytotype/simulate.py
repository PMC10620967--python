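"""Synthetic flow-cytometry studies of a mixed-ploidy plant complex.

Generates what a field campaign plus an FCM lab would produce: per-plant
fluorescence event sets (sample and internal-standard peaks over a decaying
debris background), a chromosome-count table for a calibration subset of
plants, a population table with habitat classes, and a ground-truth table
for evaluating the downstream analysis.

The generative model
--------------------
Each cytotype is a genome-size group: individuals of cytotype ``c`` draw
their true 2C genome size from ``Normal(gs_mean_c, gs_sd_c)`` (the
between-individual spread), while each FCM analysis adds within-analysis
dispersion through the configured peak CVs.  The standard peak sits at a
fixed reference channel; the sample peak at ``reference x true_gs /
standard_gs``; debris events follow a truncated exponential over the low
channels.  A configurable fraction of analyses gets inflated CVs so the
downstream quality filter has realistic work to do.

Randomness is hierarchical: one master seed is split per population and
individual with :class:`numpy.random.SeedSequence`, so a fixed seed yields
byte-identical studies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cytometry import (
    DEFAULT_REFERENCE_CHANNEL,
    DEFAULT_STANDARD_GS,
    EventSet,
)

#: Monoploid chromosome number of the complex (x); somatic count 2n = ploidy * x.
MONOPLOID_NUMBER = 7

_LABEL_RE = re.compile(r"^(\d+)x[A-Z]?$")


class SimulationError(ValueError):
    """Invalid simulation configuration or arguments."""


@dataclass(frozen=True)
class CytotypeSpec:
    """One genome-size group of the generative scenario.

    ``ploidy`` is in multiples of the monoploid number (2 = diploid …
    7 = heptaploid); ``gs_mean``/``gs_sd`` are the between-individual 2C
    genome-size mean and SD in pg; ``prevalence`` is the group's overall
    fraction among sampled individuals.
    """

    label: str
    ploidy: int
    gs_mean: float
    gs_sd: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.gs_mean <= 0 or self.gs_sd <= 0:
            raise SimulationError(f"{self.label}: gs_mean and gs_sd must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise SimulationError(f"{self.label}: prevalence must lie in [0, 1]")
        if self.ploidy < 1:
            raise SimulationError(f"{self.label}: ploidy must be a positive integer")
        match = _LABEL_RE.match(self.label)
        if match and int(match.group(1)) != self.ploidy:
            raise SimulationError(
                f"label {self.label!r} contradicts ploidy {self.ploidy}")

    @property
    def two_n(self) -> int:
        return self.ploidy * MONOPLOID_NUMBER


#: Published genome-size groups of the studied complex: label, ploidy,
#: mean 2C (pg), SD (pg).  Default prevalences are this package's choice,
#: qualitatively mirroring a landscape dominated by the heaviest hexaploid
#: group; the source study does not report group frequencies.
DEFAULT_CYTOTYPES: tuple[CytotypeSpec, ...] = (
    CytotypeSpec("2x", 2, 2.587, 0.036, 0.05),
    CytotypeSpec("4xA", 4, 5.265, 0.147, 0.12),
    CytotypeSpec("4xB", 4, 5.966, 0.128, 0.03),
    CytotypeSpec("5x", 5, 6.445, 0.173, 0.04),
    CytotypeSpec("6xA", 6, 7.405, 0.095, 0.05),
    CytotypeSpec("6xB", 6, 7.752, 0.101, 0.12),
    CytotypeSpec("6xC", 6, 8.196, 0.132, 0.49),
    CytotypeSpec("7x", 7, 8.643, 0.100, 0.10),
)

#: Probability that a population dominated by the given group lies in an
#: anthropogenic (roadside-type) habitat.  Hexaploids spread along salted
#: roads; diploids and pentaploids stay in natural saline habitats.
DEFAULT_HABITAT_PROBS: dict[str, float] = {
    "2x": 0.0, "4xA": 0.10, "4xB": 0.05, "5x": 0.0,
    "6xA": 0.30, "6xB": 0.40, "6xC": 0.70, "7x": 0.30,
}


@dataclass
class ScenarioConfig:
    """Full description of one synthetic study.

    ``mixture_matrix`` has one row per population giving the probability of
    each cytotype (column order = ``cytotypes`` order); each individual of
    the population draws its group from that row.  ``habitat_probs`` maps a
    cytotype label to the probability that a population whose mixture row is
    dominated by that label is anthropogenic.  ``qc_fail_fraction`` of
    analyses get both peak CVs inflated to 3-6% so they fail the 2.5% filter.
    """

    cytotypes: Sequence[CytotypeSpec] = DEFAULT_CYTOTYPES
    n_populations: int = 133
    individuals_per_population: int = 15
    mixture_matrix: np.ndarray | None = None
    habitat_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_PROBS))
    n_particles: int = 3500
    cv_sample: float = 1.5
    cv_standard: float = 1.5
    debris_fraction: float = 0.10
    qc_fail_fraction: float = 0.15
    anchor_count: int = 39
    standard_gs: float = DEFAULT_STANDARD_GS
    reference_channel: float = DEFAULT_REFERENCE_CHANNEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.individuals_per_population < 1 or self.n_populations < 1:
            raise SimulationError("population counts must be >= 1")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise SimulationError("debris_fraction must lie in [0, 1)")
        if not 0.0 <= self.qc_fail_fraction < 1.0:
            raise SimulationError("qc_fail_fraction must lie in [0, 1)")
        if self.n_particles < 100:
            raise SimulationError("n_particles must be >= 100")
        total = self.n_populations * self.individuals_per_population
        if self.anchor_count > total:
            raise SimulationError("anchor_count exceeds the number of individuals")
        prevalences = np.array([c.prevalence for c in self.cytotypes])
        if abs(prevalences.sum() - 1.0) > 1e-8:
            raise SimulationError("cytotype prevalences must sum to 1")
        labels = [c.label for c in self.cytotypes]
        if len(set(labels)) != len(labels):
            raise SimulationError("cytotype labels must be unique")
        if self.mixture_matrix is not None:
            matrix = np.asarray(self.mixture_matrix, dtype=float)
            if matrix.shape != (self.n_populations, len(labels)):
                raise SimulationError(
                    f"mixture_matrix must be {self.n_populations} x {len(labels)}")
            if np.any(matrix < 0) or np.any(np.abs(matrix.sum(axis=1) - 1.0) > 1e-8):
                raise SimulationError("mixture_matrix rows must be probabilities summing to 1")
            self.mixture_matrix = matrix

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.cytotypes]


@dataclass(frozen=True)
class SimulatedStudy:
    """Everything one synthetic field campaign delivers.

    ``truth`` columns: sample_id, population_id, group, ploidy, true_gs,
    is_anchor, two_n (NaN unless anchored), qc_inflated, habitat.
    """

    events: dict[str, EventSet]
    chromosome_counts: pd.DataFrame
    populations: pd.DataFrame
    truth: pd.DataFrame
    config: ScenarioConfig


def simulate_events(
    true_gs: float,
    standard_gs: float = DEFAULT_STANDARD_GS,
    cv_sample: float = 1.5,
    cv_standard: float = 1.5,
    n_particles: int = 3500,
    debris_fraction: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    reference_channel: float = DEFAULT_REFERENCE_CHANNEL,
    sample_fraction: float = 0.5,
    sample_id: str = "sample",
) -> EventSet:
    """Simulate the event stream of one co-stained FCM analysis.

    The standard peak is centred at ``reference_channel``; the sample peak
    at ``reference_channel * true_gs / standard_gs``.  Peak events are
    Gaussian with relative SD ``cv/100``.  A binomial share of
    ``debris_fraction`` events comes from a truncated exponential spanning
    the channels below the lower peak.  Ground-truth event labels are kept
    on the returned :class:`EventSet`.
    """
    if true_gs <= 0 or standard_gs <= 0:
        raise SimulationError("genome sizes must be positive")
    if n_particles <= 0:
        raise SimulationError("n_particles must be positive")
    if not 0.0 <= debris_fraction < 1.0:
        raise SimulationError("debris_fraction must lie in [0, 1)")
    if cv_sample < 0 or cv_standard < 0:
        raise SimulationError("CVs cannot be negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    sample_centre = reference_channel * true_gs / standard_gs
    n_debris = rng.binomial(n_particles, debris_fraction)
    n_sample = rng.binomial(n_particles - n_debris, sample_fraction)
    n_standard = n_particles - n_debris - n_sample

    sample_events = rng.normal(sample_centre, sample_centre * cv_sample / 100.0, n_sample)
    standard_events = rng.normal(
        reference_channel, reference_channel * cv_standard / 100.0, n_standard)
    # debris: exponential decay truncated to the channels below the lower peak
    cutoff = min(sample_centre, reference_channel)
    scale = cutoff / 3.0
    u = rng.random(n_debris)
    debris_events = -scale * np.log1p(-u * (1.0 - np.exp(-cutoff / scale)))

    values = np.concatenate([sample_events, standard_events, debris_events])
    values = np.clip(values, 0.0, None)
    labels = np.concatenate([
        np.repeat("sample", n_sample),
        np.repeat("standard", n_standard),
        np.repeat("debris", n_debris),
    ])
    order = rng.permutation(n_particles)
    return EventSet(sample_id=sample_id, values=values[order], labels=labels[order])


def _draw_positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100):
        value = rng.normal(mean, sd)
        if value > 0:
            return float(value)
    raise SimulationError(f"could not draw a positive genome size from N({mean}, {sd})")


def simulate_study(config: ScenarioConfig) -> SimulatedStudy:
    """Generate a full synthetic study from a scenario configuration.

    Deterministic given ``config.seed``.  Anchors (chromosome-counted
    individuals) are drawn so that every cytotype present receives at least
    one anchor, preferring individuals without injected QC failures; each
    anchor's 2n is exactly ``ploidy x 7``.
    """
    master = np.random.SeedSequence(config.seed)
    pop_seeds = master.spawn(config.n_populations)

    if config.mixture_matrix is None:
        prevalences = np.array([c.prevalence for c in config.cytotypes])
        matrix = np.tile(prevalences, (config.n_populations, 1))
    else:
        matrix = np.asarray(config.mixture_matrix, dtype=float)

    labels = config.labels
    events: dict[str, EventSet] = {}
    truth_rows = []
    pop_rows = []

    for p in range(config.n_populations):
        pop_id = f"P{p + 1:03d}"
        row = matrix[p]
        dominant = labels[int(np.argmax(row))]
        pop_ss = pop_seeds[p]
        ind_seeds = pop_ss.spawn(config.individuals_per_population + 1)
        rng_pop = np.random.default_rng(ind_seeds[-1])
        p_anthro = float(config.habitat_probs.get(dominant, 0.5))
        habitat = "anthropogenic" if rng_pop.random() < p_anthro else "natural"
        lat = float(rng_pop.uniform(46.0, 52.0))
        lon = float(rng_pop.uniform(8.0, 22.0))
        pop_rows.append({
            "population_id": pop_id, "habitat": habitat,
            "latitude": round(lat, 5), "longitude": round(lon, 5),
            "n_sampled": config.individuals_per_population,
        })
        for j in range(config.individuals_per_population):
            rng_ind = np.random.default_rng(ind_seeds[j])
            cyt = config.cytotypes[int(rng_ind.choice(len(labels), p=row))]
            true_gs = _draw_positive_normal(rng_ind, cyt.gs_mean, cyt.gs_sd)
            inflated = bool(rng_ind.random() < config.qc_fail_fraction)
            if inflated:
                cv_s = float(rng_ind.uniform(3.0, 6.0))
                cv_st = float(rng_ind.uniform(3.0, 6.0))
            else:
                cv_s, cv_st = config.cv_sample, config.cv_standard
            sample_id = f"{pop_id}-{j + 1:02d}"
            events[sample_id] = simulate_events(
                true_gs=true_gs, standard_gs=config.standard_gs,
                cv_sample=cv_s, cv_standard=cv_st,
                n_particles=config.n_particles,
                debris_fraction=config.debris_fraction,
                rng=rng_ind, reference_channel=config.reference_channel,
                sample_id=sample_id,
            )
            truth_rows.append({
                "sample_id": sample_id, "population_id": pop_id,
                "group": cyt.label, "ploidy": cyt.ploidy,
                "true_gs": true_gs, "qc_inflated": inflated, "habitat": habitat,
            })

    truth = pd.DataFrame(truth_rows)
    truth["is_anchor"] = False
    truth["two_n"] = np.nan

    # anchor sampling: chromosome counting "representatively covers" every
    # group, so each cytotype receives anchors at evenly spaced quantile
    # ranks of its genome-size range (margins included — group boundaries
    # are later read off the extreme anchored individuals), restricted to
    # clean analyses within the central +-2 SD of the group
    spec_of = {c.label: c for c in config.cytotypes}
    central = truth.apply(
        lambda r: abs(r["true_gs"] - spec_of[r["group"]].gs_mean)
        <= 2.0 * spec_of[r["group"]].gs_sd, axis=1)
    # near-equal per-group quotas: calibration covers every group about
    # equally (minor cytotypes are deliberately oversampled relative to
    # their frequency), remainder going to the largest groups
    present = truth["group"].value_counts()
    base = config.anchor_count // len(present)
    quota = {g: max(1, base) for g in present.index}
    order = sorted(quota, key=lambda g: -present[g])
    while sum(quota.values()) > config.anchor_count:
        g = max(quota, key=lambda g: quota[g])
        quota[g] -= 1
    i = 0
    while sum(quota.values()) < config.anchor_count:
        quota[order[i % len(order)]] += 1
        i += 1
    chosen: list[int] = []
    for label, n_g in quota.items():
        members = truth.index[(truth["group"] == label)
                              & ~truth["qc_inflated"] & central]
        if len(members) == 0:
            members = truth.index[truth["group"] == label]
        ranked = members[np.argsort(truth.loc[members, "true_gs"].to_numpy())]
        picks = np.unique(np.round(
            np.linspace(0, len(ranked) - 1, min(n_g, len(ranked)))).astype(int))
        chosen.extend(int(ranked[p]) for p in picks)
    truth.loc[chosen, "is_anchor"] = True
    truth.loc[chosen, "two_n"] = truth.loc[chosen, "ploidy"] * MONOPLOID_NUMBER

    counts = (truth.loc[truth["is_anchor"], ["sample_id", "two_n"]]
              .assign(two_n=lambda d: d["two_n"].astype(int))
              .reset_index(drop=True))
    populations = pd.DataFrame(pop_rows)
    return SimulatedStudy(events=events, chromosome_counts=counts,
                          populations=populations, truth=truth, config=config)


def default_scenario(
    n_populations: int = 133,
    individuals_per_population: int = 15,
    seed: int = 0,
    mixed_fraction: float = 0.38,
    cytotypes: Sequence[CytotypeSpec] = DEFAULT_CYTOTYPES,
    **kwargs,
) -> ScenarioConfig:
    """Default eight-cytotype scenario with a mix of pure and mixed populations.

    ``mixed_fraction`` of populations receive a mixed composition row: the
    dominant group (drawn by prevalence) keeps weight 0.6 and one or two
    companion groups share the remaining 0.4.  Pure populations are one-hot.
    The matrix construction uses its own stream derived from ``seed`` so the
    per-individual streams of :func:`simulate_study` are unaffected.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7001,)))
    prevalences = np.array([c.prevalence for c in cytotypes])
    k = len(cytotypes)
    matrix = np.zeros((n_populations, k))
    for p in range(n_populations):
        dominant = int(rng.choice(k, p=prevalences))
        if rng.random() < mixed_fraction:
            others = np.delete(np.arange(k), dominant)
            weights = prevalences[others] / prevalences[others].sum()
            n_comp = 1 if rng.random() < 0.7 else 2
            companions = rng.choice(others, size=n_comp, replace=False, p=weights)
            matrix[p, dominant] = 0.6
            matrix[p, companions] = 0.4 / n_comp
        else:
            matrix[p, dominant] = 1.0
    return ScenarioConfig(
        cytotypes=tuple(cytotypes), n_populations=n_populations,
        individuals_per_population=individuals_per_population,
        mixture_matrix=matrix, seed=seed, **kwargs,
    )


# ---------------------------------------------------------------------------
# configuration and table I/O

def scenario_to_dict(config: ScenarioConfig) -> dict:
    return {
        "cytotypes": [
            {"label": c.label, "ploidy": c.ploidy, "gs_mean": c.gs_mean,
             "gs_sd": c.gs_sd, "prevalence": c.prevalence}
            for c in config.cytotypes
        ],
        "n_populations": config.n_populations,
        "individuals_per_population": config.individuals_per_population,
        "mixture_matrix": (None if config.mixture_matrix is None
                           else np.asarray(config.mixture_matrix).tolist()),
        "habitat_probs": dict(config.habitat_probs),
        "n_particles": config.n_particles,
        "cv_sample": config.cv_sample,
        "cv_standard": config.cv_standard,
        "debris_fraction": config.debris_fraction,
        "qc_fail_fraction": config.qc_fail_fraction,
        "anchor_count": config.anchor_count,
        "standard_gs": config.standard_gs,
        "reference_channel": config.reference_channel,
        "seed": config.seed,
    }


def scenario_from_dict(data: Mapping) -> ScenarioConfig:
    data = dict(data)
    cytotypes = tuple(CytotypeSpec(**c) for c in data.pop("cytotypes"))
    matrix = data.pop("mixture_matrix", None)
    if matrix is not None:
        matrix = np.asarray(matrix, dtype=float)
    return ScenarioConfig(cytotypes=cytotypes, mixture_matrix=matrix, **data)


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(config), sort_keys=False))


def load_scenario(path: str | Path) -> ScenarioConfig:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))


def write_events_csv(events: Mapping[str, EventSet], path: str | Path) -> None:
    """Long-format events table: sample_id, channel_value, truth_label."""
    frames = []
    for sample_id, ev in events.items():
        frames.append(pd.DataFrame({
            "sample_id": sample_id,
            "channel_value": ev.values,
            "truth_label": ev.labels if ev.labels is not None else "",
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
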