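"""Population-level cytotype composition and habitat structure.

Summarises per-individual group assignments into per-population
compositions (pure vs mixed), counts populations per group combination in
the style of an upset plot, and tabulates which groups occur in natural vs
anthropogenic habitats.  Unassigned individuals never enter a population's
``groups_present`` set — "mixed" is strictly about delimited groups — but
their count is reported alongside.

The habitat association adds a permutation test (habitat labels shuffled
across populations) as a diagnostic; the counts themselves are the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delimit import UNASSIGNED

HABITATS = ("natural", "anthropogenic")


class StructureError(ValueError):
    """Invalid population summary input."""


@dataclass(frozen=True)
class PopulationSummary:
    """Cytotype composition of one population."""

    population_id: str
    habitat: str
    groups_present: frozenset[str]
    counts: dict[str, int]
    n_assigned: int
    n_unassigned: int

    @property
    def is_mixed(self) -> bool:
        return len(self.groups_present) >= 2

    @property
    def ploidies_present(self) -> frozenset[int]:
        return frozenset(int(g.rstrip("ABCDEFGH").rstrip("x")) for g in self.groups_present)


def summarize_populations(
    assignments: pd.DataFrame,
    populations: pd.DataFrame,
) -> list[PopulationSummary]:
    """One composition summary per population.

    ``assignments`` needs ``population_id`` and ``group`` columns (the
    output of :func:`cytotype.delimit.assign`); ``populations`` needs
    ``population_id`` and ``habitat``.  Populations without a single
    assigned individual are kept (empty group set) rather than dropped;
    assignments pointing at unknown populations are an error.
    """
    if not {"population_id", "group"} <= set(assignments.columns):
        raise StructureError("assignments need population_id and group columns")
    if not {"population_id", "habitat"} <= set(populations.columns):
        raise StructureError("populations need population_id and habitat columns")
    bad_habitat = set(populations["habitat"]) - set(HABITATS)
    if bad_habitat:
        raise StructureError(f"unknown habitat classes: {sorted(bad_habitat)}")
    known = set(populations["population_id"])
    unknown = set(assignments["population_id"]) - known
    if unknown:
        raise StructureError(f"assignments reference unknown populations: {sorted(unknown)}")

    habitat_of = dict(zip(populations["population_id"], populations["habitat"]))
    summaries = []
    grouped = dict(tuple(assignments.groupby("population_id", sort=False)))
    for pop_id in populations["population_id"]:
        chunk = grouped.get(pop_id)
        if chunk is None:
            counts: dict[str, int] = {}
            n_unassigned = 0
        else:
            counts = {str(k): int(v) for k, v in
                      chunk["group"].value_counts().items()}
            n_unassigned = counts.pop(UNASSIGNED, 0)
        summaries.append(PopulationSummary(
            population_id=str(pop_id),
            habitat=habitat_of[pop_id],
            groups_present=frozenset(counts),
            counts=counts,
            n_assigned=sum(counts.values()),
            n_unassigned=n_unassigned,
        ))
    return summaries


def summaries_to_frame(summaries: list[PopulationSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {"population_id": s.population_id, "habitat": s.habitat,
         "groups_present": "+".join(sorted(s.groups_present)),
         "is_mixed": s.is_mixed, "n_assigned": s.n_assigned,
         "n_unassigned": s.n_unassigned}
        for s in summaries
    ])


def mixed_fractions(summaries: list[PopulationSummary]) -> dict[str, float]:
    """Fractions of populations mixed by genome-size group and by ploidy.

    Two hexaploid groups in one population make it group-mixed but not
    ploidy-mixed, so the two fractions can differ; both are reported.
    Populations with no assigned individuals are excluded from the
    denominator.
    """
    with_data = [s for s in summaries if s.n_assigned > 0]
    if not with_data:
        return {"group_mixed": float("nan"), "ploidy_mixed": float("nan")}
    n = len(with_data)
    return {
        "group_mixed": sum(s.is_mixed for s in with_data) / n,
        "ploidy_mixed": sum(len(s.ploidies_present) >= 2 for s in with_data) / n,
    }


def intersection_counts(summaries: list[PopulationSummary]) -> pd.DataFrame:
    """Upset-style table: populations per group combination, split by habitat.

    Combinations are ordered by frequency descending, ties by label.
    Combination counts sum to the number of populations.
    """
    if not summaries:
        raise StructureError("need at least one population summary")
    rows: dict[str, dict[str, int]] = {}
    for s in summaries:
        key = "+".join(sorted(s.groups_present)) if s.groups_present else "(none)"
        entry = rows.setdefault(key, {"n_populations": 0, "n_natural": 0,
                                      "n_anthropogenic": 0})
        entry["n_populations"] += 1
        entry["n_natural" if s.habitat == "natural" else "n_anthropogenic"] += 1
    frame = (pd.DataFrame.from_dict(rows, orient="index")
             .rename_axis("combination").reset_index())
    return (frame.sort_values(["n_populations", "combination"],
                              ascending=[False, True])
            .reset_index(drop=True))


def habitat_association(
    summaries: list[PopulationSummary],
    n_permutations: int = 10_000,
    seed: int | None = None,
    randomize_ties: bool = False,
) -> pd.DataFrame:
    """Per-group habitat contingency with a permutation diagnostic.

    For each group: the number of natural and anthropogenic populations
    containing it, plus a two-sided permutation p-value obtained by
    shuffling habitat labels across populations (the statistic is the
    anthropogenic count).  The counts are the descriptive result; p-values
    are diagnostics.  With ``randomize_ties`` the p-value uses the
    randomized tie-breaking construction, making it exactly uniform under
    the null — useful for calibration checks, at the price of an extra
    random draw.
    """
    if len(summaries) < 2:
        raise StructureError("habitat association needs at least two populations")
    habitats = np.array([s.habitat for s in summaries])
    if len(set(habitats)) < 2:
        warnings.warn("all populations share one habitat class; "
                      "association test skipped", stacklevel=2)
        skip = True
    else:
        skip = False
    rng = np.random.default_rng(seed)
    groups = sorted({g for s in summaries for g in s.groups_present})
    is_anthro = habitats == "anthropogenic"

    rows = []
    for group in groups:
        present = np.array([group in s.groups_present for s in summaries])
        n_anthro = int((present & is_anthro).sum())
        n_natural = int(present.sum()) - n_anthro
        if skip:
            p_value = np.nan
        else:
            perm = np.empty(n_permutations)
            for b in range(n_permutations):
                perm[b] = (present & rng.permutation(is_anthro)).sum()
            if randomize_ties:
                u = rng.random()
                p_hi = ((perm > n_anthro).sum()
                        + u * ((perm == n_anthro).sum() + 1)) / (n_permutations + 1)
                p_value = 2.0 * min(p_hi, 1.0 - p_hi)
            else:
                p_hi = ((perm >= n_anthro).sum() + 1) / (n_permutations + 1)
                p_lo = ((perm <= n_anthro).sum() + 1) / (n_permutations + 1)
                p_value = min(1.0, 2.0 * min(p_hi, p_lo))
        rows.append({"group": group, "n_natural": n_natural,
                     "n_anthropogenic": n_anthro, "p_value": p_value})
    return pd.DataFrame(rows)


def plot_intersections(intersections: pd.DataFrame, path) -> None:
    """Stacked-bar rendering of the intersection table (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(intersections)), 4))
    x = np.arange(len(intersections))
    ax.bar(x, intersections["n_natural"], label="natural", color="#2a7f3f")
    ax.bar(x, intersections["n_anthropogenic"],
           bottom=intersections["n_natural"], label="anthropogenic", color="#b4533c")
    ax.set_xticks(x)
    ax.set_xticklabels(intersections["combination"], rotation=60, ha="right")
    ax.set_ylabel("populations")
    ax.set_title("Populations per genome-size-group combination")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
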