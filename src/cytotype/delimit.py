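"""Delimitation of genome-size groups anchored by chromosome counts.

The fitted mixture gives candidate groups; chromosome-counted individuals
("anchors") tie each mixture component to a ploidy level (2n / x with
monoploid number x = 7).  Group boundaries follow two rules:

1. between overlapping groups of *different* ploidy, the boundary is set by
   the anchored individuals: the lower group reaches up to the highest
   genome size among anchors of its ploidy, the upper group reaches down to
   the lowest genome size among anchors of its ploidy;
2. between overlapping groups of the *same* ploidy, each group keeps its
   own 1st/99th Normal percentile edge, so the shared stretch belongs to
   both and its individuals stay unassigned.

Non-overlapping neighbours keep plain percentile edges; the outermost edges
are unbounded by default.  Individuals whose genome size falls in exactly
one group interval are assigned to it; in zero or two or more intervals
they are left unassigned — deliberately conservative, interval-based only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixture import MixtureModel, classify, percentile_interval
from .simulate import MONOPLOID_NUMBER

logger = logging.getLogger(__name__)

#: Label used for individuals that no group interval claims unambiguously.
UNASSIGNED = "unassigned"

_SUFFIXES = "ABCDEFGH"


class DelimitationError(ValueError):
    """Inconsistent anchors or pathological boundary placement."""


class AneuploidError(DelimitationError):
    """A chromosome count that is not a multiple of the monoploid number."""


@dataclass(frozen=True)
class ComponentMapping:
    """Component index -> ploidy and group label (components mean-sorted)."""

    ploidies: tuple[int, ...]
    labels: tuple[str, ...]


@dataclass(frozen=True)
class GsGroup:
    """A delimited genome-size group with a half-open interval [low, high).

    ``low_rule``/``high_rule`` record how each edge was derived:
    ``"anchor"``, ``"percentile"`` or ``"unbounded"``.
    """

    label: str
    ploidy: int
    component_index: int
    low: float
    high: float
    low_rule: str
    high_rule: str

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise DelimitationError(
                f"group {self.label}: low {self.low} >= high {self.high} "
                "(pathological anchor placement)")

    def contains(self, gs: float) -> bool:
        return self.low <= gs < self.high


def ploidy_from_count(two_n: int, x: int = MONOPLOID_NUMBER) -> int:
    """Ploidy level from a somatic chromosome count (2n / x).

    Counts that are not multiples of ``x`` flag a putative aneuploid and are
    rejected; the complex shows none among counted individuals.
    """
    if two_n <= 0:
        raise DelimitationError(f"chromosome count must be positive, got {two_n}")
    if two_n % x != 0:
        raise AneuploidError(
            f"2n = {two_n} is not a multiple of x = {x}: putative aneuploid")
    return two_n // x


def map_components_to_ploidy(
    model: MixtureModel,
    anchor_gs,
    anchor_two_n,
    strict: bool = True,
) -> ComponentMapping:
    """Tie every mixture component to a ploidy via its anchors.

    Anchors are classified by max posterior; each component needs at least
    one anchor.  With ``strict`` (default) all of a component's anchors
    must agree on ploidy — a disagreement is a data inconsistency.  With
    ``strict=False`` each anchor's vote is weighted by its posterior
    responsibility for the component and the heaviest ploidy wins; the
    outvoted anchors are logged (an anchor whose genome size strays across
    the posterior boundary of two overlapping components is expected
    occasionally, and still shows up in :func:`anchor_conflicts`); an
    exact tie is always an error.
    Components sharing a ploidy get letter suffixes by ascending mean
    (6xA < 6xB …); a ploidy with a single component gets the bare label
    (e.g. ``5x``).
    """
    anchor_gs = np.asarray(anchor_gs, dtype=float).ravel()
    anchor_two_n = np.asarray(anchor_two_n).ravel().astype(int)
    if anchor_gs.size != anchor_two_n.size:
        raise DelimitationError("anchor genome sizes and counts differ in length")
    if anchor_gs.size == 0:
        raise DelimitationError("no anchors provided")
    ploidy = np.array([ploidy_from_count(c) for c in anchor_two_n])
    resp, components = classify(model, anchor_gs)

    comp_ploidy: list[int] = []
    for j in range(model.k):
        here = ploidy[components == j]
        if here.size == 0:
            uncovered = [i for i in range(model.k)
                         if not np.any(components == i)]
            raise DelimitationError(
                f"components without anchors: {uncovered}; chromosome counts "
                "must representatively cover all genome-size groups")
        unique = np.unique(here)
        if unique.size > 1:
            if strict:
                raise DelimitationError(
                    f"anchors of component {j} disagree on ploidy: "
                    f"2n = {sorted(set(here * MONOPLOID_NUMBER))}")
            votes = np.array([
                resp[(components == j) & (ploidy == p), j].sum()
                for p in unique
            ])
            order = np.argsort(votes)
            if votes[order[-1]] - votes[order[-2]] <= 1e-12:
                raise DelimitationError(
                    f"anchors of component {j} tie on ploidy: "
                    f"2n = {sorted(set(here * MONOPLOID_NUMBER))}")
            winner = int(unique[order[-1]])
            logger.warning(
                "component %d: %d of %d anchors outvoted (majority ploidy %d)",
                j, int((here != winner).sum()), int(here.size), winner)
            comp_ploidy.append(winner)
        else:
            comp_ploidy.append(int(unique[0]))

    labels: list[str] = []
    for j, p in enumerate(comp_ploidy):
        same = [i for i, q in enumerate(comp_ploidy) if q == p]
        if len(same) == 1:
            labels.append(f"{p}x")
        else:
            labels.append(f"{p}x{_SUFFIXES[same.index(j)]}")
    return ComponentMapping(ploidies=tuple(comp_ploidy), labels=tuple(labels))


def overlap(
    component_a: tuple[float, float],
    component_b: tuple[float, float],
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> bool:
    """Whether two Normal components' percentile intervals intersect.

    Components are given as ``(mean, sd)``; percentiles use the closed form
    ``mean + z_p * sd``.
    """
    lo_a, hi_a = percentile_interval(*component_a, percentiles)
    lo_b, hi_b = percentile_interval(*component_b, percentiles)
    return lo_a < hi_b and lo_b < hi_a


def delimit_groups(
    model: MixtureModel,
    mapping: ComponentMapping,
    anchor_gs,
    anchor_two_n,
    percentiles: tuple[float, float] = (1.0, 99.0),
    bounded_tails: bool = False,
) -> list[GsGroup]:
    """Turn fitted components plus anchors into delimited genome-size groups.

    Provisional intervals are each component's percentile interval; for each
    pair of *adjacent* components of different ploidy whose intervals
    overlap, the lower group's high edge becomes the highest anchored
    genome size of the lower ploidy and the upper group's low edge the
    lowest anchored genome size of the upper ploidy.  Outermost edges are
    unbounded unless ``bounded_tails``.
    """
    anchor_gs = np.asarray(anchor_gs, dtype=float).ravel()
    anchor_two_n = np.asarray(anchor_two_n).ravel().astype(int)
    anchor_ploidy = np.array([ploidy_from_count(c) for c in anchor_two_n])

    k = model.k
    lows, highs = [], []
    low_rules, high_rules = [], []
    for j in range(k):
        lo, hi = percentile_interval(model.means[j], model.sds[j], percentiles)
        lows.append(lo)
        highs.append(hi)
        low_rules.append("percentile")
        high_rules.append("percentile")

    for j in range(k - 1):
        p_low, p_high = mapping.ploidies[j], mapping.ploidies[j + 1]
        if p_low == p_high:
            continue  # homoploid: percentile edges stand
        pair_overlaps = overlap((model.means[j], model.sds[j]),
                                (model.means[j + 1], model.sds[j + 1]),
                                percentiles)
        if not pair_overlaps:
            continue
        low_anchors = anchor_gs[anchor_ploidy == p_low]
        high_anchors = anchor_gs[anchor_ploidy == p_high]
        if low_anchors.size == 0 or high_anchors.size == 0:
            raise DelimitationError(
                f"no anchors of ploidy {p_low} or {p_high} to delimit the "
                f"overlapping boundary {mapping.labels[j]}/{mapping.labels[j + 1]}")
        highs[j] = float(low_anchors.max())
        high_rules[j] = "anchor"
        lows[j + 1] = float(high_anchors.min())
        low_rules[j + 1] = "anchor"

    if not bounded_tails:
        lows[0], low_rules[0] = -np.inf, "unbounded"
        highs[-1], high_rules[-1] = np.inf, "unbounded"

    return [
        GsGroup(label=mapping.labels[j], ploidy=mapping.ploidies[j],
                component_index=j, low=lows[j], high=highs[j],
                low_rule=low_rules[j], high_rule=high_rules[j])
        for j in range(k)
    ]


def assign(measurements: pd.DataFrame, groups: list[GsGroup]) -> pd.DataFrame:
    """Assign every measured individual to a group or to ``unassigned``.

    ``measurements`` needs ``sample_id`` and ``genome_size`` columns
    (``population_id`` is carried through if present).  A sample is
    assigned iff its genome size lies in exactly one group interval; the
    ``rationale`` column records which interval test decided it.
    """
    required = {"sample_id", "genome_size"}
    if not required <= set(measurements.columns):
        raise DelimitationError("measurements need sample_id and genome_size columns")
    rows = []
    for row in measurements.itertuples(index=False):
        gs = float(row.genome_size)
        hits = [g for g in groups if g.contains(gs)]
        if len(hits) == 1:
            group, rationale = hits[0].label, (
                f"gs {gs:.3f} in [{hits[0].low:.3f}, {hits[0].high:.3f})")
        elif not hits:
            group, rationale = UNASSIGNED, f"gs {gs:.3f} outside every group interval"
        else:
            labels = "+".join(g.label for g in hits)
            group, rationale = UNASSIGNED, f"gs {gs:.3f} ambiguous between {labels}"
        rows.append({
            "sample_id": row.sample_id,
            "population_id": getattr(row, "population_id", None),
            "group": group,
            "rationale": rationale,
        })
    return pd.DataFrame(rows)


def anchor_conflicts(
    assignments: pd.DataFrame,
    counts: pd.DataFrame,
    groups: list[GsGroup],
) -> pd.DataFrame:
    """Anchored individuals whose assignment contradicts their counted ploidy.

    ``counts`` needs ``sample_id`` and ``two_n``.  Returns the conflicting
    rows (empty frame when calibration and delimitation agree); conflicts
    are reported, never dropped.
    """
    by_label = {g.label: g.ploidy for g in groups}
    merged = assignments.merge(counts[["sample_id", "two_n"]], on="sample_id")
    conflicts = []
    for row in merged.itertuples(index=False):
        counted = ploidy_from_count(int(row.two_n))
        assigned = by_label.get(row.group)
        if assigned is not None and assigned != counted:
            conflicts.append({
                "sample_id": row.sample_id, "group": row.group,
                "assigned_ploidy": assigned, "counted_ploidy": counted,
            })
    out = pd.DataFrame(conflicts,
                       columns=["sample_id", "group", "assigned_ploidy", "counted_ploidy"])
    if len(out):
        logger.warning("%d anchored individuals fall outside their own "
                       "ploidy's group interval", len(out))
    return out


def groups_to_frame(groups: list[GsGroup]) -> pd.DataFrame:
    return pd.DataFrame([
        {"label": g.label, "ploidy": g.ploidy, "component": g.component_index,
         "low": g.low, "high": g.high, "low_rule": g.low_rule, "high_rule": g.high_rule}
        for g in groups
    ])
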