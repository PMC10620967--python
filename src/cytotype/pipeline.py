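"""End-to-end orchestration: events -> measurements -> mixture -> groups -> structure.

Library core behind the command-line interface; every stage's tabular
output is kept on the result object so stages stay independently testable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cytometry import (
    DEFAULT_CV_MAX,
    DEFAULT_REFERENCE_CHANNEL,
    DEFAULT_STANDARD_GS,
    EventSet,
    evaluate_events,
    measurements_to_frame,
    qc_filter,
)
from .delimit import (
    anchor_conflicts,
    assign,
    delimit_groups,
    groups_to_frame,
    map_components_to_ploidy,
)
from .mixture import classify, fit_gmm, responsibilities_to_frame, select_model
from .structure import (
    habitat_association,
    intersection_counts,
    mixed_fractions,
    summaries_to_frame,
    summarize_populations,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the study's stated protocol."""

    cv_max: float = DEFAULT_CV_MAX
    k_candidates: tuple[int, ...] = (8, 9)
    standard_gs: float = DEFAULT_STANDARD_GS
    reference_channel: float = DEFAULT_REFERENCE_CHANNEL
    n_bins: int = 256
    max_iter: int = 1_000_000
    n_restarts: int = 10
    w_min: float = 0.02
    percentiles: tuple[float, float] = (1.0, 99.0)
    n_permutations: int = 10_000
    seed: int = 0


@dataclass
class AnalysisResult:
    """All stage outputs of one pipeline run."""

    measurements: pd.DataFrame
    model_frame: pd.DataFrame
    selection_report: pd.DataFrame
    responsibilities: pd.DataFrame
    groups: pd.DataFrame
    assignments: pd.DataFrame
    conflicts: pd.DataFrame
    summaries: pd.DataFrame
    intersections: pd.DataFrame
    habitat: pd.DataFrame
    report: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "measurements.csv": self.measurements,
            "model.csv": self.model_frame,
            "model_selection.csv": self.selection_report,
            "responsibilities.csv": self.responsibilities,
            "groups.csv": self.groups,
            "assignments.csv": self.assignments,
            "anchor_conflicts.csv": self.conflicts,
            "population_summaries.csv": self.summaries,
            "intersections.csv": self.intersections,
            "habitat_association.csv": self.habitat,
        }
        for name, frame in tables.items():
            frame.to_csv(outdir / name, index=False)
        (outdir / "report.json").write_text(json.dumps(self.report, indent=2))


def evaluate_study(
    events: Mapping[str, EventSet],
    population_of: Mapping[str, str] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Evaluate every analysis of a study into the measurements table."""
    config = config or RunConfig()
    population_of = population_of or {}
    measurements = [
        evaluate_events(
            ev, standard_gs=config.standard_gs,
            reference_channel=config.reference_channel,
            n_bins=config.n_bins, cv_max=config.cv_max,
            population_id=population_of.get(sample_id),
        )
        for sample_id, ev in events.items()
    ]
    return measurements_to_frame(measurements)


def analyze_measurements(
    measurements: pd.DataFrame,
    chromosome_counts: pd.DataFrame,
    populations: pd.DataFrame,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Run QC, mixture fitting, delimitation and population summaries.

    ``measurements`` is the table from :func:`evaluate_study` (or a
    pre-evaluated import); ``chromosome_counts`` has sample_id/two_n;
    ``populations`` has population_id/habitat.
    """
    config = config or RunConfig()
    passed = measurements[
        measurements["qc_pass"] & np.isfinite(measurements["genome_size"])
    ].reset_index(drop=True)
    if len(passed) == 0:
        raise ValueError("no measurement passed the CV filter")
    values = passed["genome_size"].to_numpy()

    candidates = [
        fit_gmm(values, k, max_iter=config.max_iter,
                n_restarts=config.n_restarts, seed=config.seed + k)
        for k in config.k_candidates
    ]
    model, selection_report = select_model(candidates, w_min=config.w_min,
                                           percentiles=config.percentiles)
    resp, labels = classify(model, values)
    responsibilities = responsibilities_to_frame(passed["sample_id"], resp, labels)

    anchors = passed.merge(chromosome_counts, on="sample_id")
    mapping = map_components_to_ploidy(model, anchors["genome_size"],
                                       anchors["two_n"], strict=False)
    groups = delimit_groups(model, mapping, anchors["genome_size"],
                            anchors["two_n"], percentiles=config.percentiles)
    assignments = assign(passed, groups)
    conflicts = anchor_conflicts(assignments, chromosome_counts, groups)

    summaries = summarize_populations(assignments, populations)
    intersections = intersection_counts(summaries)
    habitat = habitat_association(summaries, n_permutations=config.n_permutations,
                                  seed=config.seed)
    fractions = mixed_fractions(summaries)

    report = {
        "n_measured": int(len(measurements)),
        "n_qc_passed": int(len(passed)),
        "k_candidates": list(config.k_candidates),
        "k_chosen": int(model.k),
        "n_groups": len(groups),
        "groups": [g.label for g in groups],
        "n_unassigned": int((assignments["group"] == "unassigned").sum()),
        "n_anchor_conflicts": int(len(conflicts)),
        "mixed_fraction_groups": fractions["group_mixed"],
        "mixed_fraction_ploidy": fractions["ploidy_mixed"],
        "seed": config.seed,
        "cytotype_version": __version__,
    }
    model_frame = model.to_frame()
    model_frame["label"] = list(mapping.labels)
    return AnalysisResult(
        measurements=measurements, model_frame=model_frame,
        selection_report=selection_report, responsibilities=responsibilities,
        groups=groups_to_frame(groups), assignments=assignments,
        conflicts=conflicts, summaries=summaries_to_frame(summaries),
        intersections=intersections, habitat=habitat, report=report,
    )


def run_pipeline(
    events: Mapping[str, EventSet],
    chromosome_counts: pd.DataFrame,
    populations: pd.DataFrame,
    population_of: Mapping[str, str] | None = None,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Full pipeline from raw event sets to population summaries."""
    config = config or RunConfig()
    measurements = evaluate_study(events, population_of, config)
    # re-apply the partition explicitly so the counts are auditable
    qc_filter_counts = measurements["qc_pass"].value_counts().to_dict()
    logger.info("QC partition: %s", qc_filter_counts)
    return analyze_measurements(measurements, chromosome_counts, populations, config)
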