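"""Orchestration of the full 24-model movement-biomarker study.

A study combines six joint sets (the five body parts plus the whole body)
with four stimulus sets (each condition alone plus all three together),
builds the mean-movement feature table for each combination, runs the
joint-level group statistics once on the full table, and LOSO-evaluates the
classification stack per combination. Outputs mirror the study's report
shapes: a 6x4 accuracy matrix, a detail table with accuracy/TPR/TNR/kappa
and the selected/total PCA feature counts, and the joint-comparison grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import ClassifierConfig, EvaluationReport, loso_evaluate
from .features import build_feature_table
from .simulate import CohortConfig, generate_cohort
from .skeleton import (
    BODY_PARTS,
    SEGMENT_LABELS,
    STIMULUS_LABELS,
    SubjectRecording,
    read_pose_stream,
    read_schedule,
    read_subject_table,
)
from .stats import compare_all, comparison_grid

logger = logging.getLogger(__name__)

JOINT_SET_NAMES: tuple[str, ...] = ("head", "trunk", "arms", "legs", "feet", "all")
SEGMENT_SET_NAMES: tuple[str, ...] = ("V", "VA", "VAO", "all")
SEGMENT_SETS: dict[str, tuple[str, ...]] = {
    "V": ("V",),
    "VA": ("VA",),
    "VAO": ("VAO",),
    "all": STIMULUS_LABELS,
}


@dataclass(frozen=True)
class ModelSpec:
    """One joint-set x stimulus-set combination."""

    joint_set: str
    segment_set: str

    def __post_init__(self) -> None:
        if self.joint_set not in JOINT_SET_NAMES:
            raise ValueError(f"unknown joint set {self.joint_set!r}")
        if self.segment_set not in SEGMENT_SET_NAMES:
            raise ValueError(f"unknown segment set {self.segment_set!r}")

    @property
    def segments(self) -> tuple[str, ...]:
        return SEGMENT_SETS[self.segment_set]


def default_model_specs() -> list[ModelSpec]:
    """The standard 24 = 6 joint sets x 4 stimulus sets."""
    return [ModelSpec(j, s) for j in JOINT_SET_NAMES for s in SEGMENT_SET_NAMES]


@dataclass
class StudyManifest:
    """Everything needed to run (and re-run) a study deterministically."""

    cohort: CohortConfig | str | Path
    specs: list[ModelSpec] = field(default_factory=default_model_specs)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    out_dir: str | Path | None = None
    seed: int = 0


@dataclass
class StudyResult:
    accuracy_matrix: pd.DataFrame  # joint sets x stimulus sets, percent
    detail: pd.DataFrame           # one row per model, Table-2-like columns
    comparisons: pd.DataFrame      # joint-level test results on all segments
    comparison_grid: pd.DataFrame
    reports: dict[tuple[str, str], EvaluationReport]


def load_cohort(data_dir: str | Path) -> list[SubjectRecording]:
    """Load a cohort from a directory of pose streams plus manifest/schedule."""
    data_dir = Path(data_dir)
    schedule = read_schedule(data_dir / "schedule.csv")
    table = read_subject_table(data_dir / "manifest.csv")
    return [
        read_pose_stream(data_dir / f"{row.subject_id}.csv", schedule,
                         row.subject_id, row.group)
        for row in table.itertuples()
    ]


def run_study(manifest: StudyManifest) -> StudyResult:
    """Execute the full study and optionally write its report files.

    Per-spec seeds are derived from the manifest seed so each of the 24
    models is reproducible independently of execution order. A failing spec
    aborts the run with the spec named and removes partial outputs.
    """
    if isinstance(manifest.cohort, CohortConfig):
        recordings, _ = generate_cohort(manifest.cohort)
    else:
        recordings = load_cohort(manifest.cohort)

    spec_seeds = {
        spec: int(s.generate_state(1)[0] % (2**31))
        for spec, s in zip(manifest.specs,
                           np.random.SeedSequence(manifest.seed).spawn(len(manifest.specs)))
    }

    full_table = build_feature_table(recordings, "all", SEGMENT_LABELS)
    comparisons = compare_all(full_table)
    grid = comparison_grid(comparisons)

    reports: dict[tuple[str, str], EvaluationReport] = {}
    try:
        for spec in manifest.specs:
            table = build_feature_table(recordings, spec.joint_set, spec.segments)
            config = replace(manifest.classifier, seed=spec_seeds[spec])
            report = loso_evaluate(table, config,
                                   joint_set=spec.joint_set, segment_set=spec.segment_set)
            logger.info(
                "%s x %s: %d features, PCA %d, selected %d, kappa %.2f",
                spec.joint_set, spec.segment_set, table.values.shape[1],
                report.n_pca, report.n_selected, report.metrics.kappa,
            )
            reports[(spec.joint_set, spec.segment_set)] = report
    except Exception as exc:
        raise RuntimeError(
            f"study failed at model joint_set={spec.joint_set!r}, "
            f"segment_set={spec.segment_set!r}: {exc}"
        ) from exc

    detail = pd.DataFrame([r.to_row() for r in reports.values()])
    joint_names = sorted({j for j, _ in reports}, key=JOINT_SET_NAMES.index)
    seg_names = sorted({s for _, s in reports}, key=SEGMENT_SET_NAMES.index)
    matrix = pd.DataFrame(
        [[reports[(j, s)].to_row()["accuracy_pct"] if (j, s) in reports else np.nan
          for s in seg_names] for j in joint_names],
        index=pd.Index(joint_names, name="joint_set"),
        columns=pd.Index(seg_names, name="stimuli"),
    )

    result = StudyResult(matrix, detail, comparisons, grid, reports)
    if manifest.out_dir is not None:
        _write_outputs(manifest, result)
    return result


def _write_outputs(manifest: StudyManifest, result: StudyResult) -> None:
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for name, df, kwargs in (
            ("table1_accuracy.csv", result.accuracy_matrix, {"index": True}),
            ("table2_detail.csv", result.detail, {"index": False}),
            ("fig4_comparisons.csv", result.comparisons, {"index": False}),
        ):
            df.to_csv(out / name, **kwargs)
            written.append(out / name)
        log = {
            "seed": manifest.seed,
            "n_models": len(result.reports),
            "grid": list(manifest.classifier.grid),
            "models": {
                f"{j}|{s}": {
                    "n_pca": r.n_pca,
                    "n_selected": r.n_selected,
                    "grid_cost": r.grid_cost,
                    "grid_gamma": r.grid_gamma,
                    "fold_pairs": [[f.chosen_cost, f.chosen_gamma] for f in r.fold_results],
                }
                for (j, s), r in result.reports.items()
            },
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        written.append(out / "run_log.json")
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
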