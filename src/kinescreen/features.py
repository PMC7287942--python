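"""Mean inter-frame displacement features from segmented 3D joint streams.

For each subject, joint and session segment, the level of movement is
summarised as the mean Euclidean distance between the joint's 3D positions
in consecutive frames, after discarding joint samples whose detection
confidence falls below a threshold (default 0.5). Displacements are only
taken between retained samples at *adjacent original frames*: bridging a
confidence gap would fabricate motion over the gap, so gap pairs simply
contribute no value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .skeleton import (
    CameraModel,
    STIMULUS_LABELS,
    SubjectRecording,
    project_stream,
    resolve_joint_set,
    segment_indices,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 0.5


def filter_low_confidence(
    xyz: np.ndarray,
    confidence: np.ndarray,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    frame_index: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop samples whose confidence is strictly below ``threshold``.

    A sample at exactly the threshold is retained. Returns the retained
    original frame indices and the corresponding 3D samples; a fully
    filtered series yields empty arrays.
    """
    xyz = np.asarray(xyz, dtype=float)
    confidence = np.asarray(confidence, dtype=float)
    if frame_index is None:
        frame_index = np.arange(len(confidence))
    keep = ~(confidence < threshold)
    return np.asarray(frame_index)[keep], xyz[keep]


def joint_displacement_series(frame_index: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Euclidean displacements between retained samples at adjacent frames.

    ``frame_index`` must be sorted. Pairs of retained samples whose original
    frame indices differ by more than one (a confidence gap) produce no
    value; fewer than two usable samples produce an empty series.
    """
    frame_index = np.asarray(frame_index)
    xyz = np.asarray(xyz, dtype=float)
    if len(frame_index) < 2:
        return np.empty(0)
    if np.any(np.diff(frame_index) <= 0):
        raise ValueError("frame_index must be strictly increasing")
    adjacent = np.diff(frame_index) == 1
    diffs = np.diff(xyz, axis=0)[adjacent]
    return np.linalg.norm(diffs, axis=1)


def mean_joint_movement(displacements: np.ndarray) -> float:
    """Arithmetic mean displacement; NaN marks an empty series."""
    displacements = np.asarray(displacements, dtype=float)
    if displacements.size == 0:
        return float("nan")
    return float(displacements.mean())


@dataclass
class FeatureTable:
    """Subjects x (joint, segment) mean-displacement matrix with metadata.

    ``values`` is a DataFrame indexed by subject id whose columns are a
    ``(joint, segment)`` MultiIndex; ``groups`` maps subject id to its class
    label. Cells with no valid displacement pair are NaN until imputed;
    ``n_imputed`` records how many were filled with the column median.
    """

    values: pd.DataFrame
    groups: pd.Series
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    n_imputed: int = 0
    excluded_samples: pd.DataFrame | None = None

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 for ASD (the positive class), 0 for TD."""
        return (self.groups.loc[self.values.index] == "ASD").to_numpy(dtype=int)

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.values.stack([0, 1], future_stack=True).rename("value").reset_index()
        tidy.columns = ["subject_id", "joint", "segment", "value"]
        tidy["group"] = tidy["subject_id"].map(self.groups)
        return tidy[["subject_id", "group", "joint", "segment", "value"]]

    def to_csv(self, path: str | Path, tidy: bool = True) -> None:
        if tidy:
            self.to_tidy().to_csv(path, index=False)
        else:
            wide = self.values.copy()
            wide.columns = [f"j{j}_{s}" for j, s in wide.columns]
            wide.insert(0, "group", self.groups.loc[wide.index])
            wide.to_csv(path, index_label="subject_id")


def subject_segment_features(
    rec: SubjectRecording,
    joints: Sequence[int],
    segments: Sequence[str],
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    camera: CameraModel | None = None,
) -> tuple[dict[tuple[int, str], float], int]:
    """Mean movement per (joint, segment) for one subject.

    Returns the feature dict (NaN where no displacement pair survives
    filtering) and the count of confidence-excluded samples.
    """
    camera = camera or CameraModel()
    xyz_c = project_stream(rec, camera)  # (n, 25, 4)
    idx_by_label, _ = segment_indices(rec)
    feats: dict[tuple[int, str], float] = {}
    n_excluded = 0
    for label in segments:
        idx = idx_by_label.get(label, np.empty(0, dtype=int))
        for j in joints:
            ret_idx, ret_xyz = filter_low_confidence(
                xyz_c[idx, j, :3], xyz_c[idx, j, 3], threshold, frame_index=idx
            )
            n_excluded += len(idx) - len(ret_idx)
            d = joint_displacement_series(ret_idx, ret_xyz)
            feats[(j, label)] = mean_joint_movement(d)
    return feats, n_excluded


def build_feature_table(
    recordings: Iterable[SubjectRecording],
    joint_set: str | Sequence[int] = "all",
    segment_set: Sequence[str] = STIMULUS_LABELS,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    camera: CameraModel | None = None,
    impute: bool = True,
    include_nose: bool = False,
) -> FeatureTable:
    """Assemble the subjects x (joint, segment) feature matrix.

    ``joint_set`` is a body-part name (``head``/``trunk``/``arms``/``legs``/
    ``feet``/``all``) or an explicit joint list; ``segment_set`` defaults to
    the three stimulus conditions. Missing cells (no valid displacement
    pair) are imputed with the column median when ``impute`` is set; a
    column missing for every subject raises an error naming it.
    """
    joints = resolve_joint_set(joint_set, include_nose=include_nose)
    segments = tuple(segment_set)
    rows, groups, excluded = {}, {}, {}
    for rec in recordings:
        feats, n_exc = subject_segment_features(rec, joints, segments, threshold, camera)
        rows[rec.subject_id] = feats
        groups[rec.subject_id] = rec.group
        excluded[rec.subject_id] = n_exc
    columns = pd.MultiIndex.from_tuples(
        [(j, s) for j in joints for s in segments], names=["joint", "segment"]
    )
    values = pd.DataFrame.from_dict(rows, orient="index")[list(columns)]
    values.columns = columns
    values.index.name = "subject_id"

    n_imputed = 0
    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        j, s = all_missing[0]
        raise ValueError(f"feature column joint={j}, segment={s!r} is missing for all subjects")
    if impute:
        n_imputed = int(values.isna().to_numpy().sum())
        if n_imputed:
            logger.info("imputing %d missing feature cells with column medians", n_imputed)
            values = values.fillna(values.median(axis=0))
    return FeatureTable(
        values=values,
        groups=pd.Series(groups, name="group"),
        confidence_threshold=threshold,
        n_imputed=n_imputed,
        excluded_samples=pd.DataFrame({"n_excluded": pd.Series(excluded)}),
    )
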