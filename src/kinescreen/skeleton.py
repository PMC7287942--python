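"""Canonical data model and I/O for 25-joint RGB-D pose streams.

The data model mirrors what a BODY_25-style pose estimator emits on RGB-D
video: per frame, 25 joints with image coordinates ``(u, v)`` in pixels, a
depth ``z`` in meters and a detection confidence ``c`` in ``[0, 1]``.
Recordings carry a segment schedule labelling the baseline and stimulus
intervals of the 14-minute session (``BL_V, V, BL_VA, VA, BL_VAO, VAO``).

Units are canonical throughout the package: meters for depth/3D coordinates,
seconds for timestamps. Conversion happens at the I/O boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_JOINTS = 25

#: Body-part partition used by the analysis. The nose (joint 0) belongs to
#: no analysis group by default; pass ``include_nose=True`` where supported
#: to add it to the head set.
BODY_PARTS: Mapping[str, tuple[int, ...]] = {
    "head": (15, 16, 17, 18),
    "trunk": (1, 8),
    "arms": (2, 3, 4, 5, 6, 7),
    "legs": (9, 10, 11, 12, 13, 14),
    "feet": (19, 20, 21, 22, 23, 24),
}

#: All joints that take part in the analysis (nose excluded).
ANALYSIS_JOINTS: tuple[int, ...] = tuple(
    sorted(j for joints in BODY_PARTS.values() for j in joints)
)

STIMULUS_LABELS: tuple[str, ...] = ("V", "VA", "VAO")
BASELINE_LABELS: tuple[str, ...] = ("BL_V", "BL_VA", "BL_VAO")
SEGMENT_LABELS: tuple[str, ...] = ("BL_V", "V", "BL_VA", "VA", "BL_VAO", "VAO")

GROUPS: tuple[str, str] = ("ASD", "TD")


class PoseStreamFormatError(ValueError):
    """Raised when a pose-stream file does not follow the expected schema."""


class PoseStreamValidationError(ValueError):
    """Raised when parsed pose data violates a model invariant."""


def resolve_joint_set(joint_set: str | Iterable[int], include_nose: bool = False) -> tuple[int, ...]:
    """Resolve a body-part name or explicit joint iterable to joint indices.

    ``"all"`` maps to every analysis joint; a body-part name maps to its
    partition entry. ``include_nose`` adds joint 0 to ``"head"`` and ``"all"``.
    """
    if isinstance(joint_set, str):
        if joint_set == "all":
            joints = ANALYSIS_JOINTS
        elif joint_set in BODY_PARTS:
            joints = BODY_PARTS[joint_set]
        else:
            raise KeyError(f"unknown joint set {joint_set!r}")
        if include_nose and joint_set in ("all", "head"):
            joints = (0,) + tuple(joints)
        return tuple(joints)
    joints = tuple(int(j) for j in joint_set)
    for j in joints:
        if not 0 <= j < N_JOINTS:
            raise ValueError(f"joint index {j} outside [0, {N_JOINTS - 1}]")
    return joints


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics used to move between image+depth and 3D space.

    Defaults are plausible for an 848x480 RGB-D sensor and only matter for
    keeping synthetic geometry self-consistent; the movement features are
    computed in 3D and do not depend on the particular intrinsics used to
    round-trip them.
    """

    fx: float = 600.0
    fy: float = 600.0
    cx: float = 424.0
    cy: float = 240.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


@dataclass(frozen=True)
class Segment:
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not self.end > self.start:
            raise ValueError(f"segment {self.label}: end must exceed start")


@dataclass(frozen=True)
class SegmentSchedule:
    """Ordered, non-overlapping session segments.

    The default schedule alternates a 120 s baseline with a 160 s stimulus
    for each of the three conditions (total 840 s = 14 min). Frames are
    assigned to segments by the half-open convention ``[start, end)``.
    """

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for seg in self.segments:
            if seg.start < prev_end:
                raise ValueError("segments must be ordered and non-overlapping")
            prev_end = seg.end

    @classmethod
    def default(cls, duration_factor: float = 1.0) -> "SegmentSchedule":
        """Build the standard session schedule, optionally time-scaled.

        ``duration_factor`` scales every interval (0.1 gives an 84 s session
        with the same structure), which keeps synthetic cohorts cheap while
        preserving the segment proportions.
        """
        if duration_factor <= 0:
            raise ValueError("duration_factor must be positive")
        base, stim = 120.0 * duration_factor, 160.0 * duration_factor
        t, segs = 0.0, []
        for cond in STIMULUS_LABELS:
            segs.append(Segment(f"BL_{cond}", t, t + base))
            t += base
            segs.append(Segment(cond, t, t + stim))
            t += stim
        return cls(tuple(segs))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(seg.label for seg in self.segments)

    @property
    def span(self) -> tuple[float, float]:
        return self.segments[0].start, self.segments[-1].end

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.label, s.start, s.end) for s in self.segments],
            columns=["label", "start", "end"],
        )


@dataclass(frozen=True)
class SkeletonFrame:
    """One time point: 25 joints of ``(u, v, z, c)``."""

    timestamp: float
    joints: np.ndarray  # shape (25, 4): u, v, z, c

    def __post_init__(self) -> None:
        arr = np.asarray(self.joints, dtype=float)
        if arr.shape != (N_JOINTS, 4):
            raise PoseStreamValidationError(
                f"expected {N_JOINTS} joint records of (u, v, z, c), got shape {arr.shape}"
            )
        if self.timestamp < 0:
            raise PoseStreamValidationError("timestamp must be non-negative")
        if np.any(arr[:, 3] < 0) or np.any(arr[:, 3] > 1):
            raise PoseStreamValidationError("confidence must lie in [0, 1]")
        if np.any(arr[:, 2] < 0):
            raise PoseStreamValidationError("depth must be non-negative")
        object.__setattr__(self, "joints", arr)


@dataclass
class SubjectRecording:
    """A subject's validated frame stream plus schedule and group label.

    Frames are stored columnar for speed: ``timestamps`` with shape ``(n,)``
    and ``joints`` with shape ``(n, 25, 4)`` holding ``(u, v, z, c)``.
    """

    subject_id: str
    group: str
    timestamps: np.ndarray
    joints: np.ndarray
    schedule: SegmentSchedule

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.joints = np.asarray(self.joints, dtype=float)
        if self.group not in GROUPS:
            raise PoseStreamValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.joints.ndim != 3 or self.joints.shape[1:] != (N_JOINTS, 4):
            raise PoseStreamValidationError(
                f"joints must have shape (n, {N_JOINTS}, 4), got {self.joints.shape}"
            )
        if len(self.timestamps) != len(self.joints):
            raise PoseStreamValidationError("timestamps and joints disagree in length")
        if len(self.timestamps) == 0:
            raise PoseStreamValidationError("recording contains no frames")
        if np.any(np.diff(self.timestamps) <= 0):
            raise PoseStreamValidationError("timestamps must be strictly increasing")
        c = self.joints[:, :, 3]
        if np.any(c < 0) or np.any(c > 1):
            raise PoseStreamValidationError("confidence must lie in [0, 1]")
        if np.any(self.joints[:, :, 2] < 0):
            raise PoseStreamValidationError("depth must be non-negative")
        lo, hi = self.schedule.span
        if self.timestamps[0] < lo or self.timestamps[-1] > hi:
            raise PoseStreamValidationError("frame timestamps fall outside the schedule span")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(float(self.timestamps[i]), self.joints[i])


# ---------------------------------------------------------------------------
# Projection


def project_to_3d(frame: SkeletonFrame | np.ndarray, cam: CameraModel) -> np.ndarray:
    """Back-project one frame's joints to 3D camera coordinates.

    Pinhole model: ``X = (u - cx) z / fx``, ``Y = (v - cy) z / fy``,
    ``Z = z``. A joint with zero depth maps to the origin regardless of its
    image position. Returns an array of shape ``(25, 4)``: ``(X, Y, Z, c)``
    with confidence carried through unchanged.
    """
    arr = frame.joints if isinstance(frame, SkeletonFrame) else np.asarray(frame, dtype=float)
    if np.any(arr[..., 2] < 0):
        raise PoseStreamValidationError("depth must be non-negative")
    z = arr[..., 2]
    out = np.empty_like(arr)
    out[..., 0] = (arr[..., 0] - cam.cx) * z / cam.fx
    out[..., 1] = (arr[..., 1] - cam.cy) * z / cam.fy
    out[..., 2] = z
    out[..., 3] = arr[..., 3]
    return out


def project_stream(rec: SubjectRecording, cam: CameraModel) -> np.ndarray:
    """Back-project every frame of a recording; shape ``(n, 25, 4)``."""
    return project_to_3d(rec.joints, cam)


def forward_project(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Project 3D points ``(..., 3)`` to ``(u, v, z)`` rows ``(..., 3)``."""
    pts = np.asarray(points, dtype=float)
    z = pts[..., 2]
    if np.any(z <= 0):
        raise ValueError("forward projection requires strictly positive depth")
    out = np.empty_like(pts)
    out[..., 0] = pts[..., 0] * cam.fx / z + cam.cx
    out[..., 1] = pts[..., 1] * cam.fy / z + cam.cy
    out[..., 2] = z
    return out


# ---------------------------------------------------------------------------
# Segmentation


def segment_indices(rec: SubjectRecording) -> tuple[dict[str, np.ndarray], int]:
    """Assign frames to schedule segments by ``[start, end)``.

    Returns ``(indices_by_label, n_dropped)`` where each value is the array
    of frame indices falling inside that segment. Frames outside every
    segment are dropped and counted.
    """
    t = rec.timestamps
    assigned = np.zeros(len(t), dtype=bool)
    out: dict[str, np.ndarray] = {}
    for seg in rec.schedule.segments:
        mask = (t >= seg.start) & (t < seg.end) & ~assigned
        out[seg.label] = np.flatnonzero(mask)
        assigned |= mask
    n_dropped = int((~assigned).sum())
    if n_dropped:
        logger.info("%s: dropped %d frames outside all segments", rec.subject_id, n_dropped)
    for label, idx in out.items():
        if len(idx) == 0:
            logger.info("%s: segment %s contains no frames", rec.subject_id, label)
    return out, n_dropped


def segment_recording(rec: SubjectRecording) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Split a recording into per-segment sub-streams.

    Returns a map ``label -> (frame_index, timestamps, joints)`` where
    ``frame_index`` holds the original positions of the retained frames
    (needed downstream to decide frame adjacency across confidence gaps).
    """
    idx_by_label, _ = segment_indices(rec)
    return {
        label: (idx, rec.timestamps[idx], rec.joints[idx])
        for label, idx in idx_by_label.items()
    }


# ---------------------------------------------------------------------------
# File I/O

_CSV_COLUMNS = ["t"] + [f"j{j}_{f}" for j in range(N_JOINTS) for f in ("u", "v", "z", "c")]


def write_pose_stream(rec: SubjectRecording, path: str | Path, fmt: str = "csv") -> None:
    """Write a recording as flat CSV (default) or JSON-lines.

    One row per frame with columns ``t, j0_u, j0_v, j0_z, j0_c, ..., j24_c``.
    Floats use the shortest round-trip representation so a read-back is
    bit-identical.
    """
    path = Path(path)
    flat = np.column_stack([rec.timestamps, rec.joints.reshape(rec.n_frames, -1)])
    if fmt == "csv":
        # %.17g round-trips float64 exactly
        pd.DataFrame(flat, columns=_CSV_COLUMNS).to_csv(path, index=False, float_format="%.17g")
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for row in flat:
                fh.write(json.dumps(dict(zip(_CSV_COLUMNS, row.tolist()))) + "\n")
    else:
        raise ValueError(f"unknown pose-stream format {fmt!r}")


def read_pose_stream(
    path: str | Path,
    schedule: SegmentSchedule,
    subject_id: str,
    group: str,
    fmt: str | None = None,
) -> SubjectRecording:
    """Read and validate a pose-stream file into a :class:`SubjectRecording`.

    The dialect is inferred from the suffix unless ``fmt`` is given. Frames
    are sorted by timestamp; schema violations raise
    :class:`PoseStreamFormatError`, invariant violations raise
    :class:`PoseStreamValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in (".jsonl", ".ndjson") else "csv"
    if fmt == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError as exc:
            raise PoseStreamFormatError(f"{path}: empty pose-stream file") from exc
    elif fmt == "jsonl":
        rows = []
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        if not rows:
            raise PoseStreamFormatError(f"{path}: empty pose-stream file")
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown pose-stream format {fmt!r}")

    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise PoseStreamFormatError(
            f"{path}: missing joint columns (first missing: {missing[0]!r})"
        )
    if df.empty:
        raise PoseStreamFormatError(f"{path}: file contains no frames")
    df = df[_CSV_COLUMNS]
    if df.isna().any().any():
        raise PoseStreamFormatError(f"{path}: malformed rows with missing values")
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise PoseStreamValidationError(f"{path}: duplicate timestamps after sorting")
    return SubjectRecording(
        subject_id=subject_id,
        group=group,
        timestamps=arr[:, 0],
        joints=arr[:, 1:].reshape(-1, N_JOINTS, 4),
        schedule=schedule,
    )


def read_schedule(path: str | Path) -> SegmentSchedule:
    """Read a segment schedule from CSV with columns ``label,start,end``."""
    df = pd.read_csv(path)
    return SegmentSchedule(
        tuple(Segment(str(r.label), float(r.start), float(r.end)) for r in df.itertuples())
    )


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a subject table CSV with at least ``subject_id`` and ``group``."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise PoseStreamFormatError(f"{path}: subject table lacks column {col!r}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise PoseStreamValidationError(f"{path}: unknown group labels {sorted(bad)}")
    return df
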