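"""Synthetic two-group motion cohorts with controllable per-joint effects.

The generator emulates the statistical structure the downstream analysis
consumes — per-joint 3D trajectories observed through a depth camera, with
detection-confidence dropout and a labelled session schedule — without
attempting biomechanical realism. Each joint follows an anchored Gaussian
random walk whose per-axis step SD is ``base_step_sd`` multiplied by a
group/joint/segment-specific factor ``lam``; the mean inter-frame 3D
displacement of such a walk has the closed form ``sigma * 2 * sqrt(2/pi)``
(the mean of a chi distribution with 3 degrees of freedom), which makes
every downstream stage checkable analytically.

Movement-elevation effects are expressed as ``lam > 1`` entries for the ASD
group in an ``effect_map`` keyed by ``(joint, segment_label)``; ``lam = 1``
everywhere yields an exchangeable null cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .skeleton import (
    BODY_PARTS,
    CameraModel,
    N_JOINTS,
    STIMULUS_LABELS,
    SegmentSchedule,
    SubjectRecording,
    forward_project,
    write_pose_stream,
)

#: Mean of the chi distribution with 3 degrees of freedom for unit per-axis
#: SD: E|N(0, I_3)| = 2 * sqrt(2/pi).
CHI3_MEAN = float(2.0 * np.sqrt(2.0 / np.pi))

# Rough standing-child joint anchors (meters, camera frame, ~2 m from the
# sensor). Only the geometry's plausibility matters, not its accuracy.
_ANCHOR_Y = np.array([
    -0.60, -0.50, 0.0, -0.30, -0.10, -0.50, -0.30, -0.10, 0.10,  # 0-8
    0.10, 0.40, 0.70, 0.10, 0.40, 0.70,                          # legs 9-14
    -0.65, -0.65, -0.62, -0.62,                                  # head 15-18
    0.78, 0.78, 0.75, 0.78, 0.78, 0.75,                          # feet 19-24
])
_ANCHOR_X = np.array([
    0.0, 0.0, -0.15, -0.20, -0.22, 0.15, 0.20, 0.22, 0.0,
    -0.08, -0.08, -0.08, 0.08, 0.08, 0.08,
    -0.03, 0.03, -0.07, 0.07,
    -0.09, -0.12, -0.08, 0.09, 0.12, 0.08,
])


def default_anchors(depth: float = 2.0) -> np.ndarray:
    """Per-joint 3D anchor positions, shape ``(25, 3)``."""
    return np.column_stack([_ANCHOR_X, _ANCHOR_Y, np.full(N_JOINTS, depth)])


def paper_like_effects(
    head: float = 3.0,
    legs: float = 1.5,
    trunk: float = 1.3,
    baseline_head_drop: float = 0.7,
) -> dict[tuple[int, str], float]:
    """Qualitative two-group effect preset.

    Encodes the direction of the group differences the joint-level analysis
    is meant to detect: elevated head movement in every stimulus condition,
    elevated leg movement mostly under the visual stimulus, a mild trunk
    elevation under the visual stimulus, and one head joint moving *less* in
    the ASD group during two baselines. Magnitudes are a design choice (no
    calibration target exists), picked so the head effect is strong and the
    others moderate.
    """
    effects: dict[tuple[int, str], float] = {}
    for cond in STIMULUS_LABELS:
        for j in BODY_PARTS["head"]:
            effects[(j, cond)] = head
    for j in (9, 10, 11, 14):
        effects[(j, "V")] = legs
    effects[(10, "VA")] = legs
    effects[(1, "V")] = trunk
    for bl in ("BL_V", "BL_VAO"):
        effects[(16, bl)] = baseline_head_drop
    return effects


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the effective two-group design: 22 ASD and 25 TD
    subjects, a 30 Hz camera, the standard alternating baseline/stimulus
    schedule, and a 3 mm per-axis per-frame resting step SD. ``effect_map``
    multiplies the ASD group's step SD per ``(joint, segment)``;
    ``body_sway_sd`` optionally adds a whole-body random-walk component
    shared by all joints, and ``subject_sd`` an optional log-normal
    between-subject movement multiplier (mean 1). Both default to 0 so the
    per-recording displacement closed form stays exact.
    """

    n_asd: int = 22
    n_td: int = 25
    frame_rate: float = 30.0
    duration_factor: float = 1.0
    base_step_sd: float = 0.003
    effect_map: Mapping[tuple[int, str], float] = field(default_factory=dict)
    body_sway_sd: float = 0.0
    subject_sd: float = 0.0
    confidence_mean: float = 0.9
    p_drop: float = 0.05
    anchor_depth: float = 2.0
    camera: CameraModel = field(default_factory=CameraModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 1 or self.n_td < 1:
            raise ValueError("group sizes must be at least 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0.0 <= self.p_drop <= 1.0:
            raise ValueError("p_drop must lie in [0, 1]")
        if not 0.0 < self.confidence_mean <= 1.0:
            raise ValueError("confidence_mean must lie in (0, 1]")
        if any(lam < 0 for lam in self.effect_map.values()):
            raise ValueError("effect factors must be non-negative")

    @property
    def schedule(self) -> SegmentSchedule:
        return SegmentSchedule.default(self.duration_factor)


def _step_sd_per_frame(config: CohortConfig, group: str, timestamps: np.ndarray) -> np.ndarray:
    """Per-frame, per-joint step SD array of shape ``(n_frames, 25)``."""
    sd = np.full((len(timestamps), N_JOINTS), config.base_step_sd, dtype=float)
    if group != "ASD" or not config.effect_map:
        return sd
    for seg in config.schedule.segments:
        in_seg = (timestamps >= seg.start) & (timestamps < seg.end)
        if not in_seg.any():
            continue
        for (joint, label), lam in config.effect_map.items():
            if label == seg.label:
                sd[in_seg, joint] *= lam
    return sd


def generate_recording(
    config: CohortConfig,
    subject_id: str,
    group: str,
    seed: int | np.random.SeedSequence | None = None,
) -> SubjectRecording:
    """Simulate one subject's pose stream.

    Joints follow ``position(t+1) = position(t) + eps`` with isotropic
    Gaussian ``eps`` whose per-axis SD is ``base_step_sd * lam(group, joint,
    segment)``; 3D positions are observed through the camera's forward
    projection as ``(u, v, z)`` rows; confidence is drawn high
    (uniform around ``confidence_mean``) with probability ``1 - p_drop`` and
    as a dropout (uniform on ``[0, 0.5)``) otherwise. Deterministic given
    ``seed`` (falls back to ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    schedule = config.schedule
    lo, hi = schedule.span
    dt = 1.0 / config.frame_rate
    timestamps = np.arange(lo, hi - 1e-9, dt)
    n = len(timestamps)

    sd = _step_sd_per_frame(config, group, timestamps)  # (n, 25)
    if config.subject_sd > 0:
        s = config.subject_sd
        sd = sd * rng.lognormal(mean=-0.5 * s**2, sigma=s)
    steps = rng.standard_normal((n, N_JOINTS, 3)) * sd[:, :, None]
    steps[0] = 0.0  # anchor the walk at the start pose
    positions = default_anchors(config.anchor_depth)[None, :, :] + np.cumsum(steps, axis=0)
    if config.body_sway_sd > 0:
        sway = np.cumsum(rng.standard_normal((n, 3)) * config.body_sway_sd, axis=0)
        sway[0] = 0.0
        positions = positions + sway[:, None, :]
    # Keep depth in front of the camera by reflecting the walk at a floor;
    # reflection preserves step lengths except at (rare) boundary crossings.
    z_min = 0.2
    positions[:, :, 2] = z_min + np.abs(positions[:, :, 2] - z_min)

    uvz = forward_project(positions, config.camera)
    half = min(config.confidence_mean, 1.0 - config.confidence_mean, 0.1)
    conf_hi = rng.uniform(config.confidence_mean - half, config.confidence_mean + half, (n, N_JOINTS))
    conf_lo = rng.uniform(0.0, 0.5, (n, N_JOINTS))
    dropped = rng.uniform(size=(n, N_JOINTS)) < config.p_drop
    conf = np.where(dropped, conf_lo, conf_hi)

    joints = np.concatenate([uvz, conf[:, :, None]], axis=2)
    return SubjectRecording(
        subject_id=subject_id,
        group=group,
        timestamps=timestamps,
        joints=joints,
        schedule=schedule,
    )


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[SubjectRecording], pd.DataFrame]:
    """Simulate the full two-group cohort.

    Per-subject sub-seeds are spawned deterministically from ``config.seed``
    so the cohort is reproducible as a whole and per subject. When
    ``out_dir`` is given, one pose-stream CSV per subject plus a
    ``manifest.csv`` (subject_id, group, seed) are written there.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_asd + config.n_td)
    labels = [("ASD", i + 1) for i in range(config.n_asd)] + [
        ("TD", i + 1) for i in range((config.n_td))
    ]
    recordings, rows = [], []
    for child, (group, k) in zip(children, labels):
        subject_id = f"{group}{k:02d}"
        rec = generate_recording(config, subject_id, group, seed=child)
        recordings.append(rec)
        rows.append({"subject_id": subject_id, "group": group,
                     "seed": int(child.generate_state(1)[0] % (2**31))})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_pose_stream(rec, out_dir / f"{rec.subject_id}.csv")
        table.to_csv(out_dir / "manifest.csv", index=False)
        config.schedule.to_frame().to_csv(out_dir / "schedule.csv", index=False)
    return recordings, table
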