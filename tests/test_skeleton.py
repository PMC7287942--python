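"""Pose-stream data model, I/O round trips, projection and segmentation."""

from __future__ import annotations

import numpy as np
import pytest

from kinescreen.skeleton import (
    ANALYSIS_JOINTS,
    BODY_PARTS,
    CameraModel,
    N_JOINTS,
    PoseStreamFormatError,
    PoseStreamValidationError,
    SegmentSchedule,
    SkeletonFrame,
    SubjectRecording,
    forward_project,
    project_to_3d,
    read_pose_stream,
    resolve_joint_set,
    segment_indices,
    segment_recording,
    write_pose_stream,
)


def _recording(n=5, dt=1.0, schedule=None, seed=0):
    rng = np.random.default_rng(seed)
    schedule = schedule or SegmentSchedule.default()
    joints = np.empty((n, N_JOINTS, 4))
    joints[..., 0] = rng.uniform(0, 848, (n, N_JOINTS))
    joints[..., 1] = rng.uniform(0, 480, (n, N_JOINTS))
    joints[..., 2] = rng.uniform(0.5, 3.0, (n, N_JOINTS))
    joints[..., 3] = rng.uniform(0, 1, (n, N_JOINTS))
    return SubjectRecording("S01", "TD", np.arange(n) * dt, joints, schedule)


class TestBodyPartition:
    def test_analysis_partition_is_disjoint_and_covers_24_joints(self):
        all_joints = [j for part in BODY_PARTS.values() for j in part]
        assert len(all_joints) == len(set(all_joints)) == 24
        assert 0 not in all_joints  # nose excluded from the analysis sets
        assert BODY_PARTS["head"] == (15, 16, 17, 18)
        assert BODY_PARTS["trunk"] == (1, 8)

    def test_resolve_joint_set_names_and_nose_option(self):
        assert resolve_joint_set("all") == ANALYSIS_JOINTS
        assert resolve_joint_set("legs") == (9, 10, 11, 12, 13, 14)
        assert 0 in resolve_joint_set("head", include_nose=True)
        assert resolve_joint_set([3, 1, 2]) == (3, 1, 2)
        with pytest.raises(KeyError):
            resolve_joint_set("torso")
        with pytest.raises(ValueError):
            resolve_joint_set([25])


class TestSchedule:
    def test_default_schedule_structure(self):
        sched = SegmentSchedule.default()
        assert sched.labels == ("BL_V", "V", "BL_VA", "VA", "BL_VAO", "VAO")
        assert sched.span == (0.0, 840.0)
        durations = [s.end - s.start for s in sched.segments]
        assert durations == [120.0, 160.0] * 3

    def test_duration_factor_scales_every_interval(self):
        sched = SegmentSchedule.default(0.1)
        assert sched.span == (0.0, pytest.approx(84.0))

    def test_invalid_frames_rejected(self):
        with pytest.raises(PoseStreamValidationError):
            SkeletonFrame(0.0, np.zeros((24, 4)))
        bad_conf = np.zeros((25, 4))
        bad_conf[3, 3] = 1.5
        with pytest.raises(PoseStreamValidationError):
            SkeletonFrame(0.0, bad_conf)


class TestProjection:
    cam = CameraModel(fx=600, fy=600, cx=424, cy=240)

    @pytest.mark.parametrize(
        "uvz, expected",
        [
            ((424.0, 240.0, 2.0), (0.0, 0.0, 2.0)),   # principal-point ray
            ((999.0, 7.0, 0.0), (0.0, 0.0, 0.0)),     # zero depth degenerates
            ((424.0 + 600.0, 240.0, 1.5), (1.5, 0.0, 1.5)),
        ],
    )
    def test_pinhole_back_projection(self, uvz, expected):
        joints = np.zeros((N_JOINTS, 4))
        joints[:, :3] = uvz
        joints[:, 3] = 0.8
        out = project_to_3d(SkeletonFrame(0.0, joints), self.cam)
        np.testing.assert_allclose(out[0, :3], expected, atol=1e-12)
        assert out[0, 3] == 0.8  # confidence carried through

    def test_projection_linear_in_depth(self, rng):
        joints = np.zeros((N_JOINTS, 4))
        joints[:, 0] = rng.uniform(0, 848, N_JOINTS)
        joints[:, 1] = rng.uniform(0, 480, N_JOINTS)
        joints[:, 2] = 1.3
        one = project_to_3d(joints, self.cam)
        joints2 = joints.copy()
        joints2[:, 2] *= 3.0
        three = project_to_3d(joints2, self.cam)
        np.testing.assert_allclose(three[:, :3], 3.0 * one[:, :3], rtol=1e-12)

    def test_negative_depth_rejected(self):
        joints = np.zeros((N_JOINTS, 4))
        joints[1, 2] = -0.1
        with pytest.raises(PoseStreamValidationError):
            project_to_3d(joints, self.cam)

    def test_forward_projection_inverts_back_projection(self, rng):
        pts = np.column_stack([
            rng.normal(0, 0.5, 30), rng.normal(0, 0.5, 30), rng.uniform(1, 3, 30)
        ])
        uvz = forward_project(pts, self.cam)
        frame = np.concatenate([uvz, np.full((30, 1), 0.9)], axis=1)
        # project_to_3d works on any (..., 4) array
        back = project_to_3d(frame, self.cam)
        np.testing.assert_allclose(back[:, :3], pts, rtol=1e-10)


class TestSegmentation:
    def test_half_open_interval_assignment(self):
        sched = SegmentSchedule.default()
        # V spans [120, 280): a frame at 120 is in V, a frame at 280 is not
        rec = _recording(n=3, dt=1.0)
        rec.timestamps = np.array([119.9, 120.0, 280.0])
        segs = segment_recording(rec)
        assert 1 in segs["V"][0] and 0 not in segs["V"][0]
        assert 2 not in segs["V"][0] and 2 in segs["BL_VA"][0]

    def test_uniform_stream_yields_schedule_proportions(self):
        rec = _recording(n=840, dt=1.0)
        segs = segment_recording(rec)
        counts = [len(segs[lab][0]) for lab in rec.schedule.labels]
        assert counts == [120, 160, 120, 160, 120, 160]

    def test_segmentation_partitions_retained_frames(self):
        # a schedule with a gap: frames in the gap are dropped and counted
        from kinescreen.skeleton import Segment

        sched = SegmentSchedule((Segment("BL_V", 0.0, 2.0), Segment("V", 3.0, 5.0)))
        rec = _recording(n=5, schedule=sched)
        rec.timestamps = np.array([0.0, 1.0, 2.5, 3.0, 4.5])
        idx, dropped = segment_indices(rec)
        assert sum(len(v) for v in idx.values()) + dropped == rec.n_frames
        assert dropped == 1  # t=2.5 lies between the segments


class TestPoseStreamIO:
    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_round_trip_is_identity(self, tmp_path, fmt):
        rec = _recording(n=7, seed=3)
        path = tmp_path / f"s01.{fmt}"
        write_pose_stream(rec, path, fmt=fmt)
        back = read_pose_stream(path, rec.schedule, "S01", "TD", fmt=fmt)
        np.testing.assert_array_equal(back.timestamps, rec.timestamps)
        np.testing.assert_array_equal(back.joints, rec.joints)

    def test_read_sorts_frames_by_timestamp(self, tmp_path):
        rec = _recording(n=6)
        path = tmp_path / "s.csv"
        write_pose_stream(rec, path)
        lines = path.read_text().splitlines()
        shuffled = [lines[0]] + [lines[i] for i in (3, 1, 6, 2, 5, 4)]
        path.write_text("\n".join(shuffled) + "\n")
        back = read_pose_stream(path, rec.schedule, "S01", "TD")
        np.testing.assert_array_equal(back.joints, rec.joints)

    def test_missing_joint_columns_is_format_error(self, tmp_path):
        rec = _recording(n=2)
        path = tmp_path / "bad.csv"
        write_pose_stream(rec, path)
        lines = path.read_text().splitlines()
        # drop the last joint's 4 columns -> only 24 complete joints
        header = ",".join(lines[0].split(",")[:-4])
        rows = [",".join(l.split(",")[:-4]) for l in lines[1:]]
        path.write_text("\n".join([header] + rows) + "\n")
        with pytest.raises(PoseStreamFormatError, match="j24"):
            read_pose_stream(path, rec.schedule, "S01", "TD")

    def test_duplicate_timestamps_are_a_validation_error(self, tmp_path):
        rec = _recording(n=3)
        rec_dup = _recording(n=3)
        path = tmp_path / "dup.csv"
        write_pose_stream(rec, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join([lines[0], lines[1], lines[1], lines[2]]) + "\n")
        with pytest.raises(PoseStreamValidationError):
            read_pose_stream(path, rec_dup.schedule, "S01", "TD")

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(PoseStreamFormatError):
            read_pose_stream(path, SegmentSchedule.default(), "S01", "TD")

    def test_unknown_group_label_rejected(self):
        with pytest.raises(PoseStreamValidationError):
            SubjectRecording("S01", "XX", np.array([0.0]),
                             np.zeros((1, N_JOINTS, 4)), SegmentSchedule.default())
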