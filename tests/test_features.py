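"""Confidence filtering, displacement series and feature-table assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import kinescreen as ks
from kinescreen.features import (
    FeatureTable,
    build_feature_table,
    filter_low_confidence,
    joint_displacement_series,
    mean_joint_movement,
)


class TestConfidenceFilter:
    def test_high_confidence_passes_through(self):
        xyz = np.arange(9.0).reshape(3, 3)
        idx, kept = filter_low_confidence(xyz, np.array([0.9, 0.9, 0.9]))
        np.testing.assert_array_equal(idx, [0, 1, 2])
        np.testing.assert_array_equal(kept, xyz)

    def test_below_threshold_removed_with_indices_kept(self):
        xyz = np.zeros((3, 3))
        idx, _ = filter_low_confidence(xyz, np.array([0.9, 0.4, 0.9]))
        np.testing.assert_array_equal(idx, [0, 2])

    def test_exactly_at_threshold_is_retained(self):
        # the exclusion rule is strictly "below" the threshold
        idx, _ = filter_low_confidence(np.zeros((1, 3)), np.array([0.5]))
        np.testing.assert_array_equal(idx, [0])

    @given(st.integers(1, 30), st.floats(0.1, 0.9), st.floats(0.1, 0.9))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_raising_threshold_never_adds_displacements(self, n, t1, t2):
        rng = np.random.default_rng(n)
        xyz = rng.standard_normal((n, 3))
        c = rng.uniform(0, 1, n)
        lo, hi = sorted([t1, t2])
        d_lo = joint_displacement_series(*filter_low_confidence(xyz, c, lo))
        d_hi = joint_displacement_series(*filter_low_confidence(xyz, c, hi))
        assert len(d_hi) <= len(d_lo)


class TestDisplacementSeries:
    def test_stationary_joint_gives_zero_displacements(self):
        d = joint_displacement_series(np.arange(5), np.ones((5, 3)))
        np.testing.assert_array_equal(d, np.zeros(4))

    def test_euclidean_distance_between_adjacent_frames(self):
        xyz = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]])
        np.testing.assert_allclose(joint_displacement_series(np.array([0, 1]), xyz), [3.0])

    def test_gap_pairs_produce_no_value(self):
        # retained frames 0 and 2 are not adjacent: no displacement at all
        xyz = np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 5.0]])
        assert len(joint_displacement_series(np.array([0, 2]), xyz)) == 0

    def test_matches_brute_force_pairing_oracle(self, rng):
        # oracle: walk the original frame axis, pairing i with i+1 only when
        # both survive filtering
        n = 40
        xyz = rng.standard_normal((n, 3))
        c = rng.uniform(0, 1, n)
        idx, kept = filter_low_confidence(xyz, c, 0.5)
        got = joint_displacement_series(idx, kept)
        retained = set(idx.tolist())
        expected = [
            float(np.linalg.norm(xyz[i + 1] - xyz[i]))
            for i in range(n - 1)
            if i in retained and i + 1 in retained
        ]
        np.testing.assert_allclose(got, expected)

    def test_fewer_than_two_samples_is_empty(self):
        assert len(joint_displacement_series(np.array([3]), np.ones((1, 3)))) == 0


class TestMeanMovement:
    def test_arithmetic_mean(self):
        assert mean_joint_movement(np.array([1.0, 3.0])) == 2.0

    def test_empty_series_is_missing(self):
        assert np.isnan(mean_joint_movement(np.array([])))

    def test_random_walk_mean_matches_chi3_oracle(self, rng):
        steps = rng.standard_normal((10_000, 3)) * 0.01
        d = np.linalg.norm(steps, axis=1)
        assert mean_joint_movement(d) == pytest.approx(0.01 * ks.CHI3_MEAN, rel=0.02)


class TestFeatureTable:
    @pytest.mark.parametrize(
        "joint_set, segments, n_cols",
        [("head", ("V",), 4), ("trunk", ("V", "VA", "VAO"), 6), ("all", ("V",), 24)],
    )
    def test_table_shape_is_joints_times_segments(self, tiny_cohort, joint_set, segments, n_cols):
        recordings, _ = tiny_cohort
        table = build_feature_table(recordings, joint_set, segments)
        assert table.values.shape == (12, n_cols)

    def test_scaling_depth_scales_features(self, tiny_cohort):
        # 3D coordinates scale linearly with the depth channel, so every
        # feature is homogeneous of degree 1 in it
        recordings, _ = tiny_cohort
        rec = recordings[0]
        base = build_feature_table([rec], "head", ("V",))
        scaled_rec = ks.SubjectRecording(
            rec.subject_id, rec.group, rec.timestamps,
            np.concatenate([rec.joints[..., :2], 2.0 * rec.joints[..., 2:3],
                            rec.joints[..., 3:]], axis=-1),
            rec.schedule,
        )
        scaled = build_feature_table([scaled_rec], "head", ("V",))
        np.testing.assert_allclose(scaled.values.to_numpy(), 2.0 * base.values.to_numpy(),
                                   rtol=1e-10)

    def test_frame_order_does_not_matter_after_sorting(self, tmp_path, tiny_cohort):
        recordings, _ = tiny_cohort
        rec = recordings[0]
        path = tmp_path / "r.csv"
        ks.write_pose_stream(rec, path)
        lines = path.read_text().splitlines()
        body = lines[1:]
        rng = np.random.default_rng(0)
        rng.shuffle(body)
        path.write_text("\n".join([lines[0]] + body) + "\n")
        back = ks.read_pose_stream(path, rec.schedule, rec.subject_id, rec.group)
        a = build_feature_table([rec], "head", ("V",)).values.to_numpy()
        b = build_feature_table([back], "head", ("V",)).values.to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_fully_dropped_cell_is_imputed_with_column_median(self, tiny_cohort):
        recordings, _ = tiny_cohort
        rec = recordings[0]
        # suppress joint 15 entirely for one subject
        joints = rec.joints.copy()
        joints[:, 15, 3] = 0.0
        broken = ks.SubjectRecording(rec.subject_id, rec.group, rec.timestamps,
                                     joints, rec.schedule)
        table = build_feature_table([broken] + list(recordings[1:]), "head", ("V",))
        assert table.n_imputed == 1
        col = table.values[(15, "V")]
        assert col.loc[rec.subject_id] == pytest.approx(col.drop(rec.subject_id).median())

    def test_column_missing_everywhere_is_an_error(self, tiny_cohort):
        recordings, _ = tiny_cohort
        broken = []
        for rec in recordings:
            joints = rec.joints.copy()
            joints[:, 15, 3] = 0.0
            broken.append(ks.SubjectRecording(rec.subject_id, rec.group,
                                              rec.timestamps, joints, rec.schedule))
        with pytest.raises(ValueError, match="joint=15"):
            build_feature_table(broken, "head", ("V",))

    def test_labels_expose_asd_as_positive_class(self, tiny_cohort):
        recordings, _ = tiny_cohort
        table = build_feature_table(recordings, "trunk", ("V",))
        assert set(table.y) == {0, 1}
        assert table.y.sum() == 6
        tidy = table.to_tidy()
        assert set(tidy.columns) == {"subject_id", "group", "joint", "segment", "value"}
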