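"""Pose-vector parsing, sequence I/O, the skeleton graph, and normalization."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fusefall import (
    COCO_EDGES,
    build_skeleton_graph,
    motion_stream,
    normalize_sequence,
    parse_pose_vector,
    read_sequence,
    write_sequence,
)
from fusefall.skeleton import (
    FormatError,
    N_JOINTS,
    SkeletonSequence,
    is_blank_frame,
    write_edge_list,
)


def _random_sequence(rng, t=20, label="unknown"):
    kp = np.empty((t, N_JOINTS, 3))
    kp[:, :, :2] = rng.normal(100.0, 30.0, size=(t, N_JOINTS, 2))
    kp[:, :, 2] = rng.uniform(0.5, 1.0, size=(t, N_JOINTS))
    return SkeletonSequence(clip_id="r", fps=25.0, keypoints=kp, label=label)


class TestParsePoseVector:
    def test_zero_record_parses_to_zero_pose(self):
        pv = parse_pose_vector(np.zeros(57))
        assert pv.box_conf == 0.0 and pv.class_conf == 0.0
        assert np.all(pv.keypoints == 0.0)

    def test_keypoints_only_record_is_rejected(self):
        with pytest.raises(FormatError, match="57"):
            parse_pose_vector(np.zeros(51))

    def test_positional_layout_maps_first_keypoint(self):
        raw = np.zeros(57)
        raw[6:9] = (10.0, 20.0, 0.9)
        pv = parse_pose_vector(raw)
        assert tuple(pv.keypoints[0]) == (10.0, 20.0, 0.9)

    def test_non_finite_value_rejected(self):
        raw = np.zeros(57)
        raw[3] = np.nan
        with pytest.raises(FormatError, match="finite"):
            parse_pose_vector(raw)

    def test_out_of_range_confidence_rejected(self):
        raw = np.zeros(57)
        raw[4] = 1.5
        with pytest.raises(FormatError):
            parse_pose_vector(raw)

    @given(st.integers(0, 2**32 - 1))
    def test_parse_serialize_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        raw = np.concatenate([
            rng.uniform(0, 300, size=4),
            rng.uniform(0, 1, size=2),
            np.column_stack([
                rng.uniform(0, 320, size=17),
                rng.uniform(0, 240, size=17),
                rng.uniform(0, 1, size=17),
            ]).ravel(),
        ])
        assert np.allclose(parse_pose_vector(raw).serialize(), raw)


class TestReadSequence:
    def test_json_file_of_valid_frames(self, tmp_path, rng):
        seq = _random_sequence(rng, t=75)
        path = tmp_path / "clip.json"
        write_sequence(seq, path)
        loaded = read_sequence(path)
        assert loaded.n_frames == 75
        assert np.allclose(loaded.keypoints, seq.keypoints)

    def test_blank_frames_are_eliminated(self, tmp_path, rng):
        seq = _random_sequence(rng, t=75)
        seq.keypoints[(3, 40, 74), :, 2] = 0.0  # three blank frames
        path = tmp_path / "clip.json"
        write_sequence(seq, path)
        loaded = read_sequence(path)
        assert loaded.n_frames == 72
        assert loaded.n_blank_removed == 3

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text("[]")
        with pytest.raises(FormatError):
            read_sequence(path)

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_sequence(tmp_path / "nope.json")

    def test_csv_roundtrip(self, tmp_path, rng):
        seq = _random_sequence(rng, t=10)
        path = tmp_path / "clip.csv"
        write_sequence(seq, path, fmt="csv")
        loaded = read_sequence(path)
        assert loaded.n_frames == 10
        assert np.allclose(loaded.keypoints, seq.keypoints, atol=1e-3, rtol=1e-3)

    def test_frames_ordered_by_index(self, tmp_path, rng):
        seq = _random_sequence(rng, t=5)
        records = [
            {"frame": t, "keypoints": seq.keypoints[t].tolist()} for t in range(5)
        ]
        path = tmp_path / "shuffled.json"
        path.write_text(json.dumps(records[::-1]))
        loaded = read_sequence(path)
        assert np.allclose(loaded.keypoints, seq.keypoints)

    def test_blank_frame_threshold(self):
        frame = np.zeros((17, 3))
        frame[:, 2] = 0.04
        assert is_blank_frame(frame)
        frame[0, 2] = 0.5
        assert not is_blank_frame(frame)


class TestSkeletonGraph:
    def test_unilabel_is_degree_normalized_support(self):
        g = build_skeleton_graph("uni-label")
        support = g.support()
        expected = support / support.sum(axis=1, keepdims=True)
        assert g.adjacency_stack.shape == (1, 17, 17)
        np.testing.assert_allclose(g.adjacency_stack[0], expected, atol=1e-12)

    @pytest.mark.parametrize("strategy", ["uni-label", "distance", "spatial"])
    def test_support_symmetric_before_normalization(self, strategy):
        g = build_skeleton_graph(strategy)
        support = g.support()
        np.testing.assert_array_equal(support, support.T)

    def test_spatial_partitions_tile_the_neighborhood(self):
        g = build_skeleton_graph("spatial")
        assert g.n_partitions == 3
        uni = build_skeleton_graph("uni-label")
        np.testing.assert_allclose(
            g.adjacency_stack.sum(axis=0), uni.adjacency_stack[0], atol=1e-12
        )

    @pytest.mark.parametrize("strategy", ["uni-label", "distance", "spatial"])
    def test_constant_signal_is_preserved(self, strategy):
        # joint row-stochasticity of the union of partitions
        g = build_skeleton_graph(strategy)
        const = np.ones(17)
        out = sum(g.adjacency_stack[k] @ const for k in range(g.n_partitions))
        np.testing.assert_allclose(out, const, atol=1e-12)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="partition strategy"):
            build_skeleton_graph("banana")

    def test_graph_is_connected(self):
        g = build_skeleton_graph()
        assert np.all(g.hop_to_root >= 0)

    def test_edge_list_export(self, tmp_path):
        g = build_skeleton_graph()
        path = tmp_path / "edges.tsv"
        write_edge_list(g, path)
        lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
        assert len(lines) == len(COCO_EDGES)


class TestNormalization:
    def test_translation_invariance(self, rng):
        seq = _random_sequence(rng)
        shifted = SkeletonSequence(
            clip_id="s", fps=25.0, keypoints=seq.keypoints.copy()
        )
        shifted.keypoints[:, :, 0] += 5.0
        shifted.keypoints[:, :, 1] += 9.0
        np.testing.assert_allclose(
            normalize_sequence(seq).tensor,
            normalize_sequence(shifted).tensor,
            atol=1e-9,
        )

    def test_uniform_scale_invariance(self, rng):
        seq = _random_sequence(rng)
        scaled = SkeletonSequence(
            clip_id="s", fps=25.0, keypoints=seq.keypoints.copy()
        )
        scaled.keypoints[:, :, :2] *= 2.0
        np.testing.assert_allclose(
            normalize_sequence(seq).tensor,
            normalize_sequence(scaled).tensor,
            atol=1e-9,
        )

    def test_centered_unit_torso_sequence_is_fixed_point(self):
        from fusefall.skeleton import (
            LEFT_HIP, LEFT_SHOULDER, RIGHT_HIP, RIGHT_SHOULDER,
        )

        kp = np.zeros((4, N_JOINTS, 3))
        kp[:, :, 2] = 0.9
        kp[:, LEFT_HIP, :2] = (-0.5, 0.0)
        kp[:, RIGHT_HIP, :2] = (0.5, 0.0)
        kp[:, LEFT_SHOULDER, :2] = (-0.5, -1.0)
        kp[:, RIGHT_SHOULDER, :2] = (0.5, -1.0)
        seq = SkeletonSequence(clip_id="u", fps=25.0, keypoints=kp)
        norm = normalize_sequence(seq)
        assert norm.scale == pytest.approx(1.0)
        np.testing.assert_allclose(norm.tensor, kp[:, :, :2], atol=1e-12)

    def test_all_zero_sequence_rejected(self):
        kp = np.zeros((5, N_JOINTS, 3))
        seq = SkeletonSequence(clip_id="z", fps=25.0, keypoints=kp)
        with pytest.raises(ValueError, match="torso"):
            normalize_sequence(seq)

    def test_score_channel_passthrough(self, rng):
        seq = _random_sequence(rng)
        norm = normalize_sequence(seq, include_scores=True)
        assert norm.tensor.shape[2] == 3
        np.testing.assert_allclose(norm.tensor[:, :, 2], seq.keypoints[:, :, 2])


class TestMotionStream:
    def test_constant_sequence_gives_zero_motion(self, rng):
        seq = _random_sequence(rng, t=1)
        const = SkeletonSequence(
            clip_id="c", fps=25.0,
            keypoints=np.repeat(seq.keypoints, 10, axis=0),
        )
        motion = motion_stream(normalize_sequence(const))
        np.testing.assert_allclose(motion.tensor, 0.0, atol=1e-12)

    def test_linear_motion_gives_constant_difference(self, rng):
        seq = _random_sequence(rng, t=1)
        kp = np.repeat(seq.keypoints, 12, axis=0)
        kp[:, :, 0] += 3.0 * np.arange(12)[:, None]  # x(t) = x0 + 3t
        moving = SkeletonSequence(clip_id="m", fps=25.0, keypoints=kp)
        norm = normalize_sequence(moving)
        motion = motion_stream(norm)
        # per-frame hip centering removes the global translation, so the
        # differences of the *normalized* coordinates vanish
        np.testing.assert_allclose(motion.tensor[1:], 0.0, atol=1e-9)
        # without centering the difference is the constant velocity
        raw = norm.tensor + 0.0
        raw_diff = kp[1:, :, 0] - kp[:-1, :, 0]
        np.testing.assert_allclose(raw_diff, 3.0, atol=1e-12)

    def test_shape_preserved_and_first_frame_zero(self, rng):
        norm = normalize_sequence(_random_sequence(rng, t=8))
        motion = motion_stream(norm)
        assert motion.tensor.shape == norm.tensor.shape
        np.testing.assert_allclose(motion.tensor[0], 0.0)

    def test_single_frame_rejected(self, rng):
        norm = normalize_sequence(_random_sequence(rng, t=1))
        with pytest.raises(ValueError, match="2 frames"):
            motion_stream(norm)

    def test_second_difference_of_quadratic_is_constant(self):
        t = np.arange(10, dtype=float)
        kp = np.zeros((10, N_JOINTS, 3))
        kp[:, :, 2] = 0.9
        base = _template_like()
        kp[:, :, :2] = base[None]
        kp[:, 0, 0] += t**2  # quadratic trajectory on one joint
        seq = SkeletonSequence(clip_id="q", fps=25.0, keypoints=kp)
        norm = normalize_sequence(seq)
        second = motion_stream(motion_stream(norm))
        diffs = second.tensor[2:, 0, 0]
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-9)


def _template_like():
    from fusefall.synthetic import TEMPLATE

    return TEMPLATE + np.array([160.0, 120.0])
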