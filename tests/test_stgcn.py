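"""Spatial graph convolution, layer shape contracts, the two-stream network,
and the BCE loss."""

import numpy as np
import pytest

from fusefall import (
    TwoStreamConfig,
    bce_loss,
    build_skeleton_graph,
    predict_frames,
    spatial_graph_conv,
    temporal_out_length,
    train_video_model,
)
from fusefall.nn import Tensor
from fusefall.stgcn import STGCNLayer, TwoStreamSTGCN

PARTITIONS = ("uni-label", "distance", "spatial")


def _random_connected_graph(rng, n_nodes):
    edges = [(i, i + 1) for i in range(n_nodes - 1)]  # spanning path
    for _ in range(rng.integers(0, n_nodes)):
        i, j = rng.integers(0, n_nodes, 2)
        if i != j and tuple(sorted((i, j))) not in [tuple(sorted(e)) for e in edges]:
            edges.append((min(i, j), max(i, j)))
    return edges


def _bruteforce_graph_conv(features, edges, n_nodes, strategy, weights, root=0):
    """Direct per-node neighborhood sum with degree normalization."""
    neighbors = {i: {i} for i in range(n_nodes)}
    for i, j in edges:
        neighbors[i].add(j)
        neighbors[j].add(i)
    # hop distance to the root for the spatial-configuration partition
    hop = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in neighbors[u]:
                if v not in hop:
                    hop[v] = hop[u] + 1
                    nxt.append(v)
        frontier = nxt

    def subset(center, neighbor):
        if strategy == "uni-label":
            return 0
        if strategy == "distance":
            return 0 if neighbor == center else 1
        if hop[neighbor] == hop[center]:
            return 0
        return 1 if hop[neighbor] < hop[center] else 2

    t, _, c_in = features.shape
    c_out = weights.shape[2]
    out = np.zeros((t, n_nodes, c_out))
    for ti in range(t):
        for i in range(n_nodes):
            z = len(neighbors[i])
            for j in neighbors[i]:
                out[ti, i] += features[ti, j] @ weights[subset(i, j)] / z
    return out


class TestSpatialGraphConv:
    @pytest.mark.parametrize("strategy", PARTITIONS)
    @pytest.mark.parametrize("n_nodes", [2, 4, 6])
    def test_matches_bruteforce_neighborhood_sum(self, strategy, n_nodes, rng):
        for _ in range(5):
            edges = _random_connected_graph(rng, n_nodes)
            graph = build_skeleton_graph(
                strategy, edges=edges, n_joints=n_nodes, root_joints=(0,)
            )
            features = rng.normal(size=(3, n_nodes, 2))
            weights = rng.normal(size=(graph.n_partitions, 2, 4))
            got = spatial_graph_conv(features, graph, weights)
            want = _bruteforce_graph_conv(features, edges, n_nodes, strategy, weights)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_single_isolated_node_identity(self, rng):
        graph = build_skeleton_graph(
            "uni-label", edges=[], n_joints=1, root_joints=(0,)
        )
        features = rng.normal(size=(5, 1, 3))
        out = spatial_graph_conv(features, graph, np.eye(3)[None])
        np.testing.assert_allclose(out, features, atol=1e-12)

    def test_three_node_path_equals_normalized_matrix_product(self, rng):
        edges = [(0, 1), (1, 2)]
        graph = build_skeleton_graph(
            "uni-label", edges=edges, n_joints=3, root_joints=(0,)
        )
        features = np.array([[[1.0], [2.0], [3.0]]])
        out = spatial_graph_conv(features, graph, np.ones((1, 1, 1)))
        support = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float)
        expected = (support / support.sum(1, keepdims=True)) @ features[0]
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_constant_input_identity_weights_stay_constant(self, skeleton_graph):
        features = np.ones((2, 17, 3))
        weights = np.stack([np.eye(3)] * skeleton_graph.n_partitions)
        out = spatial_graph_conv(features, skeleton_graph, weights)
        np.testing.assert_allclose(out, features, atol=1e-12)

    def test_shape_mismatch_rejected(self, skeleton_graph, rng):
        with pytest.raises(ValueError):
            spatial_graph_conv(
                rng.normal(size=(2, 5, 3)), skeleton_graph, np.zeros((3, 3, 4))
            )


class TestLayerShapes:
    def _layer(self, stride, rng, in_c=2, out_c=4):
        graph = build_skeleton_graph("spatial")
        layer = STGCNLayer(
            in_c, out_c, stride, graph.adjacency_stack,
            temporal_kernel=9, dropout=0.0, rng=rng,
            drop_rng=np.random.default_rng(0),
        )
        layer.eval()
        return layer

    def test_stride_one_preserves_length(self, rng):
        layer = self._layer(1, rng)
        out = layer(Tensor(np.random.default_rng(0).normal(size=(1, 2, 75, 17))))
        assert out.shape == (1, 4, 75, 17)

    def test_stride_two_halves_length_ceil(self, rng):
        layer = self._layer(2, rng)
        out = layer(Tensor(np.random.default_rng(0).normal(size=(1, 2, 75, 17))))
        assert out.shape == (1, 4, 38, 17)

    def test_invalid_stride_rejected(self, rng):
        with pytest.raises(ValueError, match="stride"):
            self._layer(3, rng)

    def test_nine_layer_plan_maps_75_to_19(self):
        assert temporal_out_length(75) == 19

    def test_full_stack_temporal_reduction(self, rng):
        model = TwoStreamSTGCN(TwoStreamConfig.tiny(seed=0))
        model.eval()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 2, 75, 17)))
        y = model.joint_stack.input_bn(x)
        for layer in model.joint_stack.layers:
            y = layer(y)
        assert y.shape[2] == 19


class TestTwoStreamNetwork:
    def test_output_probability_in_unit_interval(self, rng):
        model = TwoStreamSTGCN(TwoStreamConfig.tiny(seed=0))
        joint = rng.normal(size=(3, 2, 75, 17))
        motion = rng.normal(size=(3, 2, 75, 17))
        p = model.predict_proba(joint, motion)
        assert np.all((p >= 0) & (p <= 1))

    def test_deterministic_for_fixed_seed(self, rng):
        joint = rng.normal(size=(2, 2, 75, 17))
        motion = np.zeros_like(joint)
        p1 = TwoStreamSTGCN(TwoStreamConfig.tiny(seed=5)).predict_proba(joint, motion)
        p2 = TwoStreamSTGCN(TwoStreamConfig.tiny(seed=5)).predict_proba(joint, motion)
        np.testing.assert_array_equal(p1, p2)

    def test_stream_shape_mismatch_rejected(self, rng):
        model = TwoStreamSTGCN(TwoStreamConfig.tiny(seed=0))
        with pytest.raises(ValueError, match="mismatch"):
            model(
                Tensor(rng.normal(size=(1, 2, 75, 17))),
                Tensor(rng.normal(size=(1, 2, 74, 17))),
            )

    def test_joint_permutation_equivariance(self, rng):
        """Relabeling joints (and permuting the adjacency accordingly) leaves
        the clip probability unchanged."""
        model = TwoStreamSTGCN(TwoStreamConfig.tiny(seed=2))
        model.eval()
        joint = rng.normal(size=(2, 2, 75, 17)).astype(np.float32)
        motion = rng.normal(size=(2, 2, 75, 17)).astype(np.float32)
        p_ref = model.predict_proba(joint, motion)
        perm = np.random.default_rng(9).permutation(17)
        for stack in (model.joint_stack, model.motion_stack):
            for layer in stack.layers:
                a = layer._a_src
                layer._a_src = np.ascontiguousarray(a[:, perm][:, :, perm])
        p_perm = model.predict_proba(joint[:, :, :, perm], motion[:, :, :, perm])
        np.testing.assert_allclose(p_ref, p_perm, atol=1e-5)


class TestBCELoss:
    def test_perfect_prediction_is_near_zero(self):
        assert bce_loss([1.0], [1.0 - 1e-7]) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_prediction_is_ln2(self):
        assert bce_loss([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2), rel=1e-12)

    def test_batch_order_invariance(self, rng):
        y = rng.integers(0, 2, size=20)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert bce_loss(y, p) == pytest.approx(bce_loss(y[perm], p[perm]), rel=1e-12)

    def test_nonnegative_on_random_batches(self, rng):
        for _ in range(100):
            y = rng.integers(0, 2, size=8)
            p = rng.uniform(size=8)
            assert bce_loss(y, p) >= 0.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bce_loss([], [])

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            bce_loss([0.5], [0.5])

    def test_tensor_path_matches_numpy_path(self, rng):
        y = rng.integers(0, 2, size=6)
        p = rng.uniform(0.01, 0.99, size=6)
        loss_t = bce_loss(y, Tensor(p))
        assert loss_t.item() == pytest.approx(bce_loss(y, p), rel=1e-5)


@pytest.fixture(scope="module")
def tiny_fixture():
    from fusefall import SimConfig, gen_dataset, motion_stream, normalize_sequence
    from fusefall.stgcn import streams_from_sequence

    ds = gen_dataset(SimConfig(n_per_class=6, seed=11))
    joints, motions = [], []
    for clip in ds.clips:
        norm = normalize_sequence(clip.skeleton)
        j, m = streams_from_sequence(norm, motion_stream(norm))
        joints.append(j)
        motions.append(m)
    return np.stack(joints), np.stack(motions), ds.labels()


@pytest.fixture(scope="module")
def frame_model():
    return TwoStreamSTGCN(TwoStreamConfig.tiny(seed=0))


class TestTraining:

    def test_loss_decreases_on_separable_data(self, tiny_fixture):
        joints, motions, labels = tiny_fixture
        config = TwoStreamConfig.tiny(epochs=6, seed=0)
        _, history = train_video_model(joints, motions, labels, config)
        assert history["loss"][-1] < history["loss"][0]

    def test_same_seed_reproduces_history(self, tiny_fixture):
        joints, motions, labels = tiny_fixture
        config = TwoStreamConfig.tiny(epochs=2, seed=4)
        _, h1 = train_video_model(joints, motions, labels, config)
        _, h2 = train_video_model(joints, motions, labels, config)
        assert h1["loss"] == h2["loss"]

    def test_single_class_dataset_refused(self, tiny_fixture):
        joints, motions, _ = tiny_fixture
        with pytest.raises(ValueError, match="one class"):
            train_video_model(
                joints, motions, np.ones(len(joints), dtype=int),
                TwoStreamConfig.tiny(epochs=1),
            )


class TestPredictFrames:
    def test_full_window_gives_clip_probability_everywhere(self, frame_model, rng):
        joint = rng.normal(size=(2, 75, 17))
        motion = rng.normal(size=(2, 75, 17))
        fp = predict_frames(frame_model, joint, motion, window=75)
        assert fp.probs.shape == (75,)
        assert np.all(fp.probs == fp.probs[0])

    def test_coverage_equals_sequence_length(self, frame_model, rng):
        joint = rng.normal(size=(2, 75, 17))
        motion = rng.normal(size=(2, 75, 17))
        for window, stride in [(45, 5), (45, 1), (30, 7), (75, 1)]:
            fp = predict_frames(frame_model, joint, motion, window=window, stride=stride)
            assert fp.probs.shape == (75,)
            assert np.all((fp.probs >= 0) & (fp.probs <= 1))

    def test_sequence_shorter_than_window_rejected(self, frame_model, rng):
        joint = rng.normal(size=(2, 30, 17))
        with pytest.raises(ValueError, match="shorter"):
            predict_frames(frame_model, joint, joint, window=45)


class TestConfigContracts:
    def test_wrong_layer_count_rejected(self):
        with pytest.raises(ValueError, match="nine"):
            TwoStreamConfig(channels=(8, 8, 8), strides=(1, 1, 1))

    def test_wrong_stride_positions_rejected(self):
        with pytest.raises(ValueError, match="strides"):
            TwoStreamConfig(strides=(1, 2, 1, 1, 1, 1, 2, 1, 1))

    def test_even_temporal_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            TwoStreamConfig(temporal_kernel=8)

    def test_default_plan_is_canonical(self):
        config = TwoStreamConfig()
        assert config.channels == (64, 64, 64, 128, 128, 128, 256, 256, 256)
        assert config.strides == (1, 1, 1, 2, 1, 1, 2, 1, 1)
        assert config.dropout == 0.5 and config.lr == 1e-3
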