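"""Two-stream spatio-temporal graph convolutional fall classifier.

The video branch classifies a skeleton clip with a stack of nine ST-GCN
layers per stream.  Each layer applies a spatial graph convolution over the
1-hop joint neighborhood — partitioned by one of three strategies, with one
weight block per partition and degree normalization balancing the subsets —
followed by a temporal convolution (kernel Γ over corresponding joints in
neighboring frames).  The temporal convolutions of layers 4 and 7 use stride
2, halving the time axis, so a 75-frame clip reaches the head at 19 frames.
A joint-coordinate stream and a motion (frame-difference) stream are
processed by separate stacks, globally pooled, concatenated, and mapped by a
fully connected layer to a normalized two-class output; training minimizes
binary cross entropy, which for a two-way softmax head coincides with
categorical cross entropy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import nn
from .nn import Tensor
from .skeleton import NormalizedSequence, SkeletonGraph, build_skeleton_graph

__all__ = [
    "TwoStreamConfig",
    "FramePredictions",
    "spatial_graph_conv",
    "STGCNLayer",
    "StreamStack",
    "TwoStreamSTGCN",
    "bce_loss",
    "train_video_model",
    "predict_clip",
    "predict_frames",
    "temporal_out_length",
]

STRIDE_PLAN = (1, 1, 1, 2, 1, 1, 2, 1, 1)


@dataclass(frozen=True)
class TwoStreamConfig:
    """Hyperparameters of the two-stream network and its training loop."""

    in_channels: int = 2
    channels: tuple = (64, 64, 64, 128, 128, 128, 256, 256, 256)
    strides: tuple = STRIDE_PLAN
    temporal_kernel: int = 9          # Γ, odd so the temporal window is symmetric
    dropout: float = 0.5
    partition: str = "spatial"
    lr: float = 1e-3
    epochs: int = 60
    batch_size: int = 16
    label_smoothing: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != 9 or len(self.strides) != 9:
            raise ValueError("the network has exactly nine ST-GCN layers")
        if tuple(self.strides) != STRIDE_PLAN:
            raise ValueError(
                "temporal strides must be 2 at layers 4 and 7 and 1 elsewhere"
            )
        if self.temporal_kernel % 2 == 0:
            raise ValueError("temporal kernel Γ must be odd")

    def layer_plan(self):
        ins = (self.in_channels,) + tuple(self.channels[:-1])
        return list(zip(ins, self.channels, self.strides))

    @classmethod
    def tiny(cls, **overrides) -> "TwoStreamConfig":
        """Desk-scale preset: same topology, narrow channels, short schedule."""
        base = cls(
            channels=(8, 8, 8, 16, 16, 16, 32, 32, 32),
            temporal_kernel=5,
            dropout=0.1,
            epochs=12,
            batch_size=32,
            label_smoothing=0.05,
        )
        return replace(base, **overrides) if overrides else base


def temporal_out_length(t: int, strides=STRIDE_PLAN) -> int:
    """Closed-form time-axis length after the nine-layer stride plan."""
    for s in strides:
        t = -(-t // s)  # ceil division; symmetric Γ//2 padding preserves ceil
    return t


def spatial_graph_conv(
    features: np.ndarray,
    graph: SkeletonGraph,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """One spatial graph convolution, (T, V, C_in) -> (T, V, C_out).

    ``weights`` has shape (K, C_in, C_out), one block per partition subset.
    Equivalent to the per-node neighborhood sum with degree normalization;
    implemented as per-partition normalized-adjacency matrix products.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 3 or features.shape[1] != graph.n_joints:
        raise ValueError(
            f"features must be (T, {graph.n_joints}, C), got {features.shape}"
        )
    k, c_in, _ = weights.shape
    if k != graph.n_partitions or c_in != features.shape[2]:
        raise ValueError("weight stack does not match graph/features")
    out = np.einsum(
        "kij,tjc,kcd->tid", graph.adjacency_stack, features, weights,
        optimize=True,
    )
    if bias is not None:
        out = out + bias
    return out


class STGCNLayer(nn.Module):
    """Graph convolution sub-block, then temporal convolution, with residual."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int,
        adjacency: np.ndarray,
        temporal_kernel: int,
        dropout: float,
        rng: np.random.Generator,
        drop_rng: np.random.Generator,
        residual: bool = True,
    ):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"temporal stride must be 1 or 2, got {stride}")
        k = adjacency.shape[0]
        # graph_prop contracts over the source axis; the stored stack is
        # [partition, target, source].
        self._a_src = np.ascontiguousarray(adjacency.transpose(0, 2, 1))
        self.gcn_conv = nn.Conv2d(k * in_channels, out_channels, 1, rng)
        self.gcn_bn = nn.BatchNorm2d(out_channels)
        self.tcn_conv = nn.Conv2d(
            out_channels, out_channels, (temporal_kernel, 1), rng,
            stride=(stride, 1), padding=(temporal_kernel // 2, 0),
        )
        self.tcn_bn = nn.BatchNorm2d(out_channels)
        self.drop = nn.Dropout(dropout, drop_rng)
        self.residual = residual
        self.res_conv = None
        self.res_bn = None
        if residual and (in_channels != out_channels or stride != 1):
            self.res_conv = nn.Conv2d(
                in_channels, out_channels, 1, rng, stride=(stride, 1), bias=False
            )
            self.res_bn = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        y = nn.graph_prop(x, self._a_src)
        y = nn.relu(self.gcn_bn(self.gcn_conv(y)))
        y = self.drop(self.tcn_bn(self.tcn_conv(y)))
        if self.residual:
            res = x if self.res_conv is None else self.res_bn(self.res_conv(x))
            y = y + res
        return nn.relu(y)


class StreamStack(nn.Module):
    """Nine ST-GCN layers plus input batch normalization for one stream."""

    def __init__(self, config: TwoStreamConfig, adjacency, rng, drop_rng):
        super().__init__()
        self.input_bn = nn.BatchNorm2d(config.in_channels)
        self.layers = [
            STGCNLayer(
                c_in, c_out, s, adjacency, config.temporal_kernel,
                config.dropout, rng, drop_rng,
            )
            for c_in, c_out, s in config.layer_plan()
        ]

    def forward(self, x: Tensor) -> Tensor:
        x = self.input_bn(x)
        for layer in self.layers:
            x = layer(x)
        return x.mean(axis=(2, 3))  # global average pool over time and joints


class TwoStreamSTGCN(nn.Module):
    """Joint stream + motion stream -> concatenated features -> 2-class head."""

    def __init__(self, config: TwoStreamConfig, graph: SkeletonGraph | None = None):
        super().__init__()
        self.config = config
        self.graph = graph or build_skeleton_graph(config.partition)
        rng = np.random.default_rng(config.seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
        )
        adj = self.graph.adjacency_stack
        self.joint_stack = StreamStack(config, adj, rng, self.dropout_rng)
        self.motion_stack = StreamStack(config, adj, rng, self.dropout_rng)
        self.head = nn.Linear(2 * config.channels[-1], 2, rng)

    def forward(self, joint: Tensor, motion: Tensor) -> Tensor:
        """Logits (N, 2); class 1 is "fall"."""
        if joint.shape != motion.shape:
            raise ValueError(
                f"stream shape mismatch: joint {joint.shape}, motion {motion.shape}"
            )
        fj = self.joint_stack(joint)
        fm = self.motion_stack(motion)
        return self.head(nn.concat([fj, fm], axis=1))

    def predict_proba(self, joint: np.ndarray, motion: np.ndarray) -> np.ndarray:
        """Fall probabilities for a batch of (N, C, T, V) stream pairs."""
        self.eval()
        logits = self.forward(Tensor(joint), Tensor(motion))
        lp = nn.log_softmax(logits, axis=1).data
        return np.exp(lp[:, 1])


def bce_loss(y_true, y_pred, eps: float = 1e-7):
    """Mean binary cross entropy; predictions clipped to (eps, 1 - eps).

    Accepts numpy arrays (returns a float) or an autodiff tensor for
    ``y_pred`` (returns a tensor for backpropagation).
    """
    y = np.asarray(y_true, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty batch")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("labels must be 0 or 1")
    if isinstance(y_pred, Tensor):
        if y_pred.data.size != y.size:
            raise ValueError("label/prediction length mismatch")
        p = nn.clip(y_pred.reshape(y.size), eps, 1.0 - eps)
        terms = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
        return -terms.mean()
    p = np.clip(np.asarray(y_pred, dtype=float).ravel(), eps, 1.0 - eps)
    if p.size != y.size:
        raise ValueError("label/prediction length mismatch")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def train_video_model(
    joint: np.ndarray,
    motion: np.ndarray,
    labels: np.ndarray,
    config: TwoStreamConfig | None = None,
    validation=None,
):
    """Train the two-stream network; deterministic for a fixed config seed.

    joint/motion: (N, C, T, V) arrays; labels: (N,) in {0, 1} (1 = fall).
    Returns (model, history) where history maps "loss" to per-epoch means
    (and "val_accuracy" when a validation tuple is given).  Targets are
    label-smoothed (default 0.1), which bounds the logit scale so the
    trained network keeps graded confidence on borderline motion instead of
    saturating; decision fusion relies on that calibration.
    """
    config = config or TwoStreamConfig()
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training refused: only one class present")
    model = TwoStreamSTGCN(config)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
    )
    eps = config.label_smoothing
    onehot = np.eye(2)[labels] * (1.0 - eps) + eps / 2.0
    history: dict[str, list[float]] = {"loss": []}
    if validation is not None:
        history["val_accuracy"] = []
    for _ in range(config.epochs):
        model.train()
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model(Tensor(joint[idx]), Tensor(motion[idx]))
            lp = nn.log_softmax(logits, axis=1)
            loss = -(lp * Tensor(onehot[idx])).sum() * (1.0 / idx.size)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item() * idx.size)
        history["loss"].append(float(np.sum(losses) / n))
        if validation is not None:
            vj, vm, vy = validation
            pred = model.predict_proba(vj, vm) > 0.5
            history["val_accuracy"].append(float(np.mean(pred == (vy == 1))))
    model.eval()
    return model, history


def predict_clip(model: TwoStreamSTGCN, joint: np.ndarray, motion: np.ndarray) -> float:
    """Fall probability for one (C, T, V) clip."""
    return float(model.predict_proba(joint[None], motion[None])[0])


@dataclass
class FramePredictions:
    """Per-frame fall probabilities for one clip."""

    clip_id: str
    probs: np.ndarray
    window: int
    stride: int

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("frame probabilities must lie in [0, 1]")


def streams_from_sequence(norm: NormalizedSequence, motion: NormalizedSequence):
    """(C, T, V) channel-first arrays for the two streams."""
    return (
        np.ascontiguousarray(norm.tensor.transpose(2, 0, 1)),
        np.ascontiguousarray(motion.tensor.transpose(2, 0, 1)),
    )


def predict_frames(
    model: TwoStreamSTGCN,
    joint: np.ndarray,
    motion: np.ndarray,
    window: int = 45,
    stride: int = 1,
    clip_id: str = "",
) -> FramePredictions:
    """Sliding-window clip classification mapped back to every frame.

    Each window of ``window`` frames is classified as a clip; every frame
    inherits the probability of the window whose center lies nearest to it
    (earliest window on ties), so the output covers all T frames.
    """
    t = joint.shape[1]
    if t < window:
        raise ValueError(f"sequence length {t} is shorter than window {window}")
    starts = list(range(0, t - window + 1, stride))
    if starts[-1] != t - window:
        starts.append(t - window)
    jb = np.stack([joint[:, s : s + window, :] for s in starts])
    mb = np.stack([motion[:, s : s + window, :] for s in starts])
    probs_w = model.predict_proba(jb, mb)
    centers = np.asarray(starts) + (window - 1) / 2.0
    frames = np.arange(t)
    nearest = np.argmin(np.abs(frames[:, None] - centers[None, :]), axis=1)
    return FramePredictions(
        clip_id=clip_id, probs=probs_w[nearest], window=window, stride=stride
    )


def save_video_model(model: TwoStreamSTGCN, path) -> None:
    """Single-file checkpoint: config echo plus all weights and BN stats."""
    meta = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_arrays())


def load_video_model(path) -> TwoStreamSTGCN:
    with np.load(path) as archive:
        raw = json.loads(archive["__config__"].tobytes().decode())
        for key in ("channels", "strides"):
            raw[key] = tuple(raw[key])
        model = TwoStreamSTGCN(TwoStreamConfig(**raw))
        model.load_state_arrays(
            {k: archive[k] for k in archive.files if k != "__config__"}
        )
    model.eval()
    return model
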