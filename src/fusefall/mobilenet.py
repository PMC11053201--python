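"""Depthwise-separable CNN (MobileNetV2) for log-mel fall/non-fall audio.

The architecture follows the standard MobileNetV2 recipe on a single-channel
input: a 3x3 stem convolution (32 channels, stride 2), seven inverted-
residual bottleneck stages described by (t expansion, c channels, n repeats,
s stride) rows, a 1x1 convolution to 1280 features, global average pooling,
dropout, and a k-way linear head.  Inverted residuals expand by t with a 1x1
convolution and ReLU6, filter with a 3x3 depthwise convolution, and project
back linearly; a shortcut is added when the stride is 1 and channel counts
match.  A width multiplier scales every channel count (rounded to multiples
of 8) for desk-scale training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .nn import Tensor

__all__ = [
    "BOTTLENECK_SCHEDULE",
    "MobileNetV2Config",
    "MobileNetV2",
    "mobilenet_forward",
    "spatial_trace",
    "make_divisible",
    "train_audio_model",
    "kfold_evaluate",
    "CVReport",
]

#: (t expansion, c output channels, n repeats, s first-repeat stride)
BOTTLENECK_SCHEDULE = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)


def make_divisible(v: float, divisor: int = 8) -> int:
    """Round a scaled channel count to a multiple of ``divisor`` (min 8)."""
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


@dataclass(frozen=True)
class MobileNetV2Config:
    input_size: int = 224
    in_channels: int = 1
    width_multiplier: float = 1.0
    n_classes: int = 2
    dropout: float = 0.2
    stem_channels: int = 32
    head_channels: int = 1280
    schedule: tuple = BOTTLENECK_SCHEDULE
    seed: int = 0

    def scaled(self, c: int) -> int:
        return make_divisible(c * self.width_multiplier)

    @classmethod
    def tiny(cls, **overrides) -> "MobileNetV2Config":
        """Desk-scale preset: quarter width, 48x48 input, truncated schedule.

        At desk-scale input sizes the deep tail of the full schedule runs on
        1x1 feature maps and memorizes instead of generalizing, so the
        preset keeps only the stages that still see spatial structure; the
        full 224-input schedule remains the default architecture.
        """
        base = cls(
            input_size=48,
            width_multiplier=0.25,
            dropout=0.1,
            schedule=BOTTLENECK_SCHEDULE[:3],
        )
        return replace(base, **overrides) if overrides else base


class InvertedResidual(nn.Module):
    def __init__(self, in_c, out_c, stride, expansion, rng):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        hidden = in_c * expansion
        self.use_residual = stride == 1 and in_c == out_c
        self.expand = None
        if expansion != 1:
            self.expand = nn.Sequential(
                nn.Conv2d(in_c, hidden, 1, rng, bias=False),
                nn.BatchNorm2d(hidden),
                nn.ReLU6(),
            )
        self.depthwise = nn.DepthwiseConv2d(
            hidden, 3, rng, stride=(stride, stride), padding=(1, 1)
        )
        self.dw_bn = nn.BatchNorm2d(hidden)
        self.act = nn.ReLU6()
        # linear bottleneck: no nonlinearity after the projection
        self.project = nn.Conv2d(hidden, out_c, 1, rng, bias=False)
        self.proj_bn = nn.BatchNorm2d(out_c)

    def forward(self, x: Tensor) -> Tensor:
        y = self.expand(x) if self.expand is not None else x
        y = self.act(self.dw_bn(self.depthwise(y)))
        y = self.proj_bn(self.project(y))
        return y + x if self.use_residual else y


class MobileNetV2(nn.Module):
    def __init__(self, config: MobileNetV2Config | None = None):
        super().__init__()
        self.config = config = config or MobileNetV2Config()
        rng = np.random.default_rng(config.seed)
        stem_c = config.scaled(config.stem_channels)
        self.stem = nn.Sequential(
            nn.Conv2d(config.in_channels, stem_c, 3, rng,
                      stride=(2, 2), padding=(1, 1), bias=False),
            nn.BatchNorm2d(stem_c),
            nn.ReLU6(),
        )
        self.stages = []
        in_c = stem_c
        for t, c, n, s in config.schedule:
            out_c = config.scaled(c)
            blocks = []
            for i in range(n):
                blocks.append(
                    InvertedResidual(in_c, out_c, s if i == 0 else 1, t, rng)
                )
                in_c = out_c
            self.stages.append(nn.Sequential(*blocks))
        head_c = config.scaled(config.head_channels)
        self.head_conv = nn.Sequential(
            nn.Conv2d(in_c, head_c, 1, rng, bias=False),
            nn.BatchNorm2d(head_c),
            nn.ReLU6(),
        )
        self.drop = nn.Dropout(
            config.dropout,
            np.random.default_rng(
                np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
            ),
        )
        self.classifier = nn.Linear(head_c, config.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Logits (N, k) from images (N, C, S, S); class 1 is "fall"."""
        n, c, h, w = x.shape
        cfg = self.config
        if c != cfg.in_channels or h != cfg.input_size or w != cfg.input_size:
            raise ValueError(
                f"expected input (N, {cfg.in_channels}, {cfg.input_size}, "
                f"{cfg.input_size}), got {x.shape}"
            )
        y = self.stem(x)
        for stage in self.stages:
            y = stage(y)
        y = self.head_conv(y)
        y = y.mean(axis=(2, 3))
        return self.classifier(self.drop(y))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities (N, k); rows sum to 1."""
        self.eval()
        lp = nn.log_softmax(self.forward(Tensor(images)), axis=1)
        return np.exp(lp.data)


def spatial_trace(config: MobileNetV2Config | None = None) -> list[int]:
    """Spatial sizes after the stem and after each bottleneck stage.

    Each stride-2 convolution with 3x3 kernel and padding 1 (or the stem)
    maps size S to ceil(S / 2).  For a 224 input this gives
    [112, 112, 56, 28, 14, 14, 7, 7], matching the canonical layer table.
    """
    config = config or MobileNetV2Config()
    size = -(-config.input_size // 2)  # stem
    trace = [size]
    for _, _, _, s in config.schedule:
        size = -(-size // s)
        trace.append(size)
    return trace


def mobilenet_forward(image: np.ndarray, config: MobileNetV2Config | None = None,
                      model: MobileNetV2 | None = None) -> np.ndarray:
    """Class probabilities for one (C, S, S) mel-spectrogram image."""
    model = model or MobileNetV2(config)
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None]
    return model.predict_proba(image[None])[0]


def train_audio_model(
    images: np.ndarray,
    labels: np.ndarray,
    config: MobileNetV2Config | None = None,
    lr: float = 1e-3,
    weight_decay: float = 1e-4,
    epochs: int = 30,
    batch_size: int = 32,
    label_smoothing: float = 0.1,
    seed: int = 0,
    validation=None,
):
    """Train the audio CNN with Adam + L2 weight decay; seed-deterministic.

    images: (N, C, S, S); labels: (N,) in {0, 1} (1 = fall).
    Returns (model, history).  Targets are label-smoothed (default 0.1) so
    the classifier keeps graded confidence on borderline sounds rather than
    saturating; decision fusion relies on that calibration.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training refused: only one class present")
    config = config or MobileNetV2Config.tiny()
    if config.seed != seed:
        config = replace(config, seed=seed)
    model = MobileNetV2(config)
    opt = nn.Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([seed, 2]).generate_state(1)[0]
    )
    onehot = (
        np.eye(config.n_classes)[labels] * (1.0 - label_smoothing)
        + label_smoothing / config.n_classes
    )
    history: dict[str, list[float]] = {"loss": []}
    if validation is not None:
        history["val_accuracy"] = []
    for _ in range(epochs):
        model.train()
        order = shuffle_rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            lp = nn.log_softmax(model(Tensor(images[idx])), axis=1)
            loss = -(lp * Tensor(onehot[idx])).sum() * (1.0 / idx.size)
            model.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * idx.size
        history["loss"].append(total / n)
        if validation is not None:
            vx, vy = validation
            pred = model.predict_proba(vx)[:, 1] > 0.5
            history["val_accuracy"].append(float(np.mean(pred == (vy == 1))))
    model.eval()
    return model, history


@dataclass
class CVReport:
    """Per-fold metric sets plus their averages (cross-validation layout)."""

    k: int
    folds: list      # list of MetricSet
    average: dict    # metric name -> mean percentage

    def to_frame(self):
        import pandas as pd

        rows = [
            {"fold": i + 1, **ms.rounded()} for i, ms in enumerate(self.folds)
        ]
        rows.append({"fold": "Average", **{
            k: round(v, 2) for k, v in self.average.items()
        }})
        return pd.DataFrame(rows)


def kfold_evaluate(
    images: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    config: MobileNetV2Config | None = None,
    **train_kwargs,
) -> CVReport:
    """Stratified k-fold cross-validation; every sample is tested once."""
    from .evaluation import METRIC_NAMES, confusion, metrics

    labels = np.asarray(labels, dtype=int)
    if labels.size < k:
        raise ValueError(f"need at least k={k} samples, got {labels.size}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in splitter.split(images, labels):
        model, _ = train_audio_model(
            images[train_idx], labels[train_idx], config=config, seed=seed,
            **train_kwargs,
        )
        pred = model.predict_proba(images[test_idx])[:, 1] > 0.5
        folds.append(metrics(confusion(pred, labels[test_idx] == 1)))
    average = {
        name: float(np.mean([getattr(ms, name) for ms in folds]))
        for name in METRIC_NAMES
    }
    return CVReport(k=k, folds=folds, average=average)


def save_audio_model(model: MobileNetV2, path) -> None:
    """Single-file checkpoint: config echo plus all weights and BN stats."""
    meta = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_arrays())


def load_audio_model(path) -> MobileNetV2:
    with np.load(path) as archive:
        raw = json.loads(archive["__config__"].tobytes().decode())
        raw["schedule"] = tuple(tuple(row) for row in raw["schedule"])
        model = MobileNetV2(MobileNetV2Config(**raw))
        model.load_state_arrays(
            {k: archive[k] for k in archive.files if k != "__config__"}
        )
    model.eval()
    return model
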