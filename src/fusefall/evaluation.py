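"""Confusion counts and the five detection metrics, with fall as positive.

Definitions: TP — fall correctly detected; TN — non-fall correctly detected;
FP — non-fall detected as fall; FN — fall detected as non-fall.  Metrics are
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total,
precision TP/(TP+FP), and F1 = 2TP/(2TP+FP+FN), reported as percentages to
two decimals (half-up) with full precision kept internally.  Undefined
ratios (zero denominator) are flagged explicitly rather than reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .skeleton import FALL, NOT_FALL

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "metrics"]

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    level: str = "video"  # "frame" or "video"

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_bool(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "iuf":
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"numeric labels must be 0/1, got {vals}")
        return arr.astype(bool)
    out = np.empty(arr.shape, dtype=bool)
    for idx, v in np.ndenumerate(arr):
        s = str(v)
        if s == FALL:
            out[idx] = True
        elif s in (NOT_FALL, "notfall", "not_fall"):
            out[idx] = False
        else:
            raise ValueError(f"unknown label {v!r}; expected fall / not-fall")
    return out


def confusion(predicted, truth, level: str = "video") -> ConfusionCounts:
    """Tally TP/FP/TN/FN from aligned predicted and true label lists."""
    pred = _as_bool(predicted)
    true = _as_bool(truth)
    if pred.shape != true.shape:
        raise ValueError(
            f"length mismatch: {pred.shape} predictions vs {true.shape} truths"
        )
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
        level=level,
    )


@dataclass(frozen=True)
class MetricSet:
    """The five metrics as percentages; NaN marks an undefined ratio."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float

    def undefined(self) -> set:
        return {k for k in METRIC_NAMES if math.isnan(getattr(self, k))}

    def rounded(self) -> dict:
        """Display form: half-up to 2 decimals; None where undefined."""
        out = {}
        for k in METRIC_NAMES:
            v = getattr(self, k)
            out[k] = (
                None
                if math.isnan(v)
                else float(Decimal(repr(v)).quantize(
                    Decimal("0.01"), rounding=ROUND_HALF_UP))
            )
        return out

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five ratios (percent) from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from zero events")
    return MetricSet(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )
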