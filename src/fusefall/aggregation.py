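"""Frame-level to video-level decision aggregation.

A clip is declared a fall when at least ``run_length`` (default 15)
consecutive frames are individually classified as fall.  The fall confidence
is the maximum, over qualifying (maximal) runs, of the mean frame probability
within the run.  For clips without a qualifying run the reported fall
probability is the maximum sliding-window mean of length ``run_length`` —
a package convention, since the source rule defines a confidence only for
detected falls; it keeps the video branch emitting a probability usable by
decision fusion for every clip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import FALL, NOT_FALL
from .stgcn import FramePredictions

__all__ = ["VideoDecision", "aggregate"]

DEFAULT_RUN_LENGTH = 15
DEFAULT_FRAME_THRESHOLD = 0.5


@dataclass
class VideoDecision:
    """Video-level label with the confidence used as the fusion input."""

    clip_id: str
    label: str
    confidence: float          # confidence in the emitted label
    fall_probability: float    # fall-class probability (fusion input a_m)
    run_start: int | None = None
    run_length: int | None = None


def _runs(mask: np.ndarray):
    """(start, length) of every maximal run of True values."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(mask) - start))
    return out


def aggregate(
    frames: FramePredictions,
    run_length: int = DEFAULT_RUN_LENGTH,
    frame_threshold: float = DEFAULT_FRAME_THRESHOLD,
) -> VideoDecision:
    """Apply the consecutive-frame rule to per-frame fall probabilities."""
    p = frames.probs
    if p.size < run_length:
        raise ValueError(
            f"need at least {run_length} frames, got {p.size}"
        )
    fall_frames = p > frame_threshold
    qualifying = [
        (s, ln) for s, ln in _runs(fall_frames) if ln >= run_length
    ]
    # Max mean probability over any window of run_length frames; this is the
    # fall probability reported for non-fall decisions.
    window_means = np.convolve(p, np.ones(run_length) / run_length, "valid")
    max_window_mean = float(window_means.max())
    if qualifying:
        means = [(float(p[s : s + ln].mean()), s, ln) for s, ln in qualifying]
        conf, s, ln = max(means)
        return VideoDecision(
            clip_id=frames.clip_id, label=FALL, confidence=conf,
            fall_probability=conf, run_start=s, run_length=ln,
        )
    return VideoDecision(
        clip_id=frames.clip_id, label=NOT_FALL,
        confidence=1.0 - max_window_mean,
        fall_probability=max_window_mean,
    )
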