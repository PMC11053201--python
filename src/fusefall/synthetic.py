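"""Synthetic paired skeleton/audio corpus with fall vs. daily-activity structure.

Each clip is 3 s: a 75-frame (25 fps) 17-joint keypoint track in 320x240
pixel coordinates and a mono 16 kHz waveform.  Content is controlled by a
scalar *severity* in [0, 1] that moves a clip monotonically from clearly
daily-activity to clearly fall-like:

- video: the hip descends by ``15 + 75·severity`` px over ``28 − 18·severity``
  frames (smoothstep profile) and the body axis rotates toward horizontal by
  up to 80 degrees; daily activities (walk, sit down, squat) occupy the low-
  severity regime (slow, small descent, upright torso), falls the high one.
- audio: a damped broadband impact transient (falls) or soft periodic
  footstep bumps (daily activity) over ambient noise, with amplitude growing
  with severity; falls are time-locked to the end of the skeletal descent.

Normal clips draw severity from class-specific ranges far from the midpoint
(falls U(0.75, 1), daily activity U(0.05, 0.25)), which makes the two
classes linearly separable in the (max hip descent rate, waveform crest
factor) plane; threshold oracles on those two features are provided.
Optional *modality error injection* replaces a clip's content in one
modality with opposite-class content drawn near (but across) the severity
midpoint: a classifier of that modality then mislabels the clip — with
moderate confidence, since the content sits near the class boundary — at a
rate matching the injection rate, while the other modality stays correct.
This creates the independent-error regime that decision fusion exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .audio import AudioClip, write_wav
from .skeleton import (
    FALL,
    LEFT_HIP,
    NOT_FALL,
    RIGHT_HIP,
    SkeletonSequence,
    write_sequence,
)

__all__ = [
    "SimConfig",
    "PairedClip",
    "SyntheticDataset",
    "gen_skeleton",
    "gen_audio",
    "gen_dataset",
    "max_descent_rate",
    "crest_factor",
    "oracle_video_label",
    "oracle_audio_label",
    "VIDEO_DESCENT_THRESHOLD",
    "AUDIO_CREST_THRESHOLD",
]

#: Standing template: joint offsets (x, y) in px relative to the hip midpoint
#: (y grows downward), COCO order.
TEMPLATE = np.array([
    (0.0, -62.0),                      # nose
    (3.0, -65.0), (-3.0, -65.0),       # eyes
    (6.0, -63.0), (-6.0, -63.0),       # ears
    (12.0, -45.0), (-12.0, -45.0),     # shoulders
    (16.0, -25.0), (-16.0, -25.0),     # elbows
    (18.0, -5.0), (-18.0, -5.0),       # wrists
    (8.0, 0.0), (-8.0, 0.0),           # hips
    (9.0, 28.0), (-9.0, 28.0),         # knees
    (10.0, 55.0), (-10.0, 55.0),       # ankles
])

ACTIVITIES = ("walk", "sit", "squat")

#: Oracle decision thresholds at the severity midpoint of the content model
#: (see docs/methods.md for the derivation).
VIDEO_DESCENT_THRESHOLD = 4.2   # px per frame, max hip descent rate
AUDIO_CREST_THRESHOLD = 19.0    # waveform peak / RMS


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_per_class: int = 130
    fps: float = 25.0
    duration: float = 3.0
    image_size: tuple = (320, 240)
    # skeleton kinematics
    fall_rotation_deg: float = 80.0
    descent_base_px: float = 15.0
    descent_span_px: float = 75.0
    descent_base_frames: float = 28.0
    descent_span_frames: float = 18.0
    fall_onset_min: int = 15
    coord_noise_px: float = 1.5
    score_dropout_rate: float = 0.03
    # audio
    sample_rate: int = 16000
    impact_snr_db: float = 25.0
    ambient_level: float = 0.01
    # coupling and error injection
    couple_audio: bool = True
    video_error_rate: float = 0.0
    audio_error_rate: float = 0.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))

    def __post_init__(self):
        for name in ("score_dropout_rate", "video_error_rate", "audio_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")


def _severity_range(content_is_fall: bool, near_boundary: bool):
    if near_boundary:
        return (0.56, 0.70) if content_is_fall else (0.30, 0.44)
    return (0.75, 1.0) if content_is_fall else (0.05, 0.25)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _descent_params(config: SimConfig, severity: float):
    amplitude = config.descent_base_px + config.descent_span_px * severity
    duration = int(round(config.descent_base_frames
                         - config.descent_span_frames * severity))
    return amplitude, max(duration, 2)


def gen_skeleton(
    label: str,
    config: SimConfig | None = None,
    seed: int = 0,
    severity: float | None = None,
    activity: str | None = None,
    extra_lean_deg: float = 0.0,
    clip_id: str = "synthetic",
) -> SkeletonSequence:
    """Generate one labeled 75-frame skeleton clip.

    ``label`` names the *content* class here ("fall" or "not-fall");
    ``severity`` overrides the class-conditional draw (used for
    near-boundary error injection).  ``extra_lean_deg`` adds a torso lean on
    top of the severity-driven rotation (ambiguous slumping-sit content).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    t_frames = config.n_frames
    is_fall = label == FALL
    if severity is None:
        severity = rng.uniform(*_severity_range(is_fall, near_boundary=False))
    if activity is None:
        activity = "fall" if is_fall else rng.choice(ACTIVITIES)

    person_scale = rng.uniform(0.9, 1.1)
    x0 = rng.uniform(120.0, 200.0)
    y0 = rng.uniform(130.0, 150.0)
    vx = rng.uniform(-1.2, 1.2)

    amplitude, dur = _descent_params(config, severity)
    onset_max = max(config.fall_onset_min + 1, t_frames - dur - 5)
    onset = int(rng.integers(config.fall_onset_min, onset_max))

    t = np.arange(t_frames)
    # descent profile in [0, 1]; squats come back up after a short hold
    profile = _smoothstep((t - onset) / dur)
    if activity == "squat":
        hold_end = onset + dur + 8
        profile = profile * 1.0
        rise = _smoothstep((t - hold_end) / dur)
        profile = np.clip(profile - rise, 0.0, 1.0)

    hip_x = x0 + vx * t if activity in ("walk", "fall") else np.full(t_frames, x0)
    hip_y = y0 + (amplitude * profile if activity != "walk" else 0.0)
    if activity == "walk":
        hip_y = y0 + 1.5 * np.sin(2 * np.pi * 1.5 * t / config.fps)

    # body-axis rotation toward horizontal, ramped with the descent profile
    rot_max = np.deg2rad(
        max(0.0, (severity - 0.2) / 0.8) * config.fall_rotation_deg
        + extra_lean_deg
    ) * (0.0 if activity == "walk" else 1.0)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    angle = sign * rot_max * profile

    offsets = np.broadcast_to(TEMPLATE * person_scale, (t_frames, 17, 2)).copy()
    if activity == "walk":
        swing = 5.0 * np.sin(2 * np.pi * 1.5 * t / config.fps)
        for j, phase in ((13, 0.0), (14, np.pi), (15, 0.0), (16, np.pi),
                         (9, np.pi), (10, 0.0)):
            offsets[:, j, 0] += swing * np.cos(phase)
    elif activity in ("sit", "squat"):
        offsets[:, (13, 14), 0] += 8.0 * profile[:, None]  # knees forward

    cos_a, sin_a = np.cos(angle), np.sin(angle)
    rot = np.empty((t_frames, 2, 2))
    rot[:, 0, 0] = cos_a
    rot[:, 0, 1] = -sin_a
    rot[:, 1, 0] = sin_a
    rot[:, 1, 1] = cos_a
    coords = np.einsum("tab,tjb->tja", rot, offsets)
    coords[:, :, 0] += hip_x[:, None]
    coords[:, :, 1] += hip_y[:, None]
    coords += rng.normal(0.0, config.coord_noise_px, size=coords.shape)

    scores = rng.uniform(0.7, 0.95, size=(t_frames, 17))
    dropout = rng.random((t_frames, 17)) < config.score_dropout_rate
    scores[dropout] = rng.uniform(0.0, 0.04, size=int(dropout.sum()))

    return SkeletonSequence(
        clip_id=clip_id,
        fps=config.fps,
        keypoints=np.concatenate([coords, scores[:, :, None]], axis=2),
        label=label,
    )


def _transient(rng, n, start, tau_s, amp, sr, lowpass_hz=None):
    """Damped noise burst; optionally band-limited (soft, muffled thud)."""
    length = min(n - start, int(6 * tau_s * sr))
    carrier = rng.normal(0.0, 1.0, size=length)
    if lowpass_hz is not None and length > 24:
        sos = signal.butter(4, lowpass_hz, "low", fs=sr, output="sos")
        carrier = signal.sosfilt(sos, carrier)
        sd = carrier.std()
        if sd > 0:
            carrier = carrier / sd
    env = amp * np.exp(-np.arange(length) / (tau_s * sr))
    return start, env * carrier


def gen_audio(
    label: str,
    config: SimConfig | None = None,
    seed: int = 0,
    severity: float | None = None,
    impact_frame: int | None = None,
    ambiguous: bool = False,
    clip_id: str = "synthetic",
) -> AudioClip:
    """Generate one labeled 3 s audio clip (content class semantics as in
    :func:`gen_skeleton`).

    ``ambiguous`` produces borderline content: a fall becomes a muffled
    band-limited thud (still transient-peaked); daily activity gains one
    faint sharp stumble among the footsteps.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    sr = config.sample_rate
    n = int(round(sr * config.duration))
    is_fall = label == FALL
    if severity is None:
        severity = rng.uniform(*_severity_range(is_fall, ambiguous))
    x = rng.normal(0.0, config.ambient_level, size=n)
    amp = config.ambient_level * (
        1.0 + severity * (10.0 ** (config.impact_snr_db / 20.0) - 1.0)
    )
    if is_fall:
        if impact_frame is not None:
            start = int(impact_frame / config.fps * sr)
        else:
            start = int(rng.uniform(0.8, 2.2) * sr)
        start = min(max(start, 0), n - 1)
        tau = 0.08 - 0.055 * severity
        s0, burst = _transient(
            rng, n, start, tau, amp, sr,
            lowpass_hz=800.0 if ambiguous else None,
        )
        x[s0 : s0 + burst.size] += burst
    else:
        period = rng.uniform(0.5, 0.7)
        t0 = rng.uniform(0.0, period)
        step_len = int(0.03 * sr)
        env = np.sin(np.pi * np.arange(step_len) / step_len)
        while t0 < config.duration:
            start = int(t0 * sr)
            stop = min(start + step_len, n)
            x[start:stop] += (
                amp * env[: stop - start] * rng.normal(0.0, 1.0, size=stop - start)
            )
            t0 += period
        if ambiguous:  # one faint, sharper stumble among the steps
            s0, burst = _transient(
                rng, n, int(rng.uniform(0.5, 2.4) * sr), 0.02, 1.2 * amp, sr
            )
            x[s0 : s0 + burst.size] += burst
    return AudioClip(samples=x, sample_rate=sr, clip_id=clip_id, label=label)


# ---------------------------------------------------------------------------
# Paired corpus
# ---------------------------------------------------------------------------


@dataclass
class PairedClip:
    clip_id: str
    label: str
    skeleton: SkeletonSequence
    audio: AudioClip
    activity: str
    video_severity: float
    audio_severity: float
    video_flipped: bool = False
    audio_flipped: bool = False
    impact_frame: int | None = None


@dataclass
class SyntheticDataset:
    clips: list
    config: SimConfig

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clip_id": c.clip_id,
                    "label": c.label,
                    "activity": c.activity,
                    "video_severity": round(c.video_severity, 4),
                    "audio_severity": round(c.audio_severity, 4),
                    "video_flipped": c.video_flipped,
                    "audio_flipped": c.audio_flipped,
                    "impact_frame": c.impact_frame,
                }
                for c in self.clips
            ]
        )

    def labels(self) -> np.ndarray:
        """Binary labels (1 = fall) in clip order."""
        return np.array([1 if c.label == FALL else 0 for c in self.clips])

    def write(self, directory) -> None:
        """Keypoint JSON + WAV + manifest CSV layout consumed by the CLI."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in self.clips:
            write_sequence(c.skeleton, directory / f"{c.clip_id}.json")
            write_wav(c.audio, directory / f"{c.clip_id}.wav")
        self.manifest().to_csv(directory / "manifest.csv", index=False)


def _descent_end_frame(config: SimConfig, seq: SkeletonSequence) -> int:
    hip_y = seq.keypoints[:, (LEFT_HIP, RIGHT_HIP), 1].mean(axis=1)
    return int(np.argmax(hip_y >= hip_y[0] + 0.9 * (hip_y.max() - hip_y[0])))


def gen_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate the paired corpus: n fall + n non-fall clips, exact balance.

    With nonzero modality error rates, each clip independently has its video
    (resp. audio) content replaced by near-boundary opposite-class content
    with the stated probability; flips are recorded in the manifest.
    """
    config = config or SimConfig()
    root = np.random.SeedSequence(config.seed)
    flip_rng = np.random.default_rng(root.spawn(1)[0])
    clips: list[PairedClip] = []
    n = config.n_per_class
    for i in range(2 * n):
        label = FALL if i < n else NOT_FALL
        clip_id = f"clip_{i:04d}"
        seeds = np.random.SeedSequence([config.seed, 7, i]).generate_state(4)
        video_flipped = bool(flip_rng.random() < config.video_error_rate)
        audio_flipped = bool(flip_rng.random() < config.audio_error_rate)

        v_is_fall = (label == FALL) != video_flipped
        a_is_fall = (label == FALL) != audio_flipped
        v_rng = np.random.default_rng(seeds[0])
        a_rng = np.random.default_rng(seeds[1])
        v_sev = v_rng.uniform(*_severity_range(v_is_fall, video_flipped))
        a_sev = a_rng.uniform(*_severity_range(a_is_fall, audio_flipped))
        v_label = FALL if v_is_fall else NOT_FALL
        a_label = FALL if a_is_fall else NOT_FALL
        # near-boundary daily activity must resemble a fall: flipped non-fall
        # video content is a slumping sit-down (descent plus a torso lean in
        # the gap between upright daily motion and full falls)
        activity = None
        lean = 0.0
        if video_flipped and not v_is_fall:
            activity = "sit"
            lean = float(np.random.default_rng(seeds[0] + 1).uniform(32.0, 46.0))

        skeleton = gen_skeleton(
            v_label, config, seed=seeds[2], severity=v_sev,
            activity=activity, extra_lean_deg=lean, clip_id=clip_id,
        )
        impact = (
            _descent_end_frame(config, skeleton)
            if (v_is_fall and a_is_fall and config.couple_audio)
            else None
        )
        audio_clip = gen_audio(
            a_label, config, seed=seeds[3], severity=a_sev,
            impact_frame=impact, ambiguous=audio_flipped, clip_id=clip_id,
        )
        # the pair carries the clip-level ground truth, not the content class
        skeleton.label = label
        audio_clip.label = label
        clips.append(
            PairedClip(
                clip_id=clip_id, label=label,
                skeleton=skeleton, audio=audio_clip,
                activity=activity or ("fall" if v_is_fall else "daily"),
                video_severity=v_sev, audio_severity=a_sev,
                video_flipped=video_flipped, audio_flipped=audio_flipped,
                impact_frame=impact,
            )
        )
    return SyntheticDataset(clips=clips, config=config)


# ---------------------------------------------------------------------------
# Feature oracles
# ---------------------------------------------------------------------------


def max_descent_rate(seq: SkeletonSequence, window: int = 4) -> float:
    """Max hip-midpoint downward velocity (px/frame) over a short window."""
    hip_y = seq.keypoints[:, (LEFT_HIP, RIGHT_HIP), 1].mean(axis=1)
    if hip_y.size <= window:
        return 0.0
    return float(np.max((hip_y[window:] - hip_y[:-window]) / window))


def crest_factor(clip: AudioClip) -> float:
    """Waveform peak-to-RMS ratio; impact transients push this up."""
    rms = np.sqrt(np.mean(clip.samples**2))
    return float(np.max(np.abs(clip.samples)) / rms) if rms > 0 else 0.0


def oracle_video_label(seq: SkeletonSequence,
                       threshold: float = VIDEO_DESCENT_THRESHOLD) -> str:
    return FALL if max_descent_rate(seq) > threshold else NOT_FALL


def oracle_audio_label(clip: AudioClip,
                       threshold: float = AUDIO_CREST_THRESHOLD) -> str:
    return FALL if crest_factor(clip) > threshold else NOT_FALL
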