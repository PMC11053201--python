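"""Audio preprocessing, augmentation, and log-mel feature extraction.

Fall sounds are short broadband impact transients over ambient room noise,
which separates them from daily-activity audio in a log-scaled mel
spectrogram.  The preprocessing chain is: an automatic energy-gate trim that
removes leading/trailing low-energy regions (replacing any manual clip
clean-up), optional augmentation (white noise at a target SNR, time-domain
lengthening/shortening, volume up/down), and mel-filterbank log-power
features resized to the square single-channel grid the CNN classifier
expects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile

from .skeleton import UNKNOWN

__all__ = [
    "AudioClip",
    "MelParams",
    "MelSpectrogram",
    "read_wav",
    "write_wav",
    "energy_gate_trim",
    "augment",
    "expand_dataset",
    "logmel",
    "to_image",
    "AUGMENT_METHODS",
]

AUGMENT_METHODS = (
    "white_noise", "stretch_longer", "stretch_shorter", "volume_up", "volume_down",
)

#: Default augmentation strengths.
NOISE_SNR_DB = 20.0
STRETCH_LONGER_FACTOR = 1.2
STRETCH_SHORTER_FACTOR = 0.8
GAIN_DB = 6.0


@dataclass
class AudioClip:
    """Mono waveform in [-1, 1] with metadata."""

    samples: np.ndarray
    sample_rate: int
    clip_id: str = ""
    label: str = UNKNOWN
    trim_failed: bool = False  # set when an energy trim found only silence

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def read_wav(path, clip_id: str | None = None, label: str = UNKNOWN) -> AudioClip:
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:  # downmix to mono
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioClip(
        samples=data.astype(float), sample_rate=int(sr),
        clip_id=clip_id or str(path), label=label,
    )


def write_wav(clip: AudioClip, path) -> None:
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (x * 32767).astype(np.int16))


def _frame_rms(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    if x.size < frame:
        return np.array([np.sqrt(np.mean(x**2))]) if x.size else np.zeros(1)
    windows = np.lib.stride_tricks.sliding_window_view(x, frame)[::hop]
    return np.sqrt(np.mean(windows**2, axis=1))


def energy_gate_trim(
    clip: AudioClip,
    threshold_db: float = -40.0,
    pad_ms: float = 100.0,
    frame: int = 512,
    hop: int = 128,
) -> AudioClip:
    """Drop leading/trailing audio below ``threshold_db`` relative to peak.

    The retained region is padded by ``pad_ms`` on both sides.  An all-silent
    clip is returned unchanged with ``trim_failed`` set, so the result is
    never empty.
    """
    if clip.samples.size == 0:
        raise ValueError("empty clip")
    rms = _frame_rms(clip.samples, frame, hop)
    peak = rms.max()
    if peak <= 0:
        return replace(clip, trim_failed=True)
    active = np.flatnonzero(20.0 * np.log10(rms / peak + 1e-300) > threshold_db)
    pad = int(round(pad_ms * 1e-3 * clip.sample_rate))
    start = max(0, active[0] * hop - pad)
    stop = min(clip.samples.size, active[-1] * hop + frame + pad)
    return replace(clip, samples=clip.samples[start:stop], trim_failed=False)


def _stretch(x: np.ndarray, factor: float) -> np.ndarray:
    """Resample-based time-domain stretch (duration scales by ``factor``)."""
    n_out = max(2, int(round(x.size * factor)))
    src = np.linspace(0.0, x.size - 1.0, n_out)
    return np.interp(src, np.arange(x.size), x)


def augment(clip: AudioClip, method: str, seed: int = 0) -> AudioClip:
    """Apply one of the five label-preserving augmentations.

    white_noise adds Gaussian noise at 20 dB SNR; the stretches rescale the
    time axis by 1.2 / 0.8; the volume methods apply ±6 dB gain.
    """
    if method not in AUGMENT_METHODS:
        raise ValueError(
            f"unknown augmentation {method!r}; expected one of {AUGMENT_METHODS}"
        )
    x = clip.samples
    if method == "white_noise":
        rng = np.random.default_rng(seed)
        p_signal = np.mean(x**2)
        sigma = np.sqrt(p_signal / 10.0 ** (NOISE_SNR_DB / 10.0))
        y = x + rng.normal(0.0, sigma, size=x.size)
    elif method == "stretch_longer":
        y = _stretch(x, STRETCH_LONGER_FACTOR)
    elif method == "stretch_shorter":
        y = _stretch(x, STRETCH_SHORTER_FACTOR)
    elif method == "volume_up":
        y = x * 10.0 ** (GAIN_DB / 20.0)
    else:  # volume_down
        y = x * 10.0 ** (-GAIN_DB / 20.0)
    return replace(clip, samples=y, clip_id=f"{clip.clip_id}#{method}")


def expand_dataset(
    clips: list[AudioClip], methods=AUGMENT_METHODS, seed: int = 0
) -> list[AudioClip]:
    """Originals plus one clip per augmentation method (6x with all five)."""
    out: list[AudioClip] = []
    for i, clip in enumerate(clips):
        out.append(clip)
        for j, method in enumerate(methods):
            out.append(augment(clip, method, seed=seed * 1_000_003 + i * 101 + j))
    return out


# ---------------------------------------------------------------------------
# Log-mel spectrograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MelParams:
    n_fft: int = 1024
    hop: int = 512
    n_mels: int = 64
    fmin: float = 0.0
    fmax: float | None = None  # defaults to Nyquist
    floor: float = 1e-10       # power floor ε before the log


@dataclass
class MelSpectrogram:
    """log10 mel power matrix (n_mels, n_frames) plus extraction params."""

    matrix: np.ndarray
    params: MelParams
    sample_rate: int
    clip_id: str = ""
    label: str = UNKNOWN


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft // 2 + 1)."""
    fmax = fmax or sample_rate / 2.0
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    freqs = np.linspace(0.0, sample_rate / 2.0, n_fft // 2 + 1)
    fb = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, center, hi = hz_pts[i : i + 3]
        rising = (freqs - lo) / max(center - lo, 1e-12)
        falling = (hi - freqs) / max(hi - center, 1e-12)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def logmel(clip: AudioClip, params: MelParams | None = None) -> MelSpectrogram:
    """Log-scaled mel spectrogram of a clip (frames start at sample 0,
    no center padding): n_frames = 1 + (L - n_fft) // hop."""
    params = params or MelParams()
    x = clip.samples
    if x.size < params.n_fft:
        raise ValueError(
            f"clip of {x.size} samples is shorter than one FFT window "
            f"({params.n_fft})"
        )
    window = np.hanning(params.n_fft)
    frames = np.lib.stride_tricks.sliding_window_view(x, params.n_fft)[:: params.hop]
    spec = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2  # (frames, bins)
    fb = mel_filterbank(
        clip.sample_rate, params.n_fft, params.n_mels, params.fmin, params.fmax
    )
    mel_power = fb @ spec.T  # (n_mels, frames)
    return MelSpectrogram(
        matrix=np.log10(np.maximum(mel_power, params.floor)),
        params=params,
        sample_rate=clip.sample_rate,
        clip_id=clip.clip_id,
        label=clip.label,
    )


def _resize_bilinear(m: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize with exact output shape."""
    h, w = m.shape
    rows = np.linspace(0.0, h - 1.0, out_h)
    cols = np.linspace(0.0, w - 1.0, out_w)
    tmp = np.empty((out_h, w))
    src_rows = np.arange(h, dtype=float)
    for j in range(w):
        tmp[:, j] = np.interp(rows, src_rows, m[:, j])
    out = np.empty((out_h, out_w))
    src_cols = np.arange(w, dtype=float)
    for i in range(out_h):
        out[i] = np.interp(cols, src_cols, tmp[i])
    return out


def to_image(
    spec: MelSpectrogram, size: int = 224, standardize: bool = True
) -> np.ndarray:
    """Resize a mel matrix to the classifier's square single-channel grid.

    Per-image standardization (zero mean, unit variance) puts clips recorded
    at different levels on a comparable scale for training.
    """
    img = _resize_bilinear(spec.matrix, size, size)
    if standardize:
        sd = img.std()
        img = (img - img.mean()) / (sd if sd > 1e-12 else 1.0)
    return img[None, :, :]  # (1, size, size)
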