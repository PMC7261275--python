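"""Log-mel spectrogram front-end and fixed-size auditory-image rendering.

The pipeline turns each analysis window into a normalized "auditory image"
for a convolutional feature extractor:

1. STFT with a Hann window of ``n_fft`` samples and hop ``hop``.
2. Power spectrogram on a decibel scale, ``10 * log10(|X|^2)``, floored.
3. Triangular mel filterbank with corner points evenly spaced on the mel
   scale ``f_mel = 2595 * log10(1 + f / 700)`` between ``f_min`` and
   ``f_max``. A hard low-cut of broadband environmental noise is realized
   by setting ``f_min`` to 2 kHz.
4. Global z-normalization ``(X - mu) / sigma`` with statistics fitted on a
   reference split, then bilinear resize to ``image_size`` square, gray
   values replicated across 3 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import zoom

from .preprocessing import WindowedSegment

__all__ = [
    "SpectrogramConfig",
    "LogMelSpectrogram",
    "NormalizationStats",
    "AuditoryImage",
    "hann",
    "stft",
    "power_to_db",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "log_mel",
    "fit_normalization",
    "render_image",
]


@dataclass(frozen=True)
class SpectrogramConfig:
    """All front-end parameters.

    Defaults are the study conditions: 2048-sample FFT frames with hop 512
    (75% frame overlap), 256 mel bands over 0–11025 Hz, 299-pixel square
    images, −80 dB numerical floor. ``window_ms``/``overlap`` describe the
    outer analysis window the clip is cut into before any STFT.
    """

    n_fft: int = 2048
    hop: int = 512
    n_mels: int = 256
    f_min: float = 0.0
    f_max: float = 11025.0
    sample_rate: int = 44100
    image_size: int = 299
    db_floor: float = -80.0
    window_ms: float = 500.0
    overlap: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_min < self.f_max <= self.sample_rate / 2.0:
            raise ValueError("require 0 <= f_min < f_max <= sample_rate/2")
        if self.hop > self.n_fft:
            raise ValueError("hop must not exceed n_fft")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")

    def with_(self, **kwargs) -> "SpectrogramConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "n_fft": self.n_fft, "hop": self.hop, "n_mels": self.n_mels,
            "f_min": self.f_min, "f_max": self.f_max,
            "sample_rate": self.sample_rate, "image_size": self.image_size,
            "db_floor": self.db_floor, "window_ms": self.window_ms,
            "overlap": self.overlap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectrogramConfig":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


@dataclass(frozen=True)
class LogMelSpectrogram:
    """Mel-band x frame matrix in dB, floored at ``config.db_floor``."""

    values: np.ndarray
    config: SpectrogramConfig
    segment_ref: str = ""


@dataclass(frozen=True)
class NormalizationStats:
    """Global scalar mean/std (population convention) in dB."""

    mean: float
    std: float
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("std must be positive")


@dataclass(frozen=True)
class AuditoryImage:
    """Normalized image_size x image_size x 3 rendering; the three
    channels are identical (grayscale replication)."""

    pixels: np.ndarray
    segment_ref: str = ""


def hann(M: int) -> np.ndarray:
    """Symmetric Hann window w[n] = (1 - cos(2*pi*n/(M-1))) / 2."""
    if M < 2:
        raise ValueError("Hann window needs M >= 2")
    n = np.arange(M, dtype=np.float64)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (M - 1)))


def stft(segment: WindowedSegment | np.ndarray, config: SpectrogramConfig) -> np.ndarray:
    """Short-time Fourier transform of a segment.

    Frame j covers samples [j*hop, j*hop + n_fft); each frame is tapered
    with a Hann window before the transform. Returns the complex
    one-sided spectrum, shape (n_fft // 2 + 1, n_frames).
    """
    x = segment.samples if isinstance(segment, WindowedSegment) else np.asarray(segment, float)
    if len(x) < config.n_fft:
        raise ValueError(f"segment length {len(x)} shorter than n_fft {config.n_fft}")
    frames = sliding_window_view(x, config.n_fft)[:: config.hop]
    w = hann(config.n_fft)
    return np.fft.rfft(frames * w, axis=1).T


def power_to_db(X: np.ndarray, db_floor: float = -80.0) -> np.ndarray:
    """Map magnitudes to decibels: 10*log10(max(X^2, eps)).

    eps = 10**(db_floor/10) makes the floor exact: zero magnitude maps to
    db_floor, never -inf.
    """
    X = np.asarray(X, dtype=np.float64)
    eps = 10.0 ** (db_floor / 10.0)
    return 10.0 * np.log10(np.maximum(X * X, eps))


def hz_to_mel(f: float | np.ndarray) -> np.ndarray:
    """Perceptual mel scale: 2595 * log10(1 + f / 700).

    The 2595 constant calibrates the map so 1000 Hz is 1000 mel. The
    HTK-style logarithmic form is used throughout (no linear segment
    below 1 kHz).
    """
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m: float | np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(config: SpectrogramConfig) -> np.ndarray:
    """Triangular filters evenly spaced on the mel scale.

    Corner points of the ``n_mels`` triangles are ``n_mels + 2`` frequencies
    equally spaced in mel between ``f_min`` and ``f_max``. Triangles have
    unnormalized peak height 1 (global scale is absorbed by the
    normalization statistics). FFT bins above ``f_max`` get zero weight.

    At fine mel spacing a triangle can fall entirely between two FFT bin
    centers; such a filter is snapped to the single bin nearest its
    center so every band stays responsive. The band count is rejected
    only when it exceeds the number of FFT bins inside [f_min, f_max].

    Returns (n_mels, n_fft // 2 + 1).
    """
    n_bins = config.n_fft // 2 + 1
    fft_freqs = np.arange(n_bins) * config.sample_rate / config.n_fft
    in_range = int(np.sum((fft_freqs >= config.f_min) & (fft_freqs <= config.f_max)))
    if config.n_mels > in_range:
        raise ValueError(
            f"n_mels={config.n_mels} exceeds the {in_range} FFT bins inside "
            f"[{config.f_min}, {config.f_max}] Hz at n_fft={config.n_fft}"
        )
    mel_pts = np.linspace(
        float(hz_to_mel(config.f_min)), float(hz_to_mel(config.f_max)), config.n_mels + 2
    )
    hz_pts = mel_to_hz(mel_pts)
    lower, center, upper = hz_pts[:-2], hz_pts[1:-1], hz_pts[2:]
    up = (fft_freqs[None, :] - lower[:, None]) / (center - lower)[:, None]
    down = (upper[:, None] - fft_freqs[None, :]) / (upper - center)[:, None]
    fb = np.maximum(0.0, np.minimum(up, down))
    fb[:, fft_freqs > config.f_max] = 0.0
    empty = np.flatnonzero(fb.sum(axis=1) == 0)
    if len(empty):
        nearest = np.abs(fft_freqs[None, :] - center[empty, None]).argmin(axis=1)
        fb[empty, nearest] = 1.0
    return fb


def log_mel(segment: WindowedSegment, config: SpectrogramConfig) -> LogMelSpectrogram:
    """Full front-end for one analysis window: STFT -> mel power -> dB.

    The mel filterbank is applied to the squared-magnitude spectrum, then
    the result is mapped to decibels and floored. Output shape is
    (n_mels, floor((len - n_fft) / hop) + 1).
    """
    X = stft(segment, config)
    power = np.abs(X) ** 2
    mel_power = _cached_filterbank(config) @ power
    eps = 10.0 ** (config.db_floor / 10.0)
    values = 10.0 * np.log10(np.maximum(mel_power, eps))
    ref = getattr(segment, "parent_id", "") or ""
    start = getattr(segment, "start_ms", None)
    seg_id = f"{ref}@{start:.1f}ms" if start is not None else ref
    return LogMelSpectrogram(values=values, config=config, segment_ref=seg_id)


_FB_CACHE: dict = {}


def _cached_filterbank(config: SpectrogramConfig) -> np.ndarray:
    key = (config.n_fft, config.n_mels, config.f_min, config.f_max, config.sample_rate)
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(config)
    return _FB_CACHE[key]


def fit_normalization(
    spectrograms: Iterable[LogMelSpectrogram], fitted_on: str = ""
) -> NormalizationStats:
    """Scalar mean/std over every cell of every spectrogram.

    Population (divide-by-N) standard deviation. Raises on an empty
    collection or zero variance (a degenerate, constant dataset).
    """
    specs: List[LogMelSpectrogram] = list(spectrograms)
    if not specs:
        raise ValueError("cannot fit normalization on an empty collection")
    total = sum(s.values.size for s in specs)
    mean = sum(float(s.values.sum()) for s in specs) / total
    var = sum(float(((s.values - mean) ** 2).sum()) for s in specs) / total
    if var <= 0.0:
        raise ValueError("zero variance: all spectrogram values identical")
    return NormalizationStats(mean=mean, std=float(np.sqrt(var)), fitted_on=fitted_on)


def render_image(
    spec: LogMelSpectrogram, stats: NormalizationStats, image_size: int | None = None
) -> AuditoryImage:
    """Normalize, bilinearly resize to a square, replicate to 3 channels.

    Row 0 of the output is the HIGHEST mel band: the image follows the
    plotting convention of low frequency at the bottom. Bilinear
    interpolation preserves constant fields and does not wrap bands.
    """
    size = image_size if image_size is not None else spec.config.image_size
    z = (spec.values - stats.mean) / stats.std
    n_mels, n_frames = z.shape
    resized = zoom(
        z, (size / n_mels, size / n_frames), order=1, grid_mode=True, mode="nearest"
    )
    resized = resized[::-1, :]  # low frequency at the bottom
    pixels = np.repeat(resized[:, :, None], 3, axis=2)
    return AuditoryImage(pixels=pixels, segment_ref=spec.segment_ref)
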