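"""Waveform ingestion and canonicalization.

Every downstream stage assumes mono float audio in [-1, 1] at a canonical
sample rate of 44.1 kHz (the rate the surgical recordings are made at).
This module reads/writes PCM WAV, averages multi-channel material to mono,
and resamples with a polyphase filter.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "CANONICAL_RATE",
    "AudioClip",
    "AudioIOError",
    "MissingFileError",
    "NotAWavError",
    "EmptyAudioError",
    "PeakOverflowError",
    "read_wav",
    "write_wav",
    "resample",
]

CANONICAL_RATE = 44100


class AudioIOError(Exception):
    """Base class for audio ingestion failures."""


class MissingFileError(AudioIOError):
    """The requested path does not exist."""


class NotAWavError(AudioIOError):
    """The file exists but is not a readable PCM WAV."""


class EmptyAudioError(AudioIOError):
    """The WAV contains zero samples."""


class PeakOverflowError(AudioIOError):
    """Refusing to write samples whose magnitude exceeds full scale."""


@dataclass(frozen=True)
class AudioClip:
    """A mono waveform with its sample rate and provenance.

    samples are float64 in [-1, 1]; ``duration_ms`` is derived from the
    sample count, never stored independently.
    """

    samples: np.ndarray
    sample_rate: int = CANONICAL_RATE
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioClip requires a 1-D (mono) sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioClip samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM WAV into a mono, [-1, 1]-scaled :class:`AudioClip`.

    Multi-channel input is averaged to a single channel (arithmetic mean).
    Integer PCM of any depth is scaled by its full-scale value; float WAV
    is taken as-is then clipped to [-1, 1].
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises ValueError on malformed RIFF
        raise NotAWavError(f"not a readable PCM WAV: {path}") from exc
    if data.size == 0:
        raise EmptyAudioError(f"zero-length audio: {path}")
    if np.issubdtype(data.dtype, np.integer):
        # scipy justifies sub-32-bit PCM to the most significant bits of the
        # container dtype, so full scale is 2**(bits-1) of the container.
        full_scale = float(2 ** (8 * data.dtype.itemsize - 1))
        samples = data.astype(np.float64) / full_scale
    elif data.dtype == np.uint8:  # pragma: no cover - 8-bit offset binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioClip(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(clip: AudioClip, path: str | Path, bit_depth: int = 16) -> None:
    """Write a clip as mono PCM WAV at 16 or 24 bit.

    Raises :class:`PeakOverflowError` if any sample exceeds full scale:
    silent clipping would corrupt the spectral content downstream stages
    measure.
    """
    if bit_depth not in (16, 24):
        raise ValueError(f"bit_depth must be 16 or 24, got {bit_depth}")
    peak = float(np.max(np.abs(clip.samples))) if len(clip) else 0.0
    if peak > 1.0:
        raise PeakOverflowError(f"peak magnitude {peak:.4f} exceeds 1.0; refusing to clip")
    path = Path(path)
    # scale by 2**(bits-1) (matching read_wav) and clip the single top code
    if bit_depth == 16:
        pcm = np.clip(np.round(clip.samples * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(str(path), clip.sample_rate, pcm)
    else:
        ints = np.clip(np.round(clip.samples * 2**23), -(2**23), 2**23 - 1).astype(np.int64)
        raw = bytearray()
        for v in ints:
            raw += int(v & 0xFFFFFF).to_bytes(3, "little")
        with wave.open(str(path), "wb") as fh:
            fh.setnchannels(1)
            fh.setsampwidth(3)
            fh.setframerate(clip.sample_rate)
            fh.writeframes(bytes(raw))


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Resample to ``target_rate`` with a polyphase anti-aliasing filter.

    Duration is preserved within one sample period; a clip already at the
    target rate is returned unchanged.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == clip.sample_rate:
        return clip
    g = np.gcd(int(target_rate), int(clip.sample_rate))
    up, down = target_rate // g, clip.sample_rate // g
    out = resample_poly(clip.samples, up, down)
    out = np.clip(out, -1.0, 1.0)
    return AudioClip(samples=out, sample_rate=int(target_rate), source_id=clip.source_id)
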