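"""Sliding-window segmentation and narrowband alarm-tone suppression.

Electrosurgical generators emit mandatory activation/alarm tones — pure
sines at 2020/3035 Hz in cutting mode and 1380/2270 Hz in coagulation
mode — superimposed on the tissue sound. A cascade of second-order IIR
notch filters can remove them before spectral analysis; it is off by
default in the pipeline because removing the tones was not observed to
help classification, but remains available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.signal import iirnotch, lfilter

from .audio_io import AudioClip

__all__ = [
    "CUTTING_ALARM_HZ",
    "COAGULATION_ALARM_HZ",
    "WindowedSegment",
    "NotchSpec",
    "slide_windows",
    "apply_notch",
]

CUTTING_ALARM_HZ = (2020.0, 3035.0)
COAGULATION_ALARM_HZ = (1380.0, 2270.0)


@dataclass(frozen=True)
class WindowedSegment:
    """A fixed-length analysis window cut from a parent clip."""

    samples: np.ndarray
    start_ms: float
    window_ms: float
    parent_id: str = ""
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))


@dataclass(frozen=True)
class NotchSpec:
    """Center frequencies and shared quality factor of a notch cascade.

    Q = 30 by default: the alarm tones are pure sines, so a narrow notch
    removes them while leaving neighboring broadband diathermy content
    essentially untouched.
    """

    center_freqs: Sequence[float] = field(
        default_factory=lambda: CUTTING_ALARM_HZ + COAGULATION_ALARM_HZ
    )
    quality_factor: float = 30.0


def slide_windows(
    clip: AudioClip, window_ms: float, overlap_frac: float
) -> List[WindowedSegment]:
    """Cut a clip into fixed-length windows with fractional overlap.

    A rectangular window of ``window_ms`` slides from the clip start with
    hop ``window_ms * (1 - overlap_frac)``; trailing material that does not
    fill a whole window is discarded (the image-rendering stage requires
    fixed-size inputs). A clip shorter than one window yields no segments.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    sr = clip.sample_rate
    win_n = int(round(window_ms / 1000.0 * sr))
    hop_ms = window_ms * (1.0 - overlap_frac)
    segments: List[WindowedSegment] = []
    k = 0
    while True:
        start_ms = k * hop_ms
        start_n = int(round(start_ms / 1000.0 * sr))
        if start_n + win_n > len(clip.samples):
            break
        segments.append(
            WindowedSegment(
                samples=clip.samples[start_n : start_n + win_n],
                start_ms=start_ms,
                window_ms=window_ms,
                parent_id=clip.source_id,
                sample_rate=sr,
            )
        )
        k += 1
    return segments


def apply_notch(clip: AudioClip, spec: NotchSpec) -> AudioClip:
    """Suppress narrowband tones with a cascade of second-order notches.

    One biquad per center frequency, applied in sequence; output has the
    same length and sample rate as the input.
    """
    nyquist = clip.sample_rate / 2.0
    for f0 in spec.center_freqs:
        if not 0.0 < f0 < nyquist:
            raise ValueError(f"notch frequency {f0} Hz outside (0, Nyquist={nyquist})")
    y = clip.samples
    for f0 in spec.center_freqs:
        b, a = iirnotch(f0, spec.quality_factor, fs=clip.sample_rate)
        y = lfilter(b, a, y)
    return AudioClip(samples=np.clip(y, -1.0, 1.0), sample_rate=clip.sample_rate,
                     source_id=clip.source_id)
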