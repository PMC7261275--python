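"""Synthetic surgical-audio generator.

No public recording of intra-abdominal diathermy sound exists, so this
module generates labeled datasets with the statistical structure the
classifier assumes: each (tissue, operation-mode) class is a stationary
sound texture — white noise shaped by a few resonant spectral peaks plus
Poisson-process crackle transients — contaminated by the electrosurgical
generator's alarm tones (pure sines at 2020/3035 Hz in cutting mode,
1380/2270 Hz in coagulation mode) and 1/f environmental noise below
2 kHz. An ``idle`` class carries only the environmental noise floor.

The generator makes no claim to physical realism of tissue vaporization
acoustics; it targets the contract the pipeline needs — class-conditional
spectral envelopes with a controllable separation (``difficulty``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import iirpeak, lfilter

from ._random import rng_for, substream
from .audio_io import CANONICAL_RATE, AudioClip, write_wav
from .classifier import MODES, TISSUES, LabelScheme
from .preprocessing import COAGULATION_ALARM_HZ, CUTTING_ALARM_HZ

__all__ = [
    "ClassSoundProfile",
    "SceneSpec",
    "TransitionAnnotation",
    "default_profiles",
    "synthesize_clip",
    "synthesize_transition",
    "synthesize_dataset",
    "synthesize_transition_set",
]


@dataclass(frozen=True)
class ClassSoundProfile:
    """Recipe for one class texture.

    ``spectral_peaks`` are (center Hz, bandwidth Hz, gain dB) resonators
    applied to white noise; ``crackle_rate`` is the Poisson rate of short
    broadband transients with an exponential envelope of
    ``crackle_decay_ms``; ``base_level_db`` sets the texture RMS in dBFS.
    """

    name: str
    spectral_peaks: Tuple[Tuple[float, float, float], ...] = ()
    crackle_rate: float = 0.0
    crackle_decay_ms: float = 5.0
    base_level_db: float = -20.0

    def __post_init__(self) -> None:
        if self.crackle_rate < 0:
            raise ValueError("crackle_rate must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """Dataset-level generation parameters.

    Clip durations are drawn from a truncated normal around 2 s — the
    average recording length the classes are modeled after — with the
    lower truncation at 1.2x the longest analysis window (1000 ms) so
    every clip yields at least one window at every configuration.
    """

    n_clips_per_class: int = 20
    duration_mean_ms: float = 2000.0
    duration_sd_ms: float = 300.0
    min_duration_ms: float = 1200.0
    alarm_level_db: float = -30.0
    noise_floor_db: float = -38.0
    difficulty: str = "easy"
    seed: int = 0
    sample_rate: int = CANONICAL_RATE

    def __post_init__(self) -> None:
        if self.difficulty not in ("easy", "hard"):
            raise ValueError("difficulty must be 'easy' or 'hard'")


@dataclass(frozen=True)
class TransitionAnnotation:
    clip_id: str
    class_before: str
    class_after: str
    truth_ms: float
    crossfade_ms: float


# Tissue resonance centers (Hz). Easy spacing separates spectral
# centroids by well over 1 kHz; hard compresses the spacing to ~400 Hz so
# classes genuinely overlap.
_EASY_CENTERS = {"fat": 3000.0, "fascia": 4600.0, "liver": 6200.0, "muscle": 7800.0}
_HARD_CENTERS = {"fat": 4800.0, "fascia": 5200.0, "liver": 5600.0, "muscle": 6000.0}
_CRACKLE_RATES = {"fat": 15.0, "fascia": 35.0, "liver": 55.0, "muscle": 75.0}


def default_profiles(
    scheme: LabelScheme, difficulty: str = "easy"
) -> Dict[str, ClassSoundProfile]:
    """Class -> profile map for a scheme and difficulty.

    ``idle`` is the bare noise floor. Under ``tissue_mode9``, the cut and
    coag variants of a tissue share resonance centers but differ in
    crackle rate (cutting doubles it) and in the gain of the secondary
    peak (+6 dB in coagulation), emulating the distinct duty cycles of
    the two power-delivery modes.
    """
    centers = _EASY_CENTERS if difficulty == "easy" else _HARD_CENTERS
    bw = 400.0 if difficulty == "easy" else 900.0
    profiles: Dict[str, ClassSoundProfile] = {
        "idle": ClassSoundProfile(name="idle", base_level_db=-60.0)
    }
    for tissue in TISSUES:
        c = centers[tissue]
        peaks = ((c, bw, 0.0), (c * 1.35, bw * 1.5, -8.0))
        if scheme.mode == "tissue5":
            profiles[tissue] = ClassSoundProfile(
                name=tissue, spectral_peaks=peaks, crackle_rate=_CRACKLE_RATES[tissue]
            )
        else:
            for op_mode in MODES:
                rate = _CRACKLE_RATES[tissue] * (2.0 if op_mode == "cut" else 1.0)
                gain2 = -8.0 + (6.0 if op_mode == "coag" else 0.0)
                profiles[f"{tissue}_{op_mode}"] = ClassSoundProfile(
                    name=f"{tissue}_{op_mode}",
                    spectral_peaks=((c, bw, 0.0), (c * 1.35, bw * 1.5, gain2)),
                    crackle_rate=rate,
                )
    return profiles


def _texture(
    profile: ClassSoundProfile, n: int, sr: int, rng: np.random.Generator
) -> np.ndarray:
    """Render the stationary class texture (resonant noise + crackles) at
    the profile's RMS level; silent for a peak-less profile."""
    if not profile.spectral_peaks:
        return np.zeros(n)
    base = rng.standard_normal(n)
    shaped = np.zeros(n)
    for center, bandwidth, gain_db in profile.spectral_peaks:
        b, a = iirpeak(center, center / bandwidth, fs=sr)
        shaped += 10.0 ** (gain_db / 20.0) * lfilter(b, a, base)
    if profile.crackle_rate > 0:
        n_events = rng.poisson(profile.crackle_rate * n / sr)
        starts = rng.integers(0, n, size=n_events)
        decay_n = max(4, int(profile.crackle_decay_ms / 1000.0 * sr))
        env = np.exp(-np.arange(3 * decay_n) / decay_n)
        crackles = np.zeros(n)
        for s in starts:
            seg = min(len(env), n - s)
            crackles[s : s + seg] += env[:seg] * rng.standard_normal(seg)
        shaped += 0.5 * crackles
    rms = float(np.sqrt(np.mean(shaped**2)))
    if rms > 0:
        shaped *= 10.0 ** (profile.base_level_db / 20.0) / rms
    return shaped


def _environment(n: int, sr: int, level_db: float, rng: np.random.Generator) -> np.ndarray:
    """1/f environmental noise, low-passed below 2 kHz, at level_db RMS."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sr)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[freqs > 2000.0] *= np.exp(-(freqs[freqs > 2000.0] - 2000.0) / 300.0)
    pink = np.fft.irfft(spectrum * shaping, n=n)
    rms = float(np.sqrt(np.mean(pink**2)))
    return pink / rms * 10.0 ** (level_db / 20.0) if rms > 0 else pink


def _alarms(
    op_mode: str | None, n: int, sr: int, level_db: float, rng: np.random.Generator
) -> np.ndarray:
    if op_mode == "cut":
        freqs: Sequence[float] = CUTTING_ALARM_HZ
    elif op_mode == "coag":
        freqs = COAGULATION_ALARM_HZ
    else:
        return np.zeros(n)
    t = np.arange(n) / sr
    amp = 10.0 ** (level_db / 20.0) * np.sqrt(2.0)  # per-tone peak for level_db RMS
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    return sum(amp * np.sin(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases))


def _guard_peak(x: np.ndarray) -> np.ndarray:
    peak = float(np.max(np.abs(x))) if len(x) else 0.0
    return x / peak * 0.99 if peak > 0.99 else x


def synthesize_clip(
    profile: ClassSoundProfile,
    duration_ms: float,
    spec: SceneSpec,
    seed: int,
    op_mode: str | None = None,
    clip_id: str = "",
) -> AudioClip:
    """Render one labeled clip: texture + alarms + environmental noise.

    ``op_mode`` selects the alarm-tone pair; idle clips (``op_mode``
    None) carry neither alarms nor crackles. Deterministic per seed;
    peak-guarded to stay within [-1, 1].
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    sr = spec.sample_rate
    n = int(round(duration_ms / 1000.0 * sr))
    rng = np.random.default_rng(substream(seed, f"clip:{clip_id or profile.name}"))
    y = _texture(profile, n, sr, rng)
    y = y + _alarms(op_mode, n, sr, spec.alarm_level_db, rng)
    y = y + _environment(n, sr, spec.noise_floor_db, rng)
    return AudioClip(samples=_guard_peak(y), sample_rate=sr, source_id=clip_id or profile.name)


def synthesize_transition(
    profile_a: ClassSoundProfile,
    profile_b: ClassSoundProfile,
    duration_ms: float,
    truth_ms: float,
    crossfade_ms: float,
    spec: SceneSpec,
    seed: int,
    op_mode: str | None = None,
    clip_id: str = "",
) -> Tuple[AudioClip, TransitionAnnotation]:
    """Two textures joined at ``truth_ms`` with a linear crossfade.

    Texture A sounds before the transition, texture B after; the
    crossfade of width ``crossfade_ms`` is centered on ``truth_ms``.
    Alarms and environment run through the whole clip.
    """
    if not crossfade_ms < min(truth_ms, duration_ms - truth_ms):
        raise ValueError("crossfade_ms must be < min(truth_ms, duration - truth_ms)")
    sr = spec.sample_rate
    n = int(round(duration_ms / 1000.0 * sr))
    rng = np.random.default_rng(substream(seed, f"transition:{clip_id}"))
    tex_a = _texture(profile_a, n, sr, rng)
    tex_b = _texture(profile_b, n, sr, rng)
    t_ms = np.arange(n) / sr * 1000.0
    if crossfade_ms > 0:
        fade = np.clip((t_ms - (truth_ms - crossfade_ms / 2)) / crossfade_ms, 0.0, 1.0)
    else:
        fade = (t_ms >= truth_ms).astype(np.float64)
    y = tex_a * (1.0 - fade) + tex_b * fade
    y = y + _alarms(op_mode, n, sr, spec.alarm_level_db, rng)
    y = y + _environment(n, sr, spec.noise_floor_db, rng)
    clip = AudioClip(samples=_guard_peak(y), sample_rate=sr, source_id=clip_id)
    ann = TransitionAnnotation(
        clip_id=clip_id, class_before=profile_a.name, class_after=profile_b.name,
        truth_ms=float(truth_ms), crossfade_ms=float(crossfade_ms),
    )
    return clip, ann


def _draw_durations(spec: SceneSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    d = rng.normal(spec.duration_mean_ms, spec.duration_sd_ms, size=n)
    return np.maximum(d, spec.min_duration_ms)


def synthesize_dataset(
    spec: SceneSpec,
    scheme: LabelScheme,
    out_dir: str | Path | None = None,
    write_audio: bool = True,
) -> Tuple[pd.DataFrame, List[AudioClip]]:
    """Generate a balanced labeled dataset and its manifest.

    ``n_clips_per_class`` clips per class; under ``tissue5`` the
    operation mode alternates cut/coag within each tissue so alarm tones
    are balanced rather than class-informative. Returns (manifest,
    clips); WAVs (16-bit PCM) and manifest.csv are written when
    ``out_dir`` is given and ``write_audio`` is true.
    """
    profiles = default_profiles(scheme, spec.difficulty)
    rng = rng_for(spec.seed, "durations")
    rows = []
    clips: List[AudioClip] = []
    for cls in scheme.classes:
        durations = _draw_durations(spec, spec.n_clips_per_class, rng)
        for i in range(spec.n_clips_per_class):
            clip_id = f"{cls}_{i:03d}"
            if cls == "idle":
                tissue, op_mode = "idle", "none"
            elif scheme.mode == "tissue5":
                tissue, op_mode = cls, MODES[i % 2]
            else:
                tissue, op_mode = cls.rsplit("_", 1)
            clip = synthesize_clip(
                profiles[cls], durations[i], spec,
                seed=spec.seed, op_mode=None if op_mode == "none" else op_mode,
                clip_id=clip_id,
            )
            clips.append(clip)
            rows.append({
                "clip_path": f"{clip_id}.wav", "clip_id": clip_id,
                "tissue": tissue, "mode": op_mode, "label": cls,
                "duration_ms": clip.duration_ms, "transition_ms": "",
            })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if write_audio:
            for clip in clips:
                write_wav(clip, out / f"{clip.source_id}.wav")
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, clips


def synthesize_transition_set(
    spec: SceneSpec,
    n_clips: int = 30,
    duration_ms: float = 4000.0,
    crossfade_ms: float = 60.0,
) -> Tuple[List[AudioClip], List[TransitionAnnotation]]:
    """Two-tissue transition clips with annotated ground truth.

    Tissue pairs cycle through all ordered pairs; transition times are
    drawn uniformly from the middle half of the clip. Emulates bench
    specimens of two tissue types traversed in sequence.
    """
    profiles = default_profiles(LabelScheme("tissue5"), spec.difficulty)
    rng = rng_for(spec.seed, "transitions")
    pairs = [(a, b) for a in TISSUES for b in TISSUES if a != b]
    clips, anns = [], []
    for i in range(n_clips):
        a, b = pairs[i % len(pairs)]
        truth = float(rng.uniform(0.25 * duration_ms, 0.75 * duration_ms))
        op_mode = MODES[i % 2]
        clip, ann = synthesize_transition(
            profiles[a], profiles[b], duration_ms, truth, crossfade_ms,
            spec, seed=spec.seed + i, op_mode=op_mode, clip_id=f"trans_{i:03d}",
        )
        clips.append(clip)
        anns.append(ann)
    return clips, anns
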