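"""Shared fixtures: small synthetic datasets and trained models are built
once per session so the expensive end-to-end checks share their inputs."""

from __future__ import annotations

import numpy as np
import pytest

import surgisound as ss


@pytest.fixture(scope="session")
def easy_scene() -> ss.SceneSpec:
    return ss.SceneSpec(n_clips_per_class=20, difficulty="easy", seed=1)


@pytest.fixture(scope="session")
def tissue5_dataset(easy_scene):
    """Easy 5-class dataset: (manifest with splits, clips)."""
    scheme = ss.LabelScheme("tissue5")
    manifest, clips = ss.synthesize_dataset(easy_scene, scheme)
    manifest = ss.split_dataset(manifest, seed=1)
    return manifest, clips, scheme


@pytest.fixture(scope="session")
def spec_config_2k() -> ss.SpectrogramConfig:
    return ss.SpectrogramConfig(f_min=2000.0, window_ms=500.0)


@pytest.fixture(scope="session")
def tissue5_features(tissue5_dataset, spec_config_2k):
    manifest, clips, scheme = tissue5_dataset
    return ss.featurize(clips, manifest, scheme, spec_config_2k)


@pytest.fixture(scope="session")
def tissue5_result(tissue5_features):
    return ss.run_experiment(tissue5_features, ss.TrainConfig(seed=1))


@pytest.fixture(scope="session")
def sine_clip():
    """One second of a full-scale 1 kHz sine at the canonical rate."""
    sr = ss.CANONICAL_RATE
    t = np.arange(sr) / sr
    return ss.AudioClip(samples=np.sin(2 * np.pi * 1000 * t), sample_rate=sr)
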