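"""Seed plumbing: every source of randomness in the package derives from a
single integer seed through named substreams, so experiments reproduce
bit-identically from one number."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "rng_for"]


def substream(seed: int, name: str) -> np.random.SeedSequence:
    """Derive an independent SeedSequence for a named stage.

    The stage name is hashed with CRC32 so the mapping is stable across
    runs and platforms; distinct names give statistically independent
    streams.
    """
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode("utf-8")),))


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Generator for a named substream of the top-level seed."""
    return np.random.default_rng(substream(seed, name))
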