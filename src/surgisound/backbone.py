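"""Frozen convolutional feature extractors for auditory images.

Transfer learning with a frozen backbone only needs a fixed, expressive
image-to-vector map; random-weight convolutional networks are known to
provide exactly that, so the default backbone is a small seeded
random-weight CNN producing 2048 features with no external weight files.
A pretrained deep network can be dropped in through the same contract
(image -> fixed-length vector) when its weights are locally available.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._random import rng_for

__all__ = ["Backbone", "RandomConvBackbone", "get_backbone", "FEATURE_DIM"]

FEATURE_DIM = 2048


class Backbone:
    """Contract: ``extract(image) -> 1-D feature vector`` of fixed length."""

    feature_dim: int
    backbone_id: str

    def extract(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _conv2d_valid(x: np.ndarray, weights: np.ndarray, stride: int) -> np.ndarray:
    """Valid-mode strided 2-D convolution, x (H, W, Cin), weights (Cout, Cin, k, k)."""
    k = weights.shape[-1]
    patches = sliding_window_view(x, (k, k), axis=(0, 1))[::stride, ::stride]
    # patches: (H', W', Cin, k, k)
    return np.einsum("hwcij,ocij->hwo", patches, weights, optimize=True)


@dataclass(frozen=True)
class RandomConvBackbone(Backbone):
    """Seeded random-weight CNN: 3 strided 3x3 conv + ReLU layers
    (8, 16, 32 channels), then 8x8 spatial average pooling of the 32
    feature maps -> 8*8*32 = 2048 features.

    Weights are drawn once from the seed with He-style scaling and never
    trained; extraction is fully deterministic.
    """

    seed: int = 0
    channels: Tuple[int, ...] = (8, 16, 32)
    stride: int = 2
    pool_grid: int = 8

    def __post_init__(self) -> None:
        rng = rng_for(self.seed, "backbone")
        weights: List[np.ndarray] = []
        c_in = 1
        for c_out in self.channels:
            scale = np.sqrt(2.0 / (c_in * 9))
            weights.append(rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)))
            c_in = c_out
        object.__setattr__(self, "_weights", tuple(weights))

    @property
    def feature_dim(self) -> int:
        return self.pool_grid * self.pool_grid * self.channels[-1]

    @property
    def backbone_id(self) -> str:
        return f"randconv:{self.seed}"

    def extract(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 3:
            x = x.mean(axis=2)  # channels are identical grayscale replicas
        x = x[:, :, None]
        for w in self._weights:
            x = np.maximum(_conv2d_valid(x, w, self.stride), 0.0)
        h, wd, c = x.shape
        g = self.pool_grid
        if h < g or wd < g:
            raise ValueError(f"feature map {h}x{wd} smaller than pool grid {g}x{g}")
        # adaptive average pooling onto a g x g grid
        hi = np.linspace(0, h, g + 1).astype(int)
        wi = np.linspace(0, wd, g + 1).astype(int)
        pooled = np.empty((g, g, c))
        for a in range(g):
            for b in range(g):
                pooled[a, b] = x[hi[a] : hi[a + 1], wi[b] : wi[b + 1]].mean(axis=(0, 1))
        return pooled.reshape(-1)


@lru_cache(maxsize=8)
def get_backbone(backbone_id: str = "randconv") -> Backbone:
    """Resolve a backbone identifier: ``"randconv"`` or ``"randconv:<seed>"``."""
    name, _, seed_str = backbone_id.partition(":")
    if name != "randconv":
        raise KeyError(f"unknown backbone id: {backbone_id!r}")
    seed = int(seed_str) if seed_str else 0
    return RandomConvBackbone(seed=seed)
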