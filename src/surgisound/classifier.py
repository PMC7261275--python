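"""Softmax head on frozen CNN features: label schemes, dataset splitting,
RMSprop training with early stopping, and inference.

The classifier is a single fully connected layer trained with mini-batch
RMSprop on a softmax cross-entropy loss over features extracted by a
frozen backbone. Two label schemes are supported: five tissue classes
(idle, fat, fascia, liver, muscle) and nine classes that additionally
split each tissue by electrosurgical operation mode (cut/coag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ._random import rng_for
from .backbone import Backbone, get_backbone
from .spectrogram import AuditoryImage, NormalizationStats, SpectrogramConfig

__all__ = [
    "TISSUES",
    "MODES",
    "LabelScheme",
    "FeatureVector",
    "TrainConfig",
    "HeadModel",
    "extract_features",
    "cross_entropy",
    "split_dataset",
    "train_head",
    "predict",
    "save_model",
    "load_model",
]

TISSUES = ("fat", "fascia", "liver", "muscle")
MODES = ("cut", "coag")


@dataclass(frozen=True)
class LabelScheme:
    """Ordered class list for one of the two supported schemes.

    ``tissue5``: idle + 4 tissues. ``tissue_mode9``: idle + tissue x mode.
    """

    mode: str = "tissue5"

    @property
    def classes(self) -> Tuple[str, ...]:
        if self.mode == "tissue5":
            return ("idle",) + TISSUES
        if self.mode == "tissue_mode9":
            return ("idle",) + tuple(f"{t}_{m}" for t in TISSUES for m in MODES)
        raise ValueError(f"unknown label scheme: {self.mode!r}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in scheme {self.mode}") from None

    def label_of(self, tissue: str, op_mode: str) -> str:
        """Class name for a (tissue, operation-mode) pair under this scheme."""
        if tissue == "idle":
            return "idle"
        return tissue if self.mode == "tissue5" else f"{tissue}_{op_mode}"

    def collapse_to_tissue(self, label: str) -> str:
        """Project a 9-class label onto its tissue (identity for tissue5)."""
        return label.rsplit("_", 1)[0] if self.mode == "tissue_mode9" and label != "idle" else label


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    extractor_id: str = "randconv"


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be < max_epochs")


@dataclass
class HeadModel:
    """A trained fully connected softmax layer plus the metadata needed to
    apply it to raw audio (backbone id, normalization stats, front-end
    config)."""

    weights: np.ndarray  # (feature_dim, n_classes)
    bias: np.ndarray  # (n_classes,)
    label_scheme: LabelScheme
    extractor_id: str = "randconv"
    norm_stats: NormalizationStats | None = None
    spectrogram_config: SpectrogramConfig | None = None
    training_log: List[Dict[str, float]] = field(default_factory=list)


def extract_features(image: AuditoryImage | np.ndarray, backbone: str | Backbone = "randconv") -> FeatureVector:
    """Run the frozen backbone on one auditory image."""
    bb = get_backbone(backbone) if isinstance(backbone, str) else backbone
    pixels = image.pixels if isinstance(image, AuditoryImage) else image
    return FeatureVector(values=bb.extract(pixels), extractor_id=bb.backbone_id)


def cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Softmax cross-entropy H(y, p) = -sum_c y_c * log(p_c), natural log.

    ``y`` one-hot (or a batch of one-hots), ``p`` probabilities on the
    simplex; probabilities are clamped at 1e-12 before the log. For a
    batch, returns the mean over observations.
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    return float(-(y * np.log(np.maximum(p, 1e-12))).sum(axis=1).mean())


def split_dataset(
    manifest: pd.DataFrame,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    label_col: str = "tissue",
) -> pd.DataFrame:
    """Assign train/val/test splits at CLIP level, stratified by class.

    All analysis windows of a clip inherit its split, so overlapping
    windows can never leak across splits. Deterministic for a seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = rng_for(seed, "split")
    out = manifest.copy()
    out["split"] = ""
    for cls, group in manifest.groupby(label_col, sort=True):
        idx = group.index.to_numpy()
        if len(idx) < 3:
            raise ValueError(f"class {cls!r} has {len(idx)} clips; need >= 3 to populate all splits")
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_train = max(1, int(round(fractions[0] * n)))
        n_val = max(1, int(round(fractions[1] * n)))
        n_train = min(n_train, n - 2)
        n_val = min(n_val, n - n_train - 1)
        splits = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
        out.loc[idx, "split"] = splits
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_head(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    scheme: LabelScheme,
    config: TrainConfig = TrainConfig(),
) -> HeadModel:
    """Train the softmax layer with mini-batch RMSprop and early stopping.

    Labels are integer class indices. Training stops when the validation
    loss has not improved for ``patience`` epochs (or at ``max_epochs``)
    and the weights of the best validation epoch are returned. The
    per-epoch train/val losses are recorded in ``training_log``.
    """
    X = np.asarray(train_features, dtype=np.float64)
    y = np.asarray(train_labels, dtype=np.int64)
    Xv = np.asarray(val_features, dtype=np.float64)
    yv = np.asarray(val_labels, dtype=np.int64)
    M = scheme.n_classes
    counts = np.bincount(y, minlength=M)
    if np.any(counts == 0):
        missing = [scheme.classes[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"empty training class(es): {missing}")

    rng = rng_for(config.seed, "train")
    d = X.shape[1]
    W = rng.normal(0.0, 0.01, size=(d, M))
    b = np.zeros(M)
    cache_W = np.zeros_like(W)
    cache_b = np.zeros_like(b)
    rho, eps = 0.9, 1e-8
    Yv_onehot = np.eye(M)[yv]
    Y_onehot_all = np.eye(M)[y]

    best = (np.inf, W.copy(), b.copy(), 0)
    log: List[Dict[str, float]] = []
    n = len(X)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = X[sel], y[sel]
            p = _softmax(xb @ W + b)
            g = (p - np.eye(M)[yb]) / len(sel)
            gW = xb.T @ g
            gb = g.sum(axis=0)
            cache_W = rho * cache_W + (1 - rho) * gW * gW
            cache_b = rho * cache_b + (1 - rho) * gb * gb
            W -= config.learning_rate * gW / (np.sqrt(cache_W) + eps)
            b -= config.learning_rate * gb / (np.sqrt(cache_b) + eps)
        train_loss = cross_entropy(Y_onehot_all, _softmax(X @ W + b))
        val_loss = cross_entropy(Yv_onehot, _softmax(Xv @ W + b))
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise RuntimeError(f"non-finite loss at epoch {epoch}: divergence")
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best[0] - 1e-9:
            best = (val_loss, W.copy(), b.copy(), epoch)
        elif epoch - best[3] >= config.patience:
            break
    return HeadModel(weights=best[1], bias=best[2], label_scheme=scheme, training_log=log)


def predict(model: HeadModel, features: FeatureVector | np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Softmax probabilities and argmax labels for one vector or a batch.

    Ties break toward the lowest class index (numpy argmax convention).
    Returns (probabilities, label indices); a single input vector yields
    a (n_classes,) probability row and a scalar index.
    """
    x = features.values if isinstance(features, FeatureVector) else np.asarray(features, float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != model.weights.shape[0]:
        raise ValueError(f"feature length {x2.shape[1]} != model {model.weights.shape[0]}")
    probs = _softmax(x2 @ model.weights + model.bias)
    labels = probs.argmax(axis=1)
    if single:
        return probs[0], labels[0]
    return probs, labels


def save_model(model: HeadModel, path: str | Path) -> None:
    """Serialize a checkpoint (npz weights + embedded JSON metadata)."""
    meta = {
        "version": 1,
        "scheme": model.label_scheme.mode,
        "extractor_id": model.extractor_id,
        "norm_stats": None if model.norm_stats is None else {
            "mean": model.norm_stats.mean, "std": model.norm_stats.std,
            "fitted_on": model.norm_stats.fitted_on,
        },
        "spectrogram_config": None if model.spectrogram_config is None
        else model.spectrogram_config.to_dict(),
        "training_log": model.training_log,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path, weights=model.weights, bias=model.bias,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> HeadModel:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        stats = meta["norm_stats"]
        cfg = meta["spectrogram_config"]
        return HeadModel(
            weights=z["weights"], bias=z["bias"],
            label_scheme=LabelScheme(meta["scheme"]),
            extractor_id=meta["extractor_id"],
            norm_stats=None if stats is None else NormalizationStats(**stats),
            spectrogram_config=None if cfg is None else SpectrogramConfig.from_dict(cfg),
            training_log=meta["training_log"],
        )
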