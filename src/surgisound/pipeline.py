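"""End-to-end experiment runner: featurize a dataset, train the head,
evaluate, and sweep spectrogram configurations.

This is the glue the CLI drives; each step is a plain function over
in-memory objects so experiments are scriptable and fully seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .audio_io import AudioClip
from .backbone import get_backbone
from .classifier import (
    HeadModel,
    LabelScheme,
    TrainConfig,
    predict,
    split_dataset,
    train_head,
)
from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics
from .preprocessing import NotchSpec, apply_notch, slide_windows
from .spectrogram import (
    NormalizationStats,
    SpectrogramConfig,
    fit_normalization,
    log_mel,
    render_image,
)

logger = logging.getLogger(__name__)

__all__ = ["WindowDataset", "featurize", "run_experiment", "grid_sweep"]


@dataclass
class WindowDataset:
    """Per-window features with labels, clip identities and splits."""

    features: np.ndarray  # (n_windows, feature_dim)
    labels: np.ndarray  # (n_windows,) class indices
    clip_ids: np.ndarray  # (n_windows,) parent clip ids
    splits: np.ndarray  # (n_windows,) train/val/test
    scheme: LabelScheme
    norm_stats: NormalizationStats
    config: SpectrogramConfig

    def subset(self, split: str) -> Tuple[np.ndarray, np.ndarray]:
        m = self.splits == split
        return self.features[m], self.labels[m]


def featurize(
    clips: Sequence[AudioClip],
    manifest: pd.DataFrame,
    scheme: LabelScheme,
    config: SpectrogramConfig,
    backbone_id: str = "randconv",
    norm_split: str = "train",
    notch: NotchSpec | None = None,
) -> WindowDataset:
    """Window every clip, compute log-mels, fit normalization on the
    reference split, render images and extract backbone features.

    ``norm_split='train'`` fits the normalization statistics on training
    windows only (no leakage); pass ``'all'`` to fit on the entire
    dataset. ``notch`` optionally suppresses alarm tones first.
    """
    if "split" not in manifest.columns or (manifest["split"] == "").any():
        raise ValueError("manifest must carry a complete 'split' column; run split_dataset first")
    by_id = {row["clip_id"]: row for _, row in manifest.iterrows()}
    specs, labels, clip_ids, splits = [], [], [], []
    for clip in clips:
        row = by_id[clip.source_id]
        if notch is not None:
            clip = apply_notch(clip, notch)
        label_idx = scheme.index(scheme.label_of(row["tissue"], row["mode"]))
        for seg in slide_windows(clip, config.window_ms, config.overlap):
            specs.append(log_mel(seg, config))
            labels.append(label_idx)
            clip_ids.append(clip.source_id)
            splits.append(row["split"])
    labels_a = np.array(labels)
    splits_a = np.array(splits)
    fit_mask = np.ones(len(specs), bool) if norm_split == "all" else splits_a == norm_split
    stats = fit_normalization(
        [s for s, m in zip(specs, fit_mask) if m], fitted_on=norm_split
    )
    bb = get_backbone(backbone_id)
    features = np.empty((len(specs), bb.feature_dim))
    for i, s in enumerate(specs):
        features[i] = bb.extract(render_image(s, stats, config.image_size).pixels)
    return WindowDataset(
        features=features, labels=labels_a, clip_ids=np.array(clip_ids),
        splits=splits_a, scheme=scheme, norm_stats=stats, config=config,
    )


@dataclass
class ExperimentResult:
    model: HeadModel
    confusion: ConfusionMatrix
    report: MetricsReport
    test_pred: np.ndarray
    test_true: np.ndarray


def run_experiment(
    dataset: WindowDataset, train_config: TrainConfig = TrainConfig()
) -> ExperimentResult:
    """Train the softmax head on the train/val splits, evaluate on test."""
    Xt, yt = dataset.subset("train")
    Xv, yv = dataset.subset("val")
    Xe, ye = dataset.subset("test")
    model = train_head(Xt, yt, Xv, yv, dataset.scheme, train_config)
    model.norm_stats = dataset.norm_stats
    model.spectrogram_config = dataset.config
    _, pred = predict(model, Xe)
    cm = confusion(ye, pred, dataset.scheme)
    return ExperimentResult(
        model=model, confusion=cm, report=metrics(cm), test_pred=pred, test_true=ye
    )


def grid_sweep(
    clips: Sequence[AudioClip],
    manifest: pd.DataFrame,
    scheme: LabelScheme,
    base_config: SpectrogramConfig = SpectrogramConfig(),
    window_grid: Sequence[float] = (300.0, 500.0, 1000.0),
    f_min_grid: Sequence[float] = (2000.0, 0.0),
    train_config: TrainConfig = TrainConfig(),
    backbone_id: str = "randconv",
) -> pd.DataFrame:
    """Test accuracy over the window-length x low-cut configuration grid.

    Returns a DataFrame indexed by f_min with one column per window
    length (ms); each cell is the window-level top-1 test accuracy of a
    full featurize + train + evaluate run at that configuration.
    """
    table = pd.DataFrame(
        index=[f"f_min={int(f)}Hz" for f in f_min_grid],
        columns=[f"{int(w)}ms" for w in window_grid],
        dtype=float,
    )
    for f_min in f_min_grid:
        for window_ms in window_grid:
            config = base_config.with_(f_min=f_min, window_ms=window_ms)
            ds = featurize(clips, manifest, scheme, config, backbone_id=backbone_id)
            result = run_experiment(ds, train_config)
            acc = result.report.top1_accuracy
            table.loc[f"f_min={int(f_min)}Hz", f"{int(window_ms)}ms"] = acc
            logger.info("grid cell window=%sms f_min=%s -> acc %.4f", window_ms, f_min, acc)
    return table
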