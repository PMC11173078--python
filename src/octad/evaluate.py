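"""Image-level aggregation, heat-map rendering, and evaluation metrics.

A scan is anomalous if any of its local regions is: the image-level
anomaly score is the *maximum* over the region score grid, so even a
single small lesion can flag the scan.  For localization, the region
grid is bilinearly upsampled to pixel resolution and optionally
Gaussian-smoothed for display; smoothing is cosmetic and never applied
before image-level scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from sklearn.metrics import roc_auc_score

from octad.bank import ScoreGrid
from octad.errors import EvaluationError, InputError

__all__ = [
    "AnomalyMap",
    "EvalMetrics",
    "image_score",
    "anomaly_heatmap",
    "roc_auc",
    "select_threshold_max_f1",
    "classification_metrics",
]


@dataclass
class AnomalyMap:
    """Pixel-resolution rendering of a region score grid."""

    pixels: np.ndarray  # (S, S)
    source_id: str = ""
    smoothing_sigma: float = 0.0


@dataclass
class EvalMetrics:
    roc_auc: float
    f1: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    n_normal: int
    n_anomalous: int


def image_score(scores: ScoreGrid) -> float:
    """Maximum region score — one bad region makes the scan anomalous."""
    if scores.grid.size == 0:
        raise InputError("empty score grid")
    return float(scores.grid.max())


def anomaly_heatmap(scores: ScoreGrid, out_size: int, sigma: float = 4.0) -> AnomalyMap:
    """Bilinear upsample to ``out_size`` then Gaussian-smooth with ``sigma`` px."""
    h, w = scores.grid.shape
    if out_size < max(h, w):
        raise InputError(f"out_size={out_size} smaller than the score grid {h}x{w}")
    if (h, w) == (out_size, out_size):
        up = scores.grid.astype(np.float64)
    else:
        up = _sk_resize(
            scores.grid, (out_size, out_size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    if sigma > 0:
        up = ndimage.gaussian_filter(up, sigma=sigma, mode="nearest")
    return AnomalyMap(pixels=up, source_id=scores.source_id, smoothing_sigma=sigma)


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise EvaluationError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney pair-counting form).

    Equals the fraction of (anomalous, normal) pairs where the anomalous
    scan outscores the normal one, ties counted one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def select_threshold_max_f1(scores, labels) -> float:
    """Threshold maximizing F1 of the anomalous class (ties: lowest).

    Candidates are the midpoints between consecutive sorted unique
    scores, plus the minimum score (everything predicted anomalous).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0])
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, best_t = f1, float(t)
    return best_t


def classification_metrics(scores, labels, threshold: float) -> EvalMetrics:
    """Confusion-matrix rates for the rule: anomalous iff score >= threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    n_pos, n_neg = tp + fn, tn + fp
    auc = roc_auc(scores, labels) if (n_pos and n_neg) else float("nan")
    return EvalMetrics(
        roc_auc=auc,
        f1=2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0,
        accuracy=(tp + tn) / len(labels) if len(labels) else 0.0,
        sensitivity=tp / n_pos if n_pos else 0.0,
        specificity=tn / n_neg if n_neg else 0.0,
        threshold=float(threshold),
        n_normal=n_neg,
        n_anomalous=n_pos,
    )
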