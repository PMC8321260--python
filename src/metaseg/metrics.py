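"""Segmentation quality metrics and multi-run statistics.

The central metric is a class-weighted Dice similarity coefficient

    DSC = sum_k 2 * w_k * sum_i p(k,i) g(k,i) / (sum_i p(k,i)^2 + sum_i g(k,i)^2)

where ``p(k,i)`` is the predicted probability of class ``k`` at pixel ``i``,
``g(k,i)`` the one-hot ground truth, and ``w_k`` a per-class weight.  For
binary tissue segmentation the conventional weighting puts 0.9 on the target
area and 0.1 on background, so a method is rewarded mostly for getting the
tissue right.

Precision and recall are reported on the binarized foreground class; the
training loss is an (unweighted by default) per-pixel cross-entropy; and
experiment summaries are means with t-based 95% confidence intervals over
independent runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ClassWeights",
    "MetricsRecord",
    "weighted_dice",
    "precision_recall",
    "pixel_cross_entropy",
    "run_statistics",
    "one_hot",
]

#: clipping bound applied to predicted probabilities inside the log
LOG_EPS = 1e-7


@dataclass(frozen=True)
class ClassWeights:
    """Per-class weights ``w_k`` of the weighted Dice coefficient.

    The default binary configuration weights the foreground (tissue) class
    0.9 and the background 0.1.  Weights must be non-negative; they are not
    forced to sum to one so that linearity in the weights is preserved.
    """

    weights: tuple

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if any(x < 0 for x in w):
            raise ValueError("class weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @classmethod
    def binary(cls, foreground: float = 0.9, background: float = 0.1) -> "ClassWeights":
        """Binary weighting, ordered (background, foreground)."""
        return cls((background, foreground))

    def __len__(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)


@dataclass(frozen=True)
class MetricsRecord:
    """One evaluation result: weighted DSC, precision and recall."""

    dsc: float
    precision: float
    recall: float

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "precision": self.precision, "recall": self.recall}


def one_hot(mask: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """One-hot encode an integer label map to shape ``(K, ...)``."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError("labels outside [0, n_classes)")
    out = np.zeros((n_classes,) + mask.shape, dtype=np.float64)
    for k in range(n_classes):
        out[k] = mask == k
    return out


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def weighted_dice(
    pred: np.ndarray,
    gt: np.ndarray,
    w: ClassWeights | None = None,
    *,
    empty_class_scores_full: bool = False,
) -> float:
    """Class-weighted Dice similarity coefficient.

    Parameters
    ----------
    pred
        Predicted probabilities, shape ``(K, ...)`` with entries in [0, 1].
    gt
        One-hot ground truth of the same shape.
    w
        Per-class weights; defaults to the binary 0.1/0.9 configuration.
    empty_class_scores_full
        How to score a class absent from both prediction and ground truth
        (zero denominator).  The default contributes 0 for that class;
        setting this flag contributes the full weight ``w_k`` instead.
    """
    pred, gt = _check_pair(pred, gt)
    if w is None:
        w = ClassWeights.binary()
    k = pred.shape[0]
    if len(w) != k:
        raise ValueError(f"{len(w)} weights for {k} classes")
    axes = tuple(range(1, pred.ndim))
    inter = np.sum(pred * gt, axis=axes)
    denom = np.sum(pred * pred, axis=axes) + np.sum(gt * gt, axis=axes)
    terms = np.zeros(k, dtype=np.float64)
    nonzero = denom > 0
    terms[nonzero] = 2.0 * inter[nonzero] / denom[nonzero]
    if empty_class_scores_full:
        terms[~nonzero] = 1.0
    return float(np.sum(w.as_array() * terms))


def precision_recall(
    pred_binary: np.ndarray, gt: np.ndarray, foreground: int = 1
) -> tuple[float, float]:
    """Foreground precision and recall of a binarized prediction.

    Both inputs are label maps (or one-hot stacks, in which case the
    ``foreground`` channel is used).  A zero denominator yields ``nan``
    for the affected quantity.
    """
    pred_binary = np.asarray(pred_binary)
    gt = np.asarray(gt)
    if pred_binary.ndim == gt.ndim and pred_binary.ndim >= 3:
        pred_binary = pred_binary[foreground]
        gt = gt[foreground]
        foreground = 1
    if pred_binary.shape != gt.shape:
        raise ValueError("shape mismatch between prediction and ground truth")
    p = pred_binary == foreground
    g = gt == foreground
    tp = float(np.sum(p & g))
    fp = float(np.sum(p & ~g))
    fn = float(np.sum(~p & g))
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return precision, recall


def pixel_cross_entropy(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean per-pixel cross-entropy ``-sum_k g log p`` with clipped logs."""
    pred, gt = _check_pair(pred, gt)
    p = np.clip(pred, LOG_EPS, 1.0)
    per_pixel = -np.sum(gt * np.log(p), axis=0)
    return float(np.mean(per_pixel))


def run_statistics(values) -> tuple[float, float]:
    """Mean and 95% confidence-interval half-width over independent runs.

    Uses the t distribution with ``n - 1`` degrees of freedom and the
    sample standard deviation, the conventional small-sample CI.
    """
    values = np.asarray(list(values), dtype=np.float64)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 runs for a confidence interval")
    mean = float(np.mean(values))
    s = float(np.std(values, ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * s / np.sqrt(n))
    return mean, half
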