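"""Segmentation and classification evaluation metrics.

Implements the full metric suite used to judge the pipeline: confusion-count
metrics (accuracy, sensitivity, specificity), revised contrast-to-noise
ratio (rCNR), mean squared error, Dice coefficient and Jaccard similarity,
Hausdorff distance between mask boundaries, PSNR, pixelwise segmentation
accuracy, and the ROC curve with trapezoid AUC.  Every definition here is
deliberately simple enough to verify against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from skimage.segmentation import find_boundaries
from sklearn import metrics as _skm

from .preprocess import estimate_noise_sigma

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_metrics",
    "confusion_from_labels",
    "rcnr",
    "mse",
    "dice_jaccard",
    "mask_boundary_points",
    "hausdorff",
    "hausdorff_masks",
    "psnr",
    "roc_curve",
    "segmentation_accuracy",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; positives = abnormal by convention."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsReport:
    """Aggregated evaluation output of one pipeline run."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    rcnr: float | None = None
    mse: float | None = None
    dice: float | None = None
    jaccard: float | None = None
    hausdorff: float | None = None
    psnr: float | None = None
    segmentation_accuracy: float | None = None
    auc: float | None = None
    roc: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "roc"}
        d["roc"] = [[float(a), float(b)] for a, b in self.roc]
        return d


def confusion_from_labels(y_true, y_pred, positive=1) -> ConfusionCounts:
    """Build confusion counts from parallel label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    p = y_true == positive
    pp = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(p & pp)),
        tn=int(np.sum(~p & ~pp)),
        fp=int(np.sum(~p & pp)),
        fn=int(np.sum(p & ~pp)),
    )


def confusion_metrics(c: ConfusionCounts):
    """Accuracy, sensitivity (recall on positives), specificity.

    A class-conditional metric whose denominator is zero is returned as
    ``None`` (undefined) rather than raising.
    """
    total = c.n_positive + c.n_negative
    if total == 0:
        raise ValueError("empty confusion table")
    accuracy = (c.tp + c.tn) / total
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return accuracy, sensitivity, specificity


def rcnr(image, vessel_mask, background_mask, sigma_n: float | None = None) -> float:
    """Revised contrast-to-noise ratio |mean(A) - mean(B)| / sigma_n.

    ``sigma_n`` defaults to the directional-residual noise estimate of the
    image itself; pass it explicitly when the true noise level is known.
    """
    img = np.asarray(image, dtype=np.float64)
    v = np.asarray(vessel_mask, dtype=bool)
    b = np.asarray(background_mask, dtype=bool)
    if not v.any() or not b.any():
        raise ValueError("vessel and background masks must be nonempty")
    if sigma_n is None:
        sigma_n = estimate_noise_sigma(img)
    if sigma_n <= 0:
        raise ValueError("degenerate noise level (sigma_n = 0)")
    return float(abs(img[v].mean() - img[b].mean()) / sigma_n)


def mse(a, b) -> float:
    """Mean squared difference between two equal-shape arrays."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((a - b) ** 2))


def dice_jaccard(reference, predicted):
    """Dice coefficient and Jaccard similarity of two binary masks.

    Two empty masks agree perfectly on absence and return (1, 1) by
    convention.  The identity ``dice = 2 J / (1 + J)`` always holds.
    """
    r = np.asarray(reference).astype(bool)
    p = np.asarray(predicted).astype(bool)
    if r.shape != p.shape:
        raise ValueError("shape mismatch")
    inter = int(np.sum(r & p))
    union = int(np.sum(r | p))
    size_sum = int(r.sum()) + int(p.sum())
    if size_sum == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / size_sum
    jaccard = inter / union if union else 1.0
    return float(dice), float(jaccard)


def mask_boundary_points(mask) -> np.ndarray:
    """(n, 2) array of boundary pixel coordinates (8-connectivity)."""
    m = np.asarray(mask).astype(bool)
    boundary = find_boundaries(m, mode="inner", connectivity=2)
    return np.argwhere(boundary).astype(np.float64)


def hausdorff(p_points, q_points) -> float:
    """Symmetric Hausdorff distance max(h(P,Q), h(Q,P)), Euclidean metric."""
    p = np.asarray(p_points, dtype=np.float64)
    q = np.asarray(q_points, dtype=np.float64)
    if p.size == 0 or q.size == 0:
        raise ValueError("point sets must be nonempty")
    d_pq = directed_hausdorff(p, q)[0]
    d_qp = directed_hausdorff(q, p)[0]
    return float(max(d_pq, d_qp))


def hausdorff_masks(reference, predicted) -> float:
    """Hausdorff distance between the boundary pixels of two masks."""
    return hausdorff(mask_boundary_points(reference), mask_boundary_points(predicted))


def psnr(reference, test, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE), in dB.

    Identical images have zero MSE; the result is flagged as ``inf``.
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    err = mse(reference, test)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


def roc_curve(scores, labels):
    """ROC points and trapezoid AUC.

    Returns ``(points, auc)`` where points is a list of (fpr, tpr) pairs at
    every distinct score threshold (monotone staircase).  The trapezoid AUC
    equals the Mann-Whitney pair-counting statistic.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("ROC requires exactly two classes in labels")
    fpr, tpr, _ = _skm.roc_curve(labels, scores, pos_label=classes.max())
    auc = float(_skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def segmentation_accuracy(reference, predicted) -> float:
    """Fraction of pixels on which the two masks agree."""
    r = np.asarray(reference).astype(bool)
    p = np.asarray(predicted).astype(bool)
    if r.shape != p.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(r == p))
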