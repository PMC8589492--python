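"""Segmentation and classification evaluation metrics.

Pixel-level segmentation quality is scored with confusion-derived rates,
the Dice and Jaccard overlap coefficients, the structure measure (S), and
the enhanced-alignment measure (E); classifier quality with the same rates
plus FPR, F1, the Matthews correlation coefficient, and ROC/AUC.

The structure measure combines an object-aware term (foreground and
background mean/dispersion similarity) with a region-aware term (the
ground-truth frame is split into four rectangles about the foreground
centroid and a luminance/contrast/structure similarity is computed per
region, weighted by area):

    S = alpha * S_o + (1 - alpha) * S_r,   alpha = 0.5 by default.

The enhanced-alignment measure compares bias-corrected maps (each map
minus its global mean) through an alignment matrix phi and averages the
enhanced alignment over all pixels:

    E = 1/(w*h) * sum_xy phi(pred(x,y), gt(x,y)).

Rates with a zero denominator are reported as explicit missing values
(``None``) together with a reason code - never silently as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DomainError, ShapeError

__all__ = ["ConfusionCounts", "confusion_from_masks", "basic_rates",
           "dice", "jaccard", "structure_measure", "e_measure", "roc_auc",
           "evaluate_segmentation", "evaluate_classification",
           "evaluate_dataset"]

_EPS = 1e-12


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")


def confusion_from_masks(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts; foreground (disc) is 1."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_shapes(pred, gt)
    p = pred > 0
    g = gt > 0
    return ConfusionCounts(tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
                           tn=int(np.sum(~p & ~g)), fn=int(np.sum(~p & g)))


@dataclass
class Rates:
    """Confusion-derived rates; undefined entries are None with a reason."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    fpr: float | None = None
    f1: float | None = None
    mcc: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)


def basic_rates(counts: ConfusionCounts) -> Rates:
    """Accuracy, sensitivity, specificity, precision, FPR, F1, MCC.

    F1 is the harmonic mean of precision and sensitivity; MCC is computed
    directly from the four counts.  A zero denominator flags the rate as
    undefined rather than coercing it to 0 or 1.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise DomainError("all confusion counts are zero")
    r = Rates()
    r.accuracy = (tp + tn) / counts.total
    if tp + fn > 0:
        r.sensitivity = tp / (tp + fn)
    else:
        r.undefined["sensitivity"] = "no positive ground truth"
    if tn + fp > 0:
        r.specificity = tn / (tn + fp)
        r.fpr = fp / (tn + fp)
    else:
        r.undefined["specificity"] = "no negative ground truth"
        r.undefined["fpr"] = "no negative ground truth"
    if tp + fp > 0:
        r.precision = tp / (tp + fp)
    else:
        r.undefined["precision"] = "no positive predictions"
    if r.precision is not None and r.sensitivity is not None:
        if r.precision + r.sensitivity > 0:
            r.f1 = (2 * r.precision * r.sensitivity
                    / (r.precision + r.sensitivity))
        else:
            r.undefined["f1"] = "precision and sensitivity both zero"
    else:
        r.undefined["f1"] = "precision or sensitivity undefined"
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom > 0:
        r.mcc = float((float(tp) * tn - float(fp) * fn) / denom)
    else:
        r.undefined["mcc"] = "degenerate confusion table"
    return r


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|P & G| / (|P| + |G|)."""
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    _check_shapes(pred, gt)
    denom = pred.sum() + gt.sum()
    if denom == 0:
        raise DomainError("dice undefined: both masks empty")
    return float(2.0 * np.sum(pred & gt) / denom)


def jaccard(pred: np.ndarray, gt: np.ndarray) -> float:
    """Jaccard (intersection over union) |P & G| / |P | G|."""
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    _check_shapes(pred, gt)
    union = np.sum(pred | gt)
    if union == 0:
        raise DomainError("jaccard undefined: both masks empty")
    return float(np.sum(pred & gt) / union)


# -- structure measure ----------------------------------------------------

def _ssim_region(pred: np.ndarray, gt: np.ndarray) -> float:
    n = pred.size
    if n <= 1:
        return 1.0 if abs(float(pred.sum() - gt.sum())) < _EPS else 0.0
    x, y = pred.mean(), gt.mean()
    sx = ((pred - x) ** 2).sum() / (n - 1)
    sy = ((gt - y) ** 2).sum() / (n - 1)
    sxy = ((pred - x) * (gt - y)).sum() / (n - 1)
    alpha = 4.0 * x * y * sxy
    beta = (x * x + y * y) * (sx + sy)
    if alpha != 0.0:
        return float(alpha / (beta + _EPS))
    return 1.0 if beta == 0.0 else 0.0


def _object_score(vals: np.ndarray) -> float:
    """Similarity of a region to the constant-1 template."""
    if vals.size == 0:
        return 0.0
    x = vals.mean()
    sigma = vals.std()
    return float(2.0 * x / (x * x + 1.0 + sigma + _EPS))


def _s_object(pred: np.ndarray, gt: np.ndarray) -> float:
    fg = pred[gt > 0]
    bg = 1.0 - pred[gt == 0]
    mu = float(np.mean(gt > 0))
    return mu * _object_score(fg) + (1.0 - mu) * _object_score(bg)


def _s_region(pred: np.ndarray, gt: np.ndarray) -> float:
    h, w = gt.shape
    g = gt > 0
    rows, cols = np.where(g)
    if rows.size == 0:
        cy, cx = h // 2, w // 2
    else:
        cy = int(np.round(rows.mean())) + 1
        cx = int(np.round(cols.mean())) + 1
    cy = min(max(cy, 1), h - 1) if h > 1 else 1
    cx = min(max(cx, 1), w - 1) if w > 1 else 1
    total = h * w
    score = 0.0
    for rs, cs in ((slice(0, cy), slice(0, cx)),
                   (slice(0, cy), slice(cx, w)),
                   (slice(cy, h), slice(0, cx)),
                   (slice(cy, h), slice(cx, w))):
        sub_p = pred[rs, cs]
        sub_g = g[rs, cs].astype(np.float64)
        weight = sub_g.size / total
        score += weight * _ssim_region(sub_p, sub_g)
    return score


def structure_measure(pred_prob: np.ndarray, gt: np.ndarray,
                      alpha: float = 0.5) -> float:
    """Structure measure S = alpha*S_o + (1-alpha)*S_r, clipped to [0, 1].

    Degenerate ground truths follow the construction's limit rules: an
    all-background gt scores ``1 - mean(pred)``, an all-foreground gt
    scores ``mean(pred)``.
    """
    pred = np.asarray(pred_prob, dtype=np.float64)
    gt = np.asarray(gt)
    _check_shapes(pred, gt)
    if not 0.0 <= alpha <= 1.0:
        raise DomainError("alpha must lie in [0, 1]")
    g = gt > 0
    y = float(g.mean())
    if y == 0.0:
        s = 1.0 - float(pred.mean())
    elif y == 1.0:
        s = float(pred.mean())
    else:
        s = alpha * _s_object(pred, g.astype(np.float64)) \
            + (1.0 - alpha) * _s_region(pred, gt)
    return float(np.clip(s, 0.0, 1.0))


# -- enhanced-alignment measure ------------------------------------------

def _e_measure_binary(pred: np.ndarray, gt: np.ndarray) -> float:
    p = (np.asarray(pred) > 0).astype(np.float64)
    g = (np.asarray(gt) > 0).astype(np.float64)
    h, w = g.shape
    if g.sum() == 0:           # limit rule: reward predicting nothing
        enhanced = 1.0 - p
    elif g.sum() == g.size:    # limit rule: reward predicting everything
        enhanced = p
    else:
        dp = p - p.mean()
        dg = g - g.mean()
        align = 2.0 * dg * dp / (dg * dg + dp * dp + _EPS)
        enhanced = (align + 1.0) ** 2 / 4.0
    return float(enhanced.sum() / (w * h))


def e_measure(pred: np.ndarray, gt: np.ndarray,
              mode: str = "single") -> float:
    """Enhanced-alignment measure of a prediction against a binary gt.

    ``mode='single'`` treats ``pred`` as already binary (any value > 0 is
    foreground for integer masks; probability maps are cut at 0.5).
    ``mode='mean'`` averages the measure over 256 binarization thresholds
    ``(t + 0.5)/256, t = 0..255`` - the half-offset grid makes the mean of
    a binary input equal its single-threshold value exactly.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt)
    _check_shapes(pred, gt)
    if mode == "single":
        if pred.dtype.kind == "f" and pred.max() <= 1.0:
            binary = pred >= 0.5 if not _is_binary(pred) else pred > 0
        else:
            binary = pred > 0
        return _e_measure_binary(binary, gt)
    if mode == "mean":
        scores = [_e_measure_binary(pred >= (t + 0.5) / 256.0, gt)
                  for t in range(256)]
        return float(np.mean(scores))
    raise DomainError(f"unknown e_measure mode: {mode!r}")


def _is_binary(arr: np.ndarray) -> bool:
    return bool(np.isin(np.unique(arr), (0.0, 1.0)).all())


# -- ROC ------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR per threshold) and AUC.

    AUC is the Mann-Whitney statistic (ties contribute 1/2), i.e. the
    trapezoid area under the threshold-swept curve.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ShapeError("scores and labels must align")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DomainError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


# -- dataset-level aggregation -------------------------------------------

def evaluate_segmentation(pred: np.ndarray, gt: np.ndarray,
                          pred_prob: np.ndarray | None = None) -> dict:
    """Full per-image segmentation report (one row of the summary table)."""
    counts = confusion_from_masks(pred, gt)
    rates = basic_rates(counts)
    prob = pred_prob if pred_prob is not None else (
        np.asarray(pred) > 0).astype(np.float64)
    return {
        "accuracy": rates.accuracy,
        "sensitivity": rates.sensitivity,
        "specificity": rates.specificity,
        "precision": rates.precision,
        "dice": dice(pred, gt),
        "jaccard": jaccard(pred, gt),
        "s_measure": structure_measure(prob, gt),
        "e_measure": e_measure(pred, gt, mode="single"),
        "e_measure_mean": e_measure(prob, gt, mode="mean"),
    }


def evaluate_classification(scores, labels, threshold: float = 0.5) -> dict:
    """Pooled classification report from scalar scores and binary labels."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    pred = (scores > threshold).astype(int)
    counts = ConfusionCounts(tp=int(np.sum((pred == 1) & (labels == 1))),
                             fp=int(np.sum((pred == 1) & (labels == 0))),
                             tn=int(np.sum((pred == 0) & (labels == 0))),
                             fn=int(np.sum((pred == 0) & (labels == 1))))
    rates = basic_rates(counts)
    report = {
        "accuracy": rates.accuracy,
        "sensitivity": rates.sensitivity,
        "specificity": rates.specificity,
        "precision": rates.precision,
        "fpr": rates.fpr,
        "f1": rates.f1,
        "mcc": rates.mcc,
        "undefined": rates.undefined,
        "confusion": {"tp": counts.tp, "fp": counts.fp,
                      "tn": counts.tn, "fn": counts.fn},
    }
    if len(np.unique(labels)) >= 2:
        _, auc = roc_auc(scores, labels)
        report["auc"] = auc
    else:
        report["auc"] = None
        report["undefined"]["auc"] = "single-class labels"
    return report


def evaluate_dataset(seg_pairs, cls_scores, cls_labels) -> dict:
    """Aggregate a split: unweighted per-image mean of segmentation
    metrics plus pooled classification counts.

    ``seg_pairs`` is an iterable of ``(pred_mask, gt_mask, prob_or_None)``.
    """
    per_image = []
    for pred, gt, prob in seg_pairs:
        per_image.append(evaluate_segmentation(pred, gt, prob))
    seg_summary = {}
    if per_image:
        for key in per_image[0]:
            vals = [m[key] for m in per_image if m[key] is not None]
            seg_summary[key] = float(np.mean(vals)) if vals else None
    report = {"segmentation": seg_summary,
              "segmentation_per_image": per_image,
              "n_images": len(per_image)}
    if cls_scores is not None and len(cls_scores):
        report["classification"] = evaluate_classification(
            cls_scores, cls_labels)
    return report
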