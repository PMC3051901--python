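"""ROC, precision-recall, and FDR-curve utilities.

Ties are handled by moving all examples that share a score across the
decision boundary together, which makes auROC equal to the Mann-Whitney
pairwise statistic with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RocCurve",
    "PrCurve",
    "roc",
    "auroc",
    "partial_auroc",
    "precision_recall",
    "estimate_fdr_curve",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    partial_auroc: float  # raw area over FPR in [0, 0.3]
    partial_auroc_normalized: float

    PARTIAL_FPR_LIMIT = 0.3


@dataclass
class PrCurve:
    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray


def _counts(scores: np.ndarray, labels: np.ndarray):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels > labels.min()
    if pos.all() or not pos.any():
        raise ValueError("need both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order].astype(float)
    # group tied scores: cumulative counts at the last index of each tie run
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(p)[idx]
    fp = np.cumsum(1 - p)[idx]
    return s[idx], tp, fp, p.sum(), (1 - p).sum()


def roc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over all distinct thresholds with trapezoidal areas."""
    thr, tp, fp, n_pos, n_neg = _counts(scores, labels)
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    area = float(np.trapezoid(tpr, fpr))
    limit = RocCurve.PARTIAL_FPR_LIMIT
    # interpolate TPR at the FPR limit, then integrate the clipped curve
    fpr_c = np.clip(fpr, None, limit)
    tpr_at = np.interp(limit, fpr, tpr)
    keep = fpr < limit
    fpr_p = np.r_[fpr_c[keep], limit]
    tpr_p = np.r_[tpr[keep], tpr_at]
    p_area = float(np.trapezoid(tpr_p, fpr_p))
    return RocCurve(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auroc=area,
        partial_auroc=p_area,
        partial_auroc_normalized=p_area / limit,
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    return roc(scores, labels).auroc


def partial_auroc(
    scores: np.ndarray, labels: np.ndarray, normalized: bool = False
) -> float:
    curve = roc(scores, labels)
    return curve.partial_auroc_normalized if normalized else curve.partial_auroc


def precision_recall(scores: np.ndarray, labels: np.ndarray) -> PrCurve:
    """Precision/recall at every distinct threshold, ties grouped."""
    thr, tp, fp, n_pos, _ = _counts(scores, labels)
    if n_pos == 0:
        raise ValueError("need at least one positive")
    recall = tp / n_pos
    precision = tp / (tp + fp)
    return PrCurve(thresholds=thr, recall=recall, precision=precision)


def estimate_fdr_curve(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical FDR (1 - precision) at every distinct score cutoff."""
    thr, tp, fp, _, _ = _counts(scores, labels)
    fdr = fp / (tp + fp)
    return thr, fdr
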