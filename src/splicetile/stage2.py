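"""Second-stage detector: integrate inclusion probabilities across samples.

For each segment the per-sample inclusion probabilities are sorted in
descending order and concatenated with the flanking-exon expression vector
permuted by the same sample order; a linear SVM trained on the SCS
benchmark separates alternative from constitutive segments.  Tissue and
stress scores quantify differential splicing on top of the inclusion
probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .arraydata import SampleInfo
from .evaluation import auroc
from .genome import Segment
from .stage1 import (
    C_GRID,
    CalibrationMap,
    LinearModel,
    fit_calibration,
    train_linear_svm,
)

__all__ = [
    "Stage2Model",
    "ASPrediction",
    "assemble_stage2_features",
    "train_stage2",
    "fdr_threshold",
    "recall_threshold",
    "tissue_score",
    "stress_score",
    "write_predictions",
]


@dataclass
class Stage2Model:
    model: LinearModel
    calibrator: CalibrationMap
    fold_aurocs: list[float]
    oof_scores: np.ndarray  # cross-validated scores of the training set

    def score(self, X: np.ndarray) -> np.ndarray:
        return self.model.score(X)

    def confidence(self, X: np.ndarray) -> np.ndarray:
        return self.calibrator(self.model.score(X))


@dataclass
class ASPrediction:
    segment: Segment
    svm_score: float
    confidence: float
    passes_fdr_cutoff: bool
    tissue_score: float
    stress_score: float
    tissue_flag: bool
    stress_flag: bool


def assemble_stage2_features(
    p_row: np.ndarray, flank_expr: np.ndarray
) -> np.ndarray:
    """Sort p descending (stable) and permute the expression row identically."""
    p = np.asarray(p_row, dtype=float)
    e = np.asarray(flank_expr, dtype=float)
    if p.shape != e.shape or p.ndim != 1:
        raise ValueError("inclusion and expression rows must match")
    order = np.argsort(-p, kind="stable")
    return np.concatenate([p[order], e[order]])


def train_stage2(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 17,
    n_folds: int = 5,
    c_grid: tuple[float, ...] = C_GRID,
) -> Stage2Model:
    """Cross-validated linear SVM on the SCS set with calibrated outputs.

    Same rotation as stage 1 (3 folds train / 1 validation / 1 test); the
    number of folds is reduced with a warning when a class is too small.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_pos = int(np.sum(y > 0))
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("stage-2 training needs both classes")
    if min(n_pos, n_neg) < n_folds:
        n_folds = max(2, min(n_pos, n_neg))
        warnings.warn(f"too few examples per fold; reduced to {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(X, y)]
    oof = np.full(len(y), np.nan)
    fold_aurocs: list[float] = []
    chosen: list[float] = []
    for i in range(n_folds):
        test_idx = folds[i]
        val_idx = folds[(i + 1) % n_folds]
        train_idx = np.concatenate(
            [folds[j] for j in range(n_folds) if j not in (i, (i + 1) % n_folds)]
        )
        best_c, best_auc = None, -np.inf
        for C in c_grid:
            m = train_linear_svm(X[train_idx], y[train_idx], C)
            try:
                auc = auroc(m.score(X[val_idx]), y[val_idx])
            except ValueError:  # validation fold may lack positives
                auc = 0.5
            if auc > best_auc or (auc == best_auc and best_c is not None and C > best_c):
                best_c, best_auc = C, auc
        m = train_linear_svm(X[train_idx], y[train_idx], best_c)
        s = m.score(X[test_idx])
        oof[test_idx] = s
        try:
            fold_aurocs.append(auroc(s, y[test_idx]))
        except ValueError:
            pass
        chosen.append(best_c)
    final_c = max(set(chosen), key=lambda c: (chosen.count(c), c))
    final = train_linear_svm(X, y, final_c)
    calibrator = fit_calibration(oof, y)
    return Stage2Model(final, calibrator, fold_aurocs, oof)


def fdr_threshold(
    scores: np.ndarray, labels: np.ndarray, target_fdr: float
) -> float:
    """Smallest cutoff whose empirical FDR among predictions >= cutoff is
    at or below the target."""
    if not 0 < target_fdr < 1:
        raise ValueError("target FDR must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels > 0  # works for {0,1} and {-1,+1} labelings
    if not pos.any():
        warnings.warn("no positives; FDR target unattainable")
        return float("inf")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order].astype(float)
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(p)[idx]
    fp = np.cumsum(1 - p)[idx]
    fdr = fp / (tp + fp)
    ok = fdr <= target_fdr
    if not ok.any():
        warnings.warn("FDR target unattainable at any cutoff")
        return float("inf")
    return float(np.min(s[idx][ok]))


def recall_threshold(
    scores: np.ndarray, labels: np.ndarray, target_recall: float
) -> float:
    """Largest cutoff with recall at or above the target."""
    if not 0 < target_recall <= 1:
        raise ValueError("target recall must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels > 0  # works for {0,1} and {-1,+1} labelings
    if not pos.any():
        raise ValueError("recall threshold needs positives")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order].astype(float)
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    recall = np.cumsum(p)[idx] / p.sum()
    ok = recall >= target_recall
    if not ok.any():
        warnings.warn("recall target unattainable; returning minimum score")
        return float(s[-1])
    return float(np.max(s[idx][ok]))


def tissue_score(p_row: np.ndarray) -> float:
    """Spread of inclusion probabilities across tissues: max - min."""
    p = np.asarray(p_row, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 2:
        raise ValueError("tissue score needs at least two tissue samples")
    return float(p.max() - p.min())


def stress_score(
    p_row: np.ndarray, pairs: list[tuple[int, int]]
) -> float:
    """Largest |p(treatment) - p(control)| over matched stress pairs."""
    if not pairs:
        raise ValueError("stress score needs at least one matched pair")
    p = np.asarray(p_row, dtype=float)
    return float(max(abs(p[t] - p[c]) for t, c in pairs))


def sample_roles(
    samples: list[SampleInfo],
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Tissue sample indices and (treatment, control) index pairs."""
    index = {s.sample_id: i for i, s in enumerate(samples)}
    tissues = np.array(
        [i for i, s in enumerate(samples) if s.condition_class == "tissue"],
        dtype=int,
    )
    pairs = [
        (i, index[s.control_id])
        for i, s in enumerate(samples)
        if s.condition_class == "stress_treatment"
    ]
    return tissues, pairs


def write_predictions(predictions: list[ASPrediction], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "segment_id\tkind\tchrom\tstart\tend\tstrand\tscore\tconfidence"
            "\tpasses_fdr\tS_tissue\ttissue_flag\tS_stress\tstress_flag\n"
        )
        for p in predictions:
            iv = p.segment.interval
            kind = "IR" if p.segment.kind == "intron" else "ES"
            fh.write(
                f"{p.segment.id}\t{kind}\t{iv.chrom}\t{iv.start + 1}\t{iv.end}"
                f"\t{iv.strand}\t{p.svm_score:.6g}\t{p.confidence:.6g}"
                f"\t{int(p.passes_fdr_cutoff)}\t{p.tissue_score:.6g}"
                f"\t{int(p.tissue_flag)}\t{p.stress_score:.6g}"
                f"\t{int(p.stress_flag)}\n"
            )
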