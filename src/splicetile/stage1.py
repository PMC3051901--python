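"""Expression-stratified linear-SVM exon/intron classifier with calibration.

One linear soft-margin SVM per expression bin (10 bins), trained on
constitutive exon (+1) versus constitutive intron (-1) hybridization
features.  Raw margins are mapped to inclusion probabilities by a monotone
piecewise-linear calibration fitted per bin with isotonic regression on
out-of-fold scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .evaluation import auroc
from .features import ExpressionBinning

__all__ = [
    "C_GRID",
    "LinearModel",
    "CalibrationMap",
    "MetaClassifier",
    "train_linear_svm",
    "fit_calibration",
    "train_meta_classifier",
    "svm_score",
    "predict_inclusion",
]

C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
N_FOLDS = 5
DEFAULT_SEED = 17


@dataclass
class LinearModel:
    """A standardized linear scorer: score = w . (x - mean)/scale + b."""

    weights: np.ndarray
    bias: float
    C: float | None
    bin_index: int
    mean: np.ndarray
    scale: np.ndarray
    is_constant: bool = False

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != {self.weights.shape[0]}"
            )
        Z = (X - self.mean) / self.scale
        return Z @ self.weights + self.bias


def svm_score(model: LinearModel, features: np.ndarray) -> np.ndarray:
    """Raw decision value(s) for one or more feature vectors."""
    return model.score(features)


@dataclass
class CalibrationMap:
    """Monotone piecewise-linear map from SVM score to probability."""

    knot_scores: np.ndarray
    knot_probs: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.knot_scores, dtype=float)
        p = np.asarray(self.knot_probs, dtype=float)
        if s.shape != p.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("knots must be matching non-empty 1-d arrays")
        if np.any(np.diff(s) < 0) or np.any(np.diff(p) < 0):
            raise ValueError("calibration knots must be non-decreasing")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("calibrated probabilities must lie in [0, 1]")
        self.knot_scores = s
        self.knot_probs = p

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return np.clip(
            np.interp(s, self.knot_scores, self.knot_probs), 0.0, 1.0
        )


def fit_calibration(scores: np.ndarray, labels: np.ndarray) -> CalibrationMap:
    """Isotonic regression of labels on scores, linearly interpolated.

    Rejects single-class inputs; warns (and falls back to the prevalence)
    when scores anti-correlate with labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("calibration needs both classes")
    y01 = (labels == classes.max()).astype(float)
    if np.corrcoef(scores, y01)[0, 1] < 0:
        warnings.warn(
            "scores anti-correlate with labels; calibration collapses to "
            "the class prevalence"
        )
        prev = float(y01.mean())
        return CalibrationMap(np.array([0.0]), np.array([prev]))
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(scores, y01)
    return CalibrationMap(iso.X_thresholds_, iso.y_thresholds_)


@dataclass
class MetaClassifier:
    binning: ExpressionBinning
    models: dict[int, LinearModel]
    calibrators: dict[int, CalibrationMap]
    fold_aurocs: dict[int, list[float]] = field(default_factory=dict)

    def mean_cv_auroc(self) -> float:
        vals = [a for lst in self.fold_aurocs.values() for a in lst]
        return float(np.mean(vals)) if vals else float("nan")


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float, bin_index: int = 0
) -> LinearModel:
    """Fit one standardized linear soft-margin SVM (hinge loss)."""
    mean, scale = _standardize_params(X)
    Z = (X - mean) / scale
    clf = LinearSVC(C=C, loss="hinge", max_iter=20000, tol=1e-5, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    return LinearModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        bin_index=bin_index,
        mean=mean,
        scale=scale,
    )


def _constant_model(y: np.ndarray, n_features: int, bin_index: int) -> LinearModel:
    bias = 1.0 if np.all(y > 0) else -1.0
    return LinearModel(
        weights=np.zeros(n_features),
        bias=bias,
        C=None,
        bin_index=bin_index,
        mean=np.zeros(n_features),
        scale=np.ones(n_features),
        is_constant=True,
    )


def _train_one_bin(
    X: np.ndarray,
    y: np.ndarray,
    bin_index: int,
    seed: int,
    c_grid: tuple[float, ...],
    n_folds: int,
) -> tuple[LinearModel, CalibrationMap, list[float]]:
    """5-fold rotation: 3 folds train, 1 validation (C search), 1 test."""
    rng_seed = seed + bin_index
    counts = np.bincount((y > 0).astype(int), minlength=2)
    n_folds = min(n_folds, counts.min()) if counts.min() < n_folds else n_folds
    if n_folds < 2:
        raise ValueError("too few examples of one class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    folds = [test for _, test in skf.split(X, y)]
    oof_scores = np.full(len(y), np.nan)
    test_aurocs: list[float] = []
    chosen: list[float] = []
    for i in range(n_folds):
        test_idx = folds[i]
        val_idx = folds[(i + 1) % n_folds]
        train_idx = np.concatenate(
            [folds[j] for j in range(n_folds) if j not in (i, (i + 1) % n_folds)]
        )
        best_c, best_auc = None, -np.inf
        for C in c_grid:
            model = train_linear_svm(X[train_idx], y[train_idx], C, bin_index)
            auc = auroc(model.score(X[val_idx]), y[val_idx])
            # ties broken toward the larger C (less regularization)
            if auc > best_auc or (auc == best_auc and best_c is not None and C > best_c):
                best_c, best_auc = C, auc
        model = train_linear_svm(X[train_idx], y[train_idx], best_c, bin_index)
        scores = model.score(X[test_idx])
        oof_scores[test_idx] = scores
        test_aurocs.append(auroc(scores, y[test_idx]))
        chosen.append(best_c)
    # final C: the grid value picked most often (ties -> larger C)
    final_c = max(set(chosen), key=lambda c: (chosen.count(c), c))
    final = train_linear_svm(X, y, final_c, bin_index)
    # calibrate on out-of-fold scores rescaled to the final model's scale
    mask = ~np.isnan(oof_scores)
    calib = fit_calibration(oof_scores[mask], y[mask])
    return final, calib, test_aurocs


def train_meta_classifier(
    X: np.ndarray,
    y: np.ndarray,
    bin_assignment: np.ndarray,
    binning: ExpressionBinning,
    seed: int = DEFAULT_SEED,
    c_grid: tuple[float, ...] = C_GRID,
    n_folds: int = N_FOLDS,
) -> MetaClassifier:
    """Train the 10-bin meta-classifier on labeled (segment, sample) pairs.

    ``y`` is +1 for exons and -1 for introns; ``bin_assignment`` holds the
    1-based expression bin of each pair.  Bins containing a single class
    fall back to a constant scorer (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    bin_assignment = np.asarray(bin_assignment, dtype=int)
    models: dict[int, LinearModel] = {}
    calibrators: dict[int, CalibrationMap] = {}
    fold_aurocs: dict[int, list[float]] = {}
    for b in range(1, 11):
        sel = bin_assignment == b
        if not np.any(sel):
            warnings.warn(f"expression bin {b} has no training pairs")
            models[b] = _constant_model(np.array([1.0]), X.shape[1], b)
            calibrators[b] = CalibrationMap(np.array([0.0]), np.array([0.5]))
            continue
        Xb, yb = X[sel], y[sel]
        if np.unique(yb).size < 2:
            warnings.warn(f"expression bin {b} has a single class")
            models[b] = _constant_model(yb, X.shape[1], b)
            prev = float(np.mean(yb > 0))
            calibrators[b] = CalibrationMap(np.array([0.0]), np.array([prev]))
            continue
        model, calib, aucs = _train_one_bin(Xb, yb, b, seed, c_grid, n_folds)
        models[b] = model
        calibrators[b] = calib
        fold_aurocs[b] = aucs
    return MetaClassifier(binning, models, calibrators, fold_aurocs)


def predict_inclusion(
    meta: MetaClassifier,
    X: np.ndarray,
    bin_assignment: np.ndarray,
) -> np.ndarray:
    """Calibrated inclusion probability for each (segment, sample) pair.

    Pairs are routed to the model of their expression bin; the bin's
    calibrator maps the raw margin into [0, 1].
    """
    X = np.asarray(X, dtype=float)
    bins = np.asarray(bin_assignment, dtype=int)
    out = np.empty(len(X))
    for b in np.unique(bins):
        sel = bins == b
        scores = meta.models[int(b)].score(X[sel])
        out[sel] = meta.calibrators[int(b)](scores)
    return out


# ---------------------------------------------------------------------------
# serialization


def save_meta_classifier(meta: MetaClassifier, path: str) -> None:
    payload = {
        "format_version": 1,
        "binning_limits": meta.binning.limits.tolist(),
        "bins": {
            str(b): {
                "weights": m.weights.tolist(),
                "bias": m.bias,
                "C": m.C,
                "mean": m.mean.tolist(),
                "scale": m.scale.tolist(),
                "is_constant": m.is_constant,
                "calibration_scores": meta.calibrators[b].knot_scores.tolist(),
                "calibration_probs": meta.calibrators[b].knot_probs.tolist(),
                "fold_aurocs": meta.fold_aurocs.get(b, []),
            }
            for b, m in meta.models.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_meta_classifier(path: str) -> MetaClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    binning = ExpressionBinning(np.array(payload["binning_limits"]))
    models: dict[int, LinearModel] = {}
    calibrators: dict[int, CalibrationMap] = {}
    fold_aurocs: dict[int, list[float]] = {}
    for b_str, d in payload["bins"].items():
        b = int(b_str)
        models[b] = LinearModel(
            weights=np.array(d["weights"]),
            bias=d["bias"],
            C=d["C"],
            bin_index=b,
            mean=np.array(d["mean"]),
            scale=np.array(d["scale"]),
            is_constant=d["is_constant"],
        )
        calibrators[b] = CalibrationMap(
            np.array(d["calibration_scores"]), np.array(d["calibration_probs"])
        )
        if d["fold_aurocs"]:
            fold_aurocs[b] = d["fold_aurocs"]
    return MetaClassifier(binning, models, calibrators, fold_aurocs)
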