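"""Splitting, precision-recall/MCC machinery, and sensitivity thresholds.

Average precision is the interpolation-free step-sum sum_i (R_i - R_{i-1}) P_i
over descending score thresholds. Max MCC sweeps a fixed threshold grid in
increments of 0.001 with prediction positive iff score >= t; any MCC whose
denominator contains a zero factor is defined as 0. Comparator scores on other
scales enter via min-max normalization, which is rank-preserving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

MCC_STEP = 0.001
SENSITIVITY_LEVELS = (60, 65, 70, 75, 80, 85, 90, 95)


def _check_two_classes(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def split_counts(n_path: int, n_benign: int, frac: float = 0.7) -> tuple:
    """Per-class train/test counts for a stratified split.

    The training side takes floor(frac * class count); the remainder tests.
    Returns ((train_path, train_benign), (test_path, test_benign)).
    """
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must be in (0,1), got {frac}")
    if n_path < 1 or n_benign < 1:
        raise ValueError("counts must be >= 1")
    tr_p = math.floor(frac * n_path)
    tr_b = math.floor(frac * n_benign)
    return (tr_p, tr_b), (n_path - tr_p, n_benign - tr_b)


def split_dataset(y, frac: float = 0.7, seed: int | None = 0) -> tuple:
    """Stratified random 70/30 split; returns (train_idx, test_idx).

    Assignment within each class is randomized by ``seed``; the per-class
    train size is floor(frac * n) to match :func:`split_counts`.
    """
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        tr_n = math.floor(frac * len(idx))
        train_idx.append(perm[:tr_n])
        test_idx.append(perm[tr_n:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def average_precision(labels, scores) -> float:
    """Step-sum average precision; 1.0 for a perfect ranking."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def mcc_from_counts(tp, fp, fn, tn) -> float:
    """MCC of one confusion matrix; 0 when any denominator factor is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_curve(labels, scores, step: float = MCC_STEP) -> tuple:
    """MCC at every grid threshold {0, step, ..., 1}; positive iff score >= t.

    Uses sorted-score cumulative counts rather than per-threshold confusion
    matrices. Returns (thresholds, mcc array).
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    n_grid = round(1.0 / step)
    thresholds = np.arange(n_grid + 1) * step
    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels == 0])
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    tp = (n_pos - np.searchsorted(pos_scores, thresholds, side="left")).astype(float)
    fp = (n_neg - np.searchsorted(neg_scores, thresholds, side="left")).astype(float)
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
    return thresholds, mcc


def max_mcc(labels, scores, step: float = MCC_STEP) -> tuple:
    """(best threshold, best MCC) over the grid; smallest t achieving the max."""
    thresholds, mcc = mcc_curve(labels, scores, step=step)
    best = mcc.max()
    idx = int(np.argmax(mcc >= best - 1e-15))
    return float(thresholds[idx]), float(best)


def min_max_normalize(scores) -> np.ndarray:
    """Rank-preserving rescale of comparator scores onto [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize constant scores")
    return (scores - lo) / (hi - lo)


def threshold_for_sensitivity(path_scores, level: float) -> float:
    """Largest threshold recovering at least ``level`` % of pathogenic scores.

    Nearest-rank-from-top rule: the threshold is the score of the
    ceil(level/100 * n)-th ranked pathogenic variant, so the realized
    sensitivity at the returned threshold (with >= t positive) is never below
    the requested level.
    """
    path_scores = np.asarray(path_scores, dtype=float)
    if len(path_scores) == 0:
        raise ValueError("path_scores must be nonempty")
    if not 0.0 < level <= 100.0:
        raise ValueError(f"sensitivity level must be in (0,100], got {level}")
    k = math.ceil(level / 100.0 * len(path_scores))
    return float(np.sort(path_scores)[::-1][k - 1])


def threshold_table(path_scores, levels=SENSITIVITY_LEVELS) -> pd.DataFrame:
    """Sensitivity-calibrated threshold rows (sensitivity %, threshold)."""
    return pd.DataFrame({
        "sensitivity_pct": list(levels),
        "threshold": [threshold_for_sensitivity(path_scores, lv) for lv in levels],
    })


@dataclass(frozen=True)
class EvalCurves:
    """Precision/recall/MCC aligned on one threshold grid."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    mcc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "precision": self.precision,
            "recall": self.recall, "mcc": self.mcc,
        })


def evaluate_curves(labels, scores, step: float = MCC_STEP) -> EvalCurves:
    """Precision, recall and MCC at every grid threshold (positive iff >= t).

    Precision with no positive predictions is reported as 1.0 (the empty
    prediction makes no false calls), keeping the array well-defined at the
    top of the grid.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    thresholds, mcc = mcc_curve(labels, scores, step=step)
    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels == 0])
    tp = len(pos_scores) - np.searchsorted(pos_scores, thresholds, side="left")
    fp = len(neg_scores) - np.searchsorted(neg_scores, thresholds, side="left")
    pred_pos = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), 1.0)
    recall = tp / len(pos_scores)
    return EvalCurves(thresholds, precision, recall, mcc)


def plot_curves(curves_by_name: dict, path) -> None:
    """Publication-style PR and MCC curves for one or more predictors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_pr, ax_mcc) = plt.subplots(1, 2, figsize=(9, 4))
    for name, c in curves_by_name.items():
        ax_pr.plot(c.recall, c.precision, label=name)
        ax_mcc.plot(c.thresholds, c.mcc, label=name)
    ax_pr.set_xlabel("Recall")
    ax_pr.set_ylabel("Precision")
    ax_pr.set_xlim(0, 1)
    ax_pr.set_ylim(0, 1.02)
    ax_mcc.set_xlabel("Threshold")
    ax_mcc.set_ylabel("MCC")
    ax_mcc.set_xlim(0, 1)
    ax_pr.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
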