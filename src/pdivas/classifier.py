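"""Random-forest pathogenicity classifier with a fraction-of-trees score.

The ensemble is a bagged forest of T decision trees (default 500); the
pathogenicity score of a variant is the fraction of trees whose leaf majority
class is pathogenic, so every score is an integer multiple of 1/T in [0, 1].
Hyperparameters (tree count, depth, per-tree sample fraction, features per
tree) are tuned by stratified k-fold cross-validation maximizing average
precision, which is robust to the heavy benign:pathogenic class imbalance.
"""

from __future__ import annotations

import json
import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .splice_features import FEATURE_NAMES
from . import evaluation

MODEL_FORMAT_VERSION = 1

DEFAULT_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [4, 8, 16, None],
    "max_samples": [0.5, 0.8, 1.0],
    "max_features": [1, 2, 3, None],
}

SMALL_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [8, None],
    "max_samples": [0.8],
    "max_features": [2, None],
}

LABELS = ("benign", "pathogenic")  # encoded 0 / 1


class UnscorableVariant(ValueError):
    """Prediction requested on an incomplete feature vector."""


def _as_matrix(X, feature_names=FEATURE_NAMES) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        X = X.loc[:, list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValueError(f"expected {len(feature_names)} feature columns")
    return X


def encode_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        out = np.zeros(len(y), dtype=int)
        for i, lab in enumerate(y):
            if lab not in LABELS:
                raise ValueError(f"unknown label {lab!r}")
            out[i] = LABELS.index(lab)
        return out
    return y.astype(int)


class PDIVASClassifier(ClassifierMixin, BaseEstimator):
    """Forest classifier over the five splice features.

    Parameters
    ----------
    n_estimators : int, default 500
        Number of trees T; scores are multiples of 1/T.
    max_depth : int or None
        Maximum tree depth (None = grown out).
    max_samples : float or None
        Bootstrap sample fraction per tree; 1.0 and None both mean a
        full-size bootstrap.
    max_features : int or None
        Features considered per split; None = all five.
    random_state : int or None
        Seed; fixed seed gives bit-identical scores across runs.

    Attributes
    ----------
    forest_ : fitted sklearn RandomForestClassifier
    classes_ : array([0, 1]) (benign, pathogenic)
    feature_names_in_ : the five feature names
    feature_importances_ : impurity-decrease importances, summing to 1
    """

    def __init__(self, n_estimators: int = 500, max_depth=None,
                 max_samples=None, max_features=None, random_state=None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_samples = max_samples
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_matrix(X)
        y = encode_labels(y)
        if np.isnan(X).any():
            raise ValueError("training rows must be complete (no missing features)")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        max_samples = self.max_samples
        if max_samples is not None and max_samples >= 1.0:
            max_samples = None
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            max_samples=max_samples,
            max_features=self.max_features,
            bootstrap=True,
            random_state=self.random_state,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_names_in_ = np.asarray(FEATURE_NAMES, dtype=object)
        self.n_features_in_ = len(FEATURE_NAMES)
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict_score(self, X) -> np.ndarray:
        """Fraction of trees voting pathogenic, one score per row in [0, 1].

        Each tree votes its leaf's majority class (sklearn breaks exact leaf
        ties toward the first class, i.e. benign). Rows with missing features
        raise :class:`UnscorableVariant`: an incomplete variant is unscorable,
        never silently 0.
        """
        check_is_fitted(self, "forest_")
        X = _as_matrix(X)
        if np.isnan(X).any():
            raise UnscorableVariant("incomplete feature vector(s); cannot score")
        votes = np.zeros(len(X))
        for tree in self.forest_.estimators_:
            votes += tree.predict(X)
        return votes / len(self.forest_.estimators_)

    def predict_proba(self, X) -> np.ndarray:
        score = self.predict_score(X)
        return np.column_stack([1.0 - score, score])

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)

    def score_one(self, fv) -> float:
        """Score a single FeatureVector; raises UnscorableVariant if incomplete."""
        if not fv.is_complete:
            raise UnscorableVariant("feature vector incomplete")
        return float(self.predict_score(fv.to_array()[None, :])[0])


# ---------------------------------------------------------------------------
# Tuning and reporting


def _grid_points(grid: dict) -> list:
    keys = sorted(grid)
    points = [{}]
    for k in keys:
        points = [{**p, k: v} for p in points for v in grid[k]]
    return points


def _tie_key(hp: dict) -> tuple:
    depth = hp.get("max_depth")
    return (hp.get("n_estimators", 0),
            np.inf if depth is None else depth)


def tune_hyperparameters(X, y, grid: dict | None = None, k: int = 5,
                         seed: int | None = 0) -> dict:
    """Pick the grid point with the best mean cross-validated average precision.

    Stratified k-fold CV; deterministic for a fixed seed. Ties break toward
    the smaller model: fewer trees first, then shallower depth.
    Returns the winning hyperparameters with a ``cv_table`` DataFrame and the
    winning mean AP attached under keys ``"cv_table"`` / ``"cv_ap"``.
    """
    grid = grid if grid is not None else DEFAULT_GRID
    points = _grid_points(grid)
    if not points or not grid:
        raise ValueError("empty hyperparameter grid")
    X = _as_matrix(X)
    y = encode_labels(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need >= {k} rows per class for {k}-fold CV")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    rows = []
    for hp in points:
        aps = []
        for train_idx, test_idx in folds:
            model = PDIVASClassifier(random_state=seed, **hp)
            model.fit(X[train_idx], y[train_idx])
            s = model.predict_score(X[test_idx])
            aps.append(evaluation.average_precision(y[test_idx], s))
        rows.append({**hp, "mean_ap": float(np.mean(aps))})
    table = pd.DataFrame(rows)
    best_ap = table["mean_ap"].max()
    winners = [hp for hp, row in zip(points, rows)
               if row["mean_ap"] >= best_ap - 1e-12]
    best = min(winners, key=_tie_key)
    out = dict(best)
    out["cv_ap"] = float(best_ap)
    out["cv_table"] = table
    return out


def train(X, y, hp: dict | None = None, seed: int | None = 0) -> PDIVASClassifier:
    """Fit a forest on the full training set with chosen hyperparameters."""
    hp = {k: v for k, v in (hp or {}).items()
          if k in ("n_estimators", "max_depth", "max_samples", "max_features")}
    model = PDIVASClassifier(random_state=seed, **hp)
    return model.fit(X, y)


def predict(model: PDIVASClassifier, x) -> float:
    """Score one FeatureVector (see :meth:`PDIVASClassifier.score_one`)."""
    return model.score_one(x)


def feature_importances(model: PDIVASClassifier) -> dict:
    """Impurity-decrease importances per feature; non-negative, sum to 1."""
    check_is_fitted(model, "forest_")
    return dict(zip(FEATURE_NAMES, (float(w) for w in model.feature_importances_)))


def cumulative_feature_analysis(X_train, y_train, X_test, y_test,
                                ordered_features=FEATURE_NAMES,
                                hp: dict | None = None,
                                seed: int | None = 0) -> pd.DataFrame:
    """Train on growing feature prefixes and evaluate each on the same split.

    Returns one row per prefix with held-out average precision and max MCC.
    The same train/test pair is reused for every row so the deltas isolate
    each added feature's contribution.
    """
    if len(ordered_features) < 1:
        raise ValueError("need at least one feature")
    Xtr = _as_matrix(X_train)
    Xte = _as_matrix(X_test)
    ytr = encode_labels(y_train)
    yte = encode_labels(y_test)
    hp = {k: v for k, v in (hp or {}).items()
          if k in ("n_estimators", "max_depth", "max_samples", "max_features")}
    rows = []
    for i in range(1, len(ordered_features) + 1):
        prefix = list(ordered_features[:i])
        idx = [FEATURE_NAMES.index(f) for f in prefix]
        sub_hp = dict(hp)
        if sub_hp.get("max_features") is not None:
            sub_hp["max_features"] = min(sub_hp["max_features"], len(idx))
        forest = RandomForestClassifier(
            bootstrap=True, random_state=seed,
            **{k: (None if k == "max_samples" and v is not None and v >= 1.0 else v)
               for k, v in sub_hp.items()},
        )
        forest.fit(Xtr[:, idx], ytr)
        scores = np.zeros(len(Xte))
        for tree in forest.estimators_:
            scores += tree.predict(Xte[:, idx])
        scores /= len(forest.estimators_)
        _, mcc = evaluation.max_mcc(yte, scores)
        rows.append({
            "n_features": i,
            "features": "+".join(prefix),
            "average_precision": evaluation.average_precision(yte, scores),
            "max_mcc": mcc,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: PDIVASClassifier, path, metadata: dict | None = None) -> None:
    """Persist a fitted model to a single versioned file."""
    check_is_fitted(model, "forest_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.get_params(),
        "forest": model.forest_,
        "metadata": metadata or {},
    }
    joblib.dump(payload, path)


def load_model(path) -> PDIVASClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    model = PDIVASClassifier(**payload["params"])
    model.forest_ = payload["forest"]
    model.classes_ = model.forest_.classes_
    model.feature_names_in_ = np.asarray(FEATURE_NAMES, dtype=object)
    model.n_features_in_ = len(FEATURE_NAMES)
    model.feature_importances_ = model.forest_.feature_importances_
    model.metadata_ = payload["metadata"]
    return model


def write_training_report(path, hp: dict, seed, extra: dict | None = None) -> None:
    """JSON training report: CV table, chosen hyperparameters, seed."""
    report = {
        "seed": seed,
        "hyperparameters": {k: v for k, v in hp.items()
                            if k not in ("cv_table", "cv_ap")},
        "cv_ap": hp.get("cv_ap"),
        "cv_table": (hp["cv_table"].to_dict(orient="records")
                     if "cv_table" in hp else None),
    }
    if extra:
        report.update(extra)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
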