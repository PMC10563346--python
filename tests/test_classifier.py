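import numpy as np
import pandas as pd
import pytest

import pdivas as P
from pdivas.classifier import (
    PDIVASClassifier, SMALL_GRID, UnscorableVariant,
    cumulative_feature_analysis, feature_importances, load_model, save_model,
    train, tune_hyperparameters,
)
from pdivas.splice_features import FEATURE_NAMES, FeatureVector


def beta_dataset(n_path=100, n_benign=100, seed=0):
    """Near-separable two-class table: pathogenic gains ~ Beta(8,2),
    benign ~ Beta(2,8)."""
    rng = np.random.default_rng(seed)
    Xp = rng.beta(8, 2, size=(n_path, 5))
    Xb = rng.beta(2, 8, size=(n_benign, 5))
    X = pd.DataFrame(np.vstack([Xp, Xb]), columns=list(FEATURE_NAMES))
    y = np.array([1] * n_path + [0] * n_benign)
    return X, y


def test_score_is_fraction_of_trees_granularity():
    X, y = beta_dataset(seed=1)
    model = PDIVASClassifier(n_estimators=50, random_state=0).fit(X, y)
    s = model.predict_score(X)
    assert np.all((s >= 0) & (s <= 1))
    multiples = s * 50
    assert np.allclose(multiples, np.round(multiples), atol=1e-9)


def test_near_separable_data_high_average_precision():
    X, y = beta_dataset(n_path=100, n_benign=100, seed=2)
    tr, te = P.split_dataset(y, 0.7, seed=2)
    model = train(X.iloc[tr], y[tr], {"n_estimators": 200}, seed=2)
    ap = P.average_precision(y[te], model.predict_score(X.iloc[te]))
    assert ap >= 0.99


def test_identical_rows_mixed_labels_score_class_fraction():
    """With no signal, each tree votes its bootstrap majority; at a balanced
    mix the vote fraction sits at the class fraction, identically per row."""
    X = pd.DataFrame(np.full((200, 5), 0.5), columns=list(FEATURE_NAMES))
    y = np.array([0, 1] * 100)
    model = PDIVASClassifier(n_estimators=500, random_state=0).fit(X, y)
    s = model.predict_score(X)
    assert len(np.unique(s)) == 1
    assert abs(s[0] - 0.5) < 0.06


def test_fixed_seed_bit_identical_scores():
    X, y = beta_dataset(seed=3)
    s1 = PDIVASClassifier(n_estimators=100, random_state=7).fit(X, y).predict_score(X)
    s2 = PDIVASClassifier(n_estimators=100, random_state=7).fit(X, y).predict_score(X)
    assert np.array_equal(s1, s2)


def test_single_class_training_rejected():
    X, _ = beta_dataset(seed=0)
    with pytest.raises(ValueError):
        PDIVASClassifier(n_estimators=10, random_state=0).fit(X, np.zeros(len(X)))


def test_incomplete_vector_is_unscorable_not_zero():
    X, y = beta_dataset(seed=4)
    model = PDIVASClassifier(n_estimators=20, random_state=0).fit(X, y)
    fv = FeatureVector(0.5, 0.5, 0.5, None, 0.5)
    with pytest.raises(UnscorableVariant):
        model.score_one(fv)
    bad = X.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(UnscorableVariant):
        model.predict_score(bad)


def test_tune_single_point_grid_returns_it():
    X, y = beta_dataset(n_path=30, n_benign=30, seed=5)
    hp = tune_hyperparameters(X, y, grid={"n_estimators": [25]}, k=5, seed=0)
    assert hp["n_estimators"] == 25
    assert 0.0 <= hp["cv_ap"] <= 1.0
    with pytest.raises(ValueError):
        tune_hyperparameters(X, y, grid={}, k=5, seed=0)


def test_tune_prefers_deep_trees_on_xor_structure():
    """Depth-1 stumps cannot express a two-feature interaction; CV on average
    precision must pick the deeper setting."""
    rng = np.random.default_rng(0)
    n = 400
    a = rng.random(n) < 0.5
    b = rng.random(n) < 0.5
    X = pd.DataFrame({
        "spliceai_del_gain_mean": a.astype(float),
        "spliceai_del_gain_max": b.astype(float),
        "spliceai_raw_gain_mean": rng.random(n),
        "consplice": rng.random(n),
        "maxentscan": rng.random(n),
    }).clip(0, 1)
    y = (a ^ b).astype(int)
    hp = tune_hyperparameters(
        X, y, grid={"max_depth": [1, 8], "max_features": [None],
                    "n_estimators": [100]}, k=5, seed=0)
    assert hp["max_depth"] == 8


def test_tune_deterministic_and_tie_break():
    X, y = beta_dataset(n_path=25, n_benign=25, seed=6)
    grid = {"n_estimators": [50, 100], "max_depth": [4, None]}
    hp1 = tune_hyperparameters(X, y, grid=grid, k=5, seed=3)
    hp2 = tune_hyperparameters(X, y, grid=grid, k=5, seed=3)
    assert {k: hp1[k] for k in grid} == {k: hp2[k] for k in grid}
    # fully separable data ties every grid point at AP 1.0:
    # the smallest model (fewest trees, then shallowest) must win
    rng = np.random.default_rng(0)
    Xs = pd.DataFrame(np.vstack([rng.uniform(0.9, 1.0, (25, 5)),
                                 rng.uniform(0.0, 0.1, (25, 5))]),
                      columns=list(FEATURE_NAMES))
    ys = np.array([1] * 25 + [0] * 25)
    hp = tune_hyperparameters(Xs, ys, grid=grid, k=5, seed=0)
    assert hp["n_estimators"] == 50 and hp["max_depth"] == 4


def test_feature_importances_sum_and_dominance():
    rng = np.random.default_rng(1)
    n = 300
    informative = np.concatenate([rng.beta(8, 2, n // 2), rng.beta(2, 8, n // 2)])
    X = pd.DataFrame({
        "spliceai_del_gain_mean": informative,
        "spliceai_del_gain_max": rng.random(n),
        "spliceai_raw_gain_mean": rng.random(n),
        "consplice": rng.random(n),
        "maxentscan": rng.random(n),
    })
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    model = PDIVASClassifier(n_estimators=100, random_state=0).fit(X, y)
    imp = feature_importances(model)
    assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
    assert min(imp.values()) >= 0.0
    assert max(imp, key=imp.get) == "spliceai_del_gain_mean"


def test_cumulative_feature_analysis_rows_and_signal():
    rng = np.random.default_rng(2)
    n = 400
    informative = np.concatenate([rng.beta(8, 2, n // 2), rng.beta(2, 8, n // 2)])
    X = pd.DataFrame({
        "spliceai_del_gain_mean": rng.random(n),  # pure noise first
        "spliceai_del_gain_max": informative,
        "spliceai_raw_gain_mean": rng.random(n),
        "consplice": rng.random(n),
        "maxentscan": rng.random(n),
    })
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    tr, te = P.split_dataset(y, 0.7, seed=0)
    one = cumulative_feature_analysis(X.iloc[tr], y[tr], X.iloc[te], y[te],
                                      ordered_features=("spliceai_del_gain_mean",),
                                      hp={"n_estimators": 50}, seed=0)
    assert len(one) == 1
    table = cumulative_feature_analysis(
        X.iloc[tr], y[tr], X.iloc[te], y[te],
        ordered_features=("spliceai_del_gain_mean", "spliceai_del_gain_max"),
        hp={"n_estimators": 50}, seed=0)
    assert len(table) == 2
    # adding the only informative feature to a noise prefix raises AP sharply
    assert table.average_precision.iloc[1] > table.average_precision.iloc[0] + 0.2
    with pytest.raises(ValueError):
        cumulative_feature_analysis(X.iloc[tr], y[tr], X.iloc[te], y[te],
                                    ordered_features=())


def test_model_round_trip_serialization(tmp_path):
    X, y = beta_dataset(seed=8)
    model = PDIVASClassifier(n_estimators=30, random_state=5).fit(X, y)
    path = tmp_path / "model.joblib"
    save_model(model, path, metadata={"note": "test"})
    back = load_model(path)
    assert np.array_equal(model.predict_score(X), back.predict_score(X))
    assert back.metadata_ == {"note": "test"}


def test_sklearn_estimator_contract():
    model = PDIVASClassifier(n_estimators=10, random_state=0)
    params = model.get_params()
    assert params["n_estimators"] == 10
    model.set_params(n_estimators=20)
    assert model.get_params()["n_estimators"] == 20
    X, y = beta_dataset(n_path=20, n_benign=20, seed=9)
    model.fit(X, y)
    assert list(model.classes_) == [0, 1]
    assert model.predict(X).shape == (40,)
    proba = model.predict_proba(X)
    assert np.allclose(proba.sum(axis=1), 1.0)
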