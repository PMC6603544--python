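"""NNI regressors: splitting, grids, cross-validation, importance."""

import numpy as np
import pandas as pd
import pytest

from plantnni.regression import (
    DEFAULT_GRIDS,
    SVR_GRID_VALUES,
    CVResult,
    ImportanceTable,
    ModelConfig,
    NNIRegressor,
    SingleLayerNet,
    cross_validate,
    feature_importance,
    split_dataset,
)


def _linear_data(n=120, d=5, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = 0.7 + 0.2 * X[:, 0] + 0.1 * X[:, 1] + noise * rng.standard_normal(n)
    cols = [f"f{i}" for i in range(d)]
    return pd.DataFrame(X, columns=cols), pd.Series(y)


# ------------------------------------------------------------- splitting


def test_split_sizes_match_study_convention():
    df = pd.DataFrame({"x": np.arange(382)})
    train, test = split_dataset(df, train_frac=0.75, seed=0)
    assert (len(train), len(test)) == (287, 95)


def test_split_is_a_reproducible_partition():
    df = pd.DataFrame({"x": np.arange(40)})
    a_train, a_test = split_dataset(df, seed=5)
    b_train, b_test = split_dataset(df, seed=5)
    assert a_train.index.tolist() == b_train.index.tolist()
    assert set(a_train.index) | set(a_test.index) == set(range(40))
    assert set(a_train.index) & set(a_test.index) == set()


def test_split_rejects_bad_fraction():
    df = pd.DataFrame({"x": np.arange(20)})
    for frac in (0.0, 1.0, -0.2):
        with pytest.raises(ValueError):
            split_dataset(df, train_frac=frac)


# ----------------------------------------------------------------- grids


def test_svr_grid_is_the_17_powers_of_two():
    assert len(SVR_GRID_VALUES) == 17
    assert SVR_GRID_VALUES[0] == 0.00390625
    assert SVR_GRID_VALUES[-1] == 256.0
    assert np.allclose(np.diff(np.log2(SVR_GRID_VALUES)), 1.0)
    assert DEFAULT_GRIDS["svr"]["cost"] == list(SVR_GRID_VALUES)
    assert DEFAULT_GRIDS["svr"]["gamma"] == list(SVR_GRID_VALUES)


def test_default_grid_shapes():
    assert DEFAULT_GRIDS["rf"] == {"ntree": [300], "mtry": [2, 5, 8]}
    assert DEFAULT_GRIDS["nn"]["decay"] == [0, 0.1, 0.01]
    assert DEFAULT_GRIDS["nn"]["size"] == [2, 5, 9]
    assert len(ModelConfig("svr").candidates()) == 289


def test_empty_grid_rejected():
    with pytest.raises(ValueError):
        ModelConfig("rf", grid={"mtry": []})
    with pytest.raises(ValueError):
        ModelConfig("boost")


def test_tie_break_prefers_parsimonious_candidate():
    cands = ModelConfig("nn").candidates()
    assert cands[0] == {"size": 2, "decay": 0}
    mean = np.ones(len(cands))
    res = CVResult(candidates=cands, mean_rmse=mean, sd_rmse=np.zeros(len(cands)),
                   fold_assignment=np.zeros(1, dtype=int))
    assert res.best_params == {"size": 2, "decay": 0}


# ------------------------------------------------------- cross-validation


def test_constant_target_gives_near_zero_rmse():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 3))
    y = np.full(40, 0.8)
    res = cross_validate(X, y, ModelConfig("rf", grid={"ntree": [50], "mtry": [2]}))
    assert res.mean_rmse[res.best_index] == pytest.approx(0.0, abs=1e-6)


def test_cv_choice_reproducible_under_seed():
    X, y = _linear_data()
    grid = {"cost": [0.25, 1.0, 4.0], "gamma": [0.01, 0.1]}
    a = cross_validate(X.to_numpy(), y, ModelConfig("svr", grid=grid, seed=3))
    b = cross_validate(X.to_numpy(), y, ModelConfig("svr", grid=grid, seed=3))
    assert a.best_params == b.best_params
    assert np.array_equal(a.mean_rmse, b.mean_rmse)
    assert np.array_equal(a.fold_assignment, b.fold_assignment)
    assert (a.sd_rmse >= 0).all()


def test_cv_requires_enough_samples():
    with pytest.raises(ValueError):
        cross_validate(np.zeros((5, 2)), np.zeros(5), ModelConfig("rf"))


# --------------------------------------------------------------- fitting


@pytest.mark.parametrize("algorithm", ["rf", "svr", "nn"])
def test_fit_predict_deterministic(algorithm):
    X, y = _linear_data(n=60)
    grid = {"rf": {"ntree": [50], "mtry": [2]},
            "svr": {"cost": [1.0], "gamma": [0.1]},
            "nn": {"size": [3], "decay": [0.01]}}[algorithm]
    preds = []
    for _ in range(2):
        est = NNIRegressor(algorithm=algorithm, grid=grid, random_state=1)
        est.fit(X, y)
        preds.append(est.predict(X))
    assert np.array_equal(preds[0], preds[1])
    assert np.all(np.isfinite(preds[0]))


def test_nn_trains_to_finite_weights():
    X, y = _linear_data(n=80)
    net = SingleLayerNet(size=5, decay=0.01, random_state=0)
    net.fit((X - X.mean()) / X.std(), np.clip(y, 0.05, 0.95))
    assert np.all(np.isfinite(net.theta_))


def test_nn_logistic_output_bounded():
    X, y = _linear_data(n=80)
    net = SingleLayerNet(size=5, decay=0.0, output="logistic", random_state=0)
    net.fit(X.to_numpy(), y.to_numpy())
    pred = net.predict(X.to_numpy())
    assert pred.min() > 0.0 and pred.max() < 1.0


def test_rf_in_sample_beats_out_of_sample():
    X, y = _linear_data(n=120, noise=0.1)
    train_X, test_X = X.iloc[:90], X.iloc[90:]
    train_y, test_y = y.iloc[:90], y.iloc[90:]
    est = NNIRegressor("rf", grid={"ntree": [100], "mtry": [2]}, random_state=0)
    est.fit(train_X, train_y)

    def r2(Xs, ys):
        pred = est.predict(Xs)
        return 1 - np.sum((ys - pred) ** 2) / np.sum((ys - ys.mean()) ** 2)

    assert r2(train_X, train_y) >= r2(test_X, test_y)


def test_rf_predictions_within_training_target_range():
    X, y = _linear_data(n=100)
    est = NNIRegressor("rf", grid={"ntree": [100], "mtry": [2]}, random_state=0)
    est.fit(X, y)
    rng = np.random.default_rng(9)
    far = pd.DataFrame(rng.normal(scale=5.0, size=(30, X.shape[1])),
                       columns=X.columns)
    pred = est.predict(far)
    assert pred.min() >= y.min() - 1e-12
    assert pred.max() <= y.max() + 1e-12


def test_predict_empty_input_and_missing_features():
    X, y = _linear_data(n=40)
    est = NNIRegressor("svr", grid={"cost": [1.0], "gamma": [0.1]})
    est.fit(X, y)
    assert est.predict(X.iloc[:0]).shape == (0,)
    with pytest.raises(ValueError, match="missing"):
        est.predict(X.drop(columns=["f0"]))


def test_nonfinite_features_rejected():
    X, y = _linear_data(n=40)
    X.iloc[0, 0] = np.nan
    with pytest.raises(ValueError):
        NNIRegressor("rf").fit(X, y)


# ------------------------------------------------------------ importance


def test_constant_feature_importance_exactly_zero():
    X, y = _linear_data(n=60)
    X["const"] = 1.0
    est = NNIRegressor("rf", grid={"ntree": [50], "mtry": [2]}, random_state=0)
    est.fit(X, y)
    imp = feature_importance(est, X, y, n_permutations=3, seed=0)
    assert imp.scores["const"] == 0.0
    assert imp.method == "%IncMSE"


def test_signal_feature_ranks_first_irrelevant_near_zero():
    rng = np.random.default_rng(4)
    n = 150
    X = pd.DataFrame({"signal": rng.normal(size=n),
                      "irrelevant": rng.normal(size=n)})
    y = 0.5 + 0.3 * X["signal"] + 0.02 * rng.standard_normal(n)
    est = NNIRegressor("rf", grid={"ntree": [100], "mtry": [1]}, random_state=0)
    est.fit(X, y)
    imp = feature_importance(est, X, y, n_permutations=5, seed=0)
    assert imp.top(1) == ["signal"]
    assert abs(imp.scores["irrelevant"]) < 0.3 * imp.scores["signal"]


def test_importance_rejects_zero_permutations():
    X, y = _linear_data(n=40)
    est = NNIRegressor("rf", grid={"ntree": [20], "mtry": [2]}).fit(X, y)
    with pytest.raises(ValueError):
        feature_importance(est, X, y, n_permutations=0)
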