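"""NNI regression: random forest, RBF support-vector regression, and a
single-hidden-layer neural network, tuned by 10-fold cross-validation.

The dataset (feature table joined with measured NNI) is split 75/25
into training and test sets.  On the training set each algorithm's
hyperparameter grid is scored by 10-fold cross-validated RMSE and the
candidate with the lowest mean RMSE wins (ties go to the most
parsimonious candidate).  Default grids:

* RF — 300 trees, ``mtry`` (features tried per split) in {2, 5, 8};
* SVR — RBF kernel, cost and gamma each over the 17 powers of two
  from 2**-8 to 2**8 (epsilon fixed at 0.1);
* NN — one logistic hidden layer, weight decay in {0, 0.1, 0.01} and
  hidden size in {2, 5, 9}.

The network defaults to a logistic output unit, so its predictions lie
in (0, 1) and saturate at 1.000 — adequate for NNI near its usual range
but a documented ceiling; a linear output is available via
``nn_output="linear"``.  Feature importance for all three algorithms is
permutation-based %IncMSE, the percentage increase in mean squared
error when one feature's values are shuffled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SVR_GRID_VALUES",
    "DEFAULT_GRIDS",
    "ModelConfig",
    "CVResult",
    "split_dataset",
    "SingleLayerNet",
    "cross_validate",
    "train_final",
    "NNIRegressor",
    "feature_importance",
    "ImportanceTable",
]

#: The 17 powers of two 2**-8 .. 2**8 used for both SVR cost and gamma.
SVR_GRID_VALUES = tuple(float(2.0**k) for k in range(-8, 9))

DEFAULT_GRIDS = {
    "rf": {"ntree": [300], "mtry": [2, 5, 8]},
    "svr": {"cost": list(SVR_GRID_VALUES), "gamma": list(SVR_GRID_VALUES)},
    "nn": {"size": [2, 5, 9], "decay": [0, 0.1, 0.01]},
}

# candidate enumeration order = parsimony order for tie-breaking
_PARAM_ORDER = {"rf": ["mtry", "ntree"], "svr": ["cost", "gamma"],
                "nn": ["size", "decay"]}


@dataclass
class ModelConfig:
    """Algorithm choice plus hyperparameter grid and seed."""

    algorithm: str
    grid: dict | None = None
    seed: int = 0
    nn_output: str = "logistic"

    def __post_init__(self) -> None:
        if self.algorithm not in DEFAULT_GRIDS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def candidates(self) -> list[dict]:
        keys = [k for k in _PARAM_ORDER[self.algorithm] if k in self.grid]
        keys += [k for k in self.grid if k not in keys]
        values = [sorted(self.grid[k]) for k in keys]
        return [dict(zip(keys, combo)) for combo in itertools.product(*values)]


@dataclass
class CVResult:
    """Per-candidate cross-validation RMSE summary."""

    candidates: list[dict]
    mean_rmse: np.ndarray
    sd_rmse: np.ndarray
    fold_assignment: np.ndarray
    best_index: int = field(init=False)
    best_params: dict = field(init=False)

    def __post_init__(self) -> None:
        self.best_index = int(np.argmin(self.mean_rmse))  # first min = parsimony
        self.best_params = self.candidates[self.best_index]


def split_dataset(data: pd.DataFrame, train_frac: float = 0.75, seed: int = 0):
    """Random disjoint train/test split with round(train_frac * n) training rows."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(data)
    if n < 8:
        raise ValueError("need at least 8 samples to split")
    n_train = int(math.floor(train_frac * n + 0.5))  # half-up
    perm = np.random.default_rng(seed).permutation(n)
    return data.iloc[perm[:n_train]], data.iloc[perm[n_train:]]


class SingleLayerNet(BaseEstimator, RegressorMixin):
    """Single-hidden-layer feed-forward network trained by L-BFGS.

    Logistic hidden units; logistic (default) or identity output unit.
    The objective is the sum of squared errors plus ``decay`` times the
    sum of squared weights (biases included), minimized from a small
    uniform random initialization.  Deterministic for a fixed
    ``random_state``.
    """

    def __init__(self, size: int = 5, decay: float = 0.0, output: str = "logistic",
                 random_state: int = 0, maxiter: int = 500, init_range: float = 0.7):
        self.size = size
        self.decay = decay
        self.output = output
        self.random_state = random_state
        self.maxiter = maxiter
        self.init_range = init_range

    def _unpack(self, theta: np.ndarray, d: int):
        s = self.size
        i = 0
        w1 = theta[i:i + d * s].reshape(d, s); i += d * s
        b1 = theta[i:i + s]; i += s
        w2 = theta[i:i + s]; i += s
        b2 = theta[i]
        return w1, b1, w2, b2

    def _loss_grad(self, theta, X, y):
        d = X.shape[1]
        w1, b1, w2, b2 = self._unpack(theta, d)
        h = expit(X @ w1 + b1)
        z = h @ w2 + b2
        logistic = self.output == "logistic"
        yhat = expit(z) if logistic else z
        resid = yhat - y
        loss = float(resid @ resid) + self.decay * float(theta @ theta)
        dz = 2.0 * resid * (yhat * (1 - yhat) if logistic else 1.0)
        gw2 = h.T @ dz
        gb2 = dz.sum()
        dh = np.outer(dz, w2) * h * (1 - h)
        gw1 = X.T @ dh
        gb1 = dh.sum(axis=0)
        grad = np.concatenate([gw1.ravel(), gb1, gw2, [gb2]]) + 2.0 * self.decay * theta
        return loss, grad

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        d = X.shape[1]
        n_par = d * self.size + self.size + self.size + 1
        rng = np.random.default_rng(self.random_state)
        theta0 = rng.uniform(-self.init_range, self.init_range, n_par)
        res = minimize(self._loss_grad, theta0, args=(X, y), jac=True,
                       method="L-BFGS-B", options={"maxiter": self.maxiter})
        self.theta_ = res.x
        self.n_features_in_ = d
        self.converged_ = bool(res.success)
        return self

    def predict(self, X):
        check_is_fitted(self, "theta_")
        X = np.asarray(X, dtype=float)
        w1, b1, w2, b2 = self._unpack(self.theta_, X.shape[1])
        z = expit(X @ w1 + b1) @ w2 + b2
        return expit(z) if self.output == "logistic" else z


def _build_estimator(config: ModelConfig, params: dict):
    if config.algorithm == "rf":
        return RandomForestRegressor(
            n_estimators=int(params["ntree"]),
            max_features=int(params["mtry"]),
            random_state=config.seed,
        )
    if config.algorithm == "svr":
        return SVR(kernel="rbf", C=params["cost"], gamma=params["gamma"],
                   epsilon=0.1)
    return SingleLayerNet(size=int(params["size"]), decay=params["decay"],
                          output=config.nn_output, random_state=config.seed)


def cross_validate(X, y, config: ModelConfig, cv: int = 10) -> CVResult:
    """Grid scoring by k-fold cross-validated RMSE (mean ± SD across folds)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(X) < cv:
        raise ValueError(f"need at least {cv} training samples for {cv}-fold CV")
    candidates = config.candidates()
    kf = KFold(n_splits=cv, shuffle=True, random_state=config.seed)
    splits = list(kf.split(X))
    fold_assignment = np.empty(len(X), dtype=int)
    for f, (_, test_idx) in enumerate(splits):
        fold_assignment[test_idx] = f
    rmse = np.empty((len(candidates), cv))
    for ci, params in enumerate(candidates):
        for f, (tr, te) in enumerate(splits):
            est = _build_estimator(config, params)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            rmse[ci, f] = float(np.sqrt(np.mean((pred - y[te]) ** 2)))
    return CVResult(candidates=candidates, mean_rmse=rmse.mean(axis=1),
                    sd_rmse=rmse.std(axis=1), fold_assignment=fold_assignment)


def train_final(X, y, config: ModelConfig, params: dict):
    """Fit the chosen candidate on the full training set."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    est = _build_estimator(config, params)
    est.fit(X, np.asarray(y, dtype=float).reshape(-1))
    return est


class NNIRegressor(BaseEstimator, RegressorMixin):
    """Tuned NNI regressor (``algorithm`` in {"rf", "svr", "nn"}).

    ``fit`` z-scores the features with training-set statistics, selects
    hyperparameters by ``cv``-fold cross-validated RMSE over ``grid``
    (default grid per algorithm), and refits the winner on the full
    training set.  Fitted attributes: ``cv_result_``, ``best_params_``,
    ``model_``, ``mean_``, ``scale_``, ``feature_names_in_``.
    """

    def __init__(self, algorithm: str = "rf", grid: dict | None = None,
                 cv: int = 10, random_state: int = 0,
                 nn_output: str = "logistic"):
        self.algorithm = algorithm
        self.grid = grid
        self.cv = cv
        self.random_state = random_state
        self.nn_output = nn_output

    def _validate_X(self, X, fitting: bool):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            if fitting:
                self.feature_names_in_ = names
            elif hasattr(self, "feature_names_in_"):
                missing = [f for f in self.feature_names_in_ if f not in names]
                if missing:
                    raise ValueError(f"missing features: {missing}")
                X = X[self.feature_names_in_]
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if fitting:
                self.feature_names_in_ = None
        if arr.ndim != 2:
            raise ValueError("expected a 2-D feature array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite feature values")
        return arr

    def fit(self, X, y):
        arr = self._validate_X(X, fitting=True)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(y) != len(arr):
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = arr.shape[1]
        self.mean_ = arr.mean(axis=0)
        scale = arr.std(axis=0)
        self.scale_ = np.where(scale == 0, 1.0, scale)
        z = (arr - self.mean_) / self.scale_
        config = ModelConfig(algorithm=self.algorithm, grid=self.grid,
                             seed=self.random_state, nn_output=self.nn_output)
        grid = config.grid
        if self.algorithm == "rf":
            # mtry cannot exceed the feature count
            grid = dict(grid)
            grid["mtry"] = [m for m in grid["mtry"] if m <= arr.shape[1]] or [
                arr.shape[1]
            ]
            config.grid = grid
        self.cv_result_ = cross_validate(z, y, config, cv=self.cv)
        self.best_params_ = self.cv_result_.best_params
        self.model_ = train_final(z, y, config, self.best_params_)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        arr = self._validate_X(X, fitting=False)
        if arr.shape[0] == 0:
            return np.empty(0)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        pred = self.model_.predict((arr - self.mean_) / self.scale_)
        if not np.all(np.isfinite(pred)):
            raise ValueError("model produced non-finite predictions")
        return pred


@dataclass
class ImportanceTable:
    """Permutation importance scores (%IncMSE) per feature."""

    scores: pd.Series
    method: str = "%IncMSE"

    def top(self, k: int = 5) -> list[str]:
        return list(self.scores.sort_values(ascending=False).index[:k])


def feature_importance(model: NNIRegressor, X, y, n_permutations: int = 10,
                       seed: int = 0) -> ImportanceTable:
    """Permutation %IncMSE: 100 * (MSE_permuted - MSE_base) / MSE_base.

    Applied uniformly to all three algorithms so scores are comparable.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"x{i}" for i in range(np.asarray(X).shape[1])])
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(
        X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    base_pred = (model.predict(X) if isinstance(X, pd.DataFrame)
                 else model.predict(arr))
    base_mse = float(np.mean((base_pred - y) ** 2))
    rng = np.random.default_rng(seed)
    scores = {}
    for j, name in enumerate(names):
        inc = []
        for _ in range(n_permutations):
            perm = arr.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            Xp = pd.DataFrame(perm, columns=names) if isinstance(X, pd.DataFrame) else perm
            mse = float(np.mean((model.predict(Xp) - y) ** 2))
            inc.append(mse - base_mse)
        scores[name] = 100.0 * float(np.mean(inc)) / base_mse if base_mse > 0 else 0.0
    return ImportanceTable(scores=pd.Series(scores))
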