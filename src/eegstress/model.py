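"""Individualized regressors with exhaustive grid-search cross-validation.

Four regressor families are fitted per participant — ridge regression
(on polynomial feature expansions), random forest, multi-layer
perceptron and support vector regression — each over its fixed
hyperparameter grid (18, 18, 24 and 60 combinations respectively).
Every combination is scored by 5-fold cross-validation (mean squared
error) on the training rows only; the winner is refitted on the full
training set and evaluated once on the held-out survey rows.

Fold assignment is a contiguous, unshuffled split by default (fully
deterministic); a seeded shuffled split is available via ``shuffle``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures
from sklearn.svm import SVR

FAMILIES = ("ridge", "random_forest", "mlp", "svr")

#: the hyperparameter grids explored per family (order fixed; ties in CV
#: score resolve to the earliest combination in this enumeration order).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ridge": {
        "degree": [1, 2, 3],
        "alpha": [1e-4, 1e-3, 1e-2, 1e-1, 10.0, 1e2],
    },
    "random_forest": {
        "n_estimators": [100, 200, 300],
        "max_features": [5, 6, 7],
        "max_depth": [6, 7],
    },
    "mlp": {
        "hidden_layers": [1, 2],
        "neurons": [3, 4],
        "activation": ["relu", "tanh"],
        "alpha": [1e-3, 1e-2, 1e-1],
    },
    "svr": {
        "kernel": ["linear", "poly", "rbf", "sigmoid"],
        "C": [2.0**-5, 2.0**-3, 2.0**-1, 2.0, 2.0**3],
        "epsilon": [1e-3, 1e-2, 1e-1],
    },
}


def reduced_grids() -> dict[str, dict[str, list]]:
    """A thinned grid (values drawn from the full one) for quick
    structural runs, smoke tests and examples."""
    return {
        "ridge": {"degree": [1], "alpha": [1e-2, 10.0]},
        "random_forest": {"n_estimators": [100], "max_features": [5], "max_depth": [6, 7]},
        "mlp": {"hidden_layers": [1], "neurons": [3], "activation": ["relu"], "alpha": [1e-2]},
        "svr": {"kernel": ["rbf"], "C": [2.0], "epsilon": [1e-2, 1e-1]},
    }


def grid_combinations(family: str, grid: dict[str, list] | None = None) -> list[dict]:
    """All hyperparameter combinations of a family, in deterministic order."""
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def make_estimator(
    family: str,
    params: dict,
    seed: int = 0,
    mlp_max_iter: int = 500,
    mlp_solver: str = "lbfgs",
):
    """Instantiate a regressor for one hyperparameter combination.

    Ridge's "polynomial degree" is a polynomial expansion of the seven
    feature columns ahead of the linear ridge fit. The MLP uses the
    lbfgs solver: with a handful of neurons and a few hundred samples it
    converges quickly and deterministically.
    """
    if family == "ridge":
        return Pipeline(
            [
                ("poly", PolynomialFeatures(degree=params["degree"], include_bias=False)),
                ("ridge", Ridge(alpha=params["alpha"])),
            ]
        )
    if family == "random_forest":
        return RandomForestRegressor(
            n_estimators=params["n_estimators"],
            max_features=params["max_features"],
            max_depth=params["max_depth"],
            random_state=seed,
            n_jobs=1,
        )
    if family == "mlp":
        hidden = (params["neurons"],) * params["hidden_layers"]
        return MLPRegressor(
            hidden_layer_sizes=hidden,
            activation=params["activation"],
            alpha=params["alpha"],
            solver=mlp_solver,
            max_iter=mlp_max_iter,
            random_state=seed,
        )
    if family == "svr":
        return SVR(kernel=params["kernel"], C=params["C"], epsilon=params["epsilon"])
    raise ValueError(f"unknown regressor family {family!r}")


def scale_columns(
    X: np.ndarray, train_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns using statistics of the training rows only.

    Returns the fully transformed matrix plus the per-column location
    (training mean) and scale (training sd; 1 for zero-variance columns),
    so test rows are shifted and scaled with training parameters alone.
    """
    X = np.asarray(X, dtype=float)
    loc = X[train_idx].mean(axis=0)
    scale = X[train_idx].std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - loc) / scale, loc, scale


def cv_folds(n: int, folds: int = 5, shuffle: bool = False, seed: int = 0) -> list[np.ndarray]:
    """Fold membership over n training rows: contiguous by default."""
    order = np.arange(n)
    if shuffle:
        np.random.default_rng(seed).shuffle(order)
    return [f for f in np.array_split(order, folds) if len(f)]


@dataclass
class FitResult:
    """Outcome of a grid search: winner, its model, and the CV table."""

    family: str
    best_params: dict
    best_cv_mse: float
    cv_table: list = field(repr=False)  # (params, mean_mse, per-fold mses)
    model: object = field(repr=False, default=None)
    n_fold_fits: int = 0

    @property
    def n_combinations(self) -> int:
        return len(self.cv_table)


def grid_search_fit(
    family: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    grid: dict[str, list] | None = None,
    shuffle: bool = False,
    mlp_max_iter: int = 500,
) -> FitResult:
    """Score every combination by k-fold CV, refit the winner on all rows.

    A combination that fails to fit on some fold is scored as worst
    (infinite error) rather than aborting the search. The minimum mean
    CV error wins; ties break to the earliest combination in grid order.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    combos = grid_combinations(family, grid)
    fold_idx = cv_folds(len(y_train), folds=folds, shuffle=shuffle, seed=seed)
    table, n_fits = [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for params in combos:
            fold_mses = []
            for hold in fold_idx:
                fit_rows = np.setdiff1d(np.arange(len(y_train)), hold)
                try:
                    est = make_estimator(family, params, seed=seed, mlp_max_iter=mlp_max_iter)
                    est.fit(X_train[fit_rows], y_train[fit_rows])
                    pred = est.predict(X_train[hold])
                    mse = float(np.mean((y_train[hold] - pred) ** 2))
                    if not np.isfinite(mse):
                        mse = np.inf
                except Exception:
                    mse = np.inf
                fold_mses.append(mse)
                n_fits += 1
            table.append((params, float(np.mean(fold_mses)), fold_mses))
        best_i = int(np.argmin([row[1] for row in table]))
        best_params = table[best_i][0]
        model = make_estimator(family, best_params, seed=seed, mlp_max_iter=mlp_max_iter)
        model.fit(X_train, y_train)
    return FitResult(
        family=family,
        best_params=best_params,
        best_cv_mse=table[best_i][1],
        cv_table=table,
        model=model,
        n_fold_fits=n_fits,
    )


def predict(fit: FitResult, X: np.ndarray, clip: bool = False) -> np.ndarray:
    """Predictions of the refitted winner; optionally clipped to [1, 5]."""
    yhat = np.asarray(fit.model.predict(np.asarray(X, dtype=float)), dtype=float)
    if not np.isfinite(yhat).all():
        raise ValueError("model produced non-finite predictions")
    return np.clip(yhat, 1.0, 5.0) if clip else yhat
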