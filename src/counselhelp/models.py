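"""Helpfulness-vote regression: five algorithms under ten-fold CV MAE.

The outcome is the raw helpful-vote count (no transform by default; an
optional ``log1p`` flag exists in the pipeline config).  Model comparison
runs every algorithm over every feature-source combination with a
*shared* fold partition, so the resulting grid of mean absolute errors is
paired across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = ["ALGORITHMS", "ModelSpec", "EvaluationResult", "make_estimator",
           "fit_regressor", "cross_validate_mae", "compare_feature_sets",
           "SOURCE_SET_LABELS"]

ALGORITHMS = ("linear_regression", "ridge", "lasso", "svr", "random_forest")

#: display labels used in the comparison grid
ALGORITHM_LABELS = {
    "linear_regression": "Linear regression",
    "ridge": "Ridge",
    "lasso": "Lasso",
    "svr": "SVR",
    "random_forest": "Random forest",
}

SOURCE_SET_LABELS = {
    ("counselor",): "counselor",
    ("counselee",): "counselee",
    ("synchrony",): "synchrony",
    ("counselee", "counselor", "synchrony"): "all_sources",
}


@dataclass(frozen=True)
class ModelSpec:
    """One regressor configuration.

    Defaults: ridge/lasso penalty 1.0; SVR linear kernel, C=1.0,
    epsilon=0.1; random forest 500 trees, unlimited depth, seeded.
    """

    algorithm: str = "random_forest"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; one of {ALGORITHMS}")


def make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "linear_regression":
        return LinearRegression(**hp)
    if spec.algorithm == "ridge":
        hp.setdefault("alpha", 1.0)
        return Ridge(**hp)
    if spec.algorithm == "lasso":
        hp.setdefault("alpha", 1.0)
        return Lasso(**hp)
    if spec.algorithm == "svr":
        hp.setdefault("kernel", "linear")
        hp.setdefault("C", 1.0)
        hp.setdefault("epsilon", 0.1)
        return SVR(**hp)
    hp.setdefault("n_estimators", 500)
    hp.setdefault("random_state", spec.seed)
    return RandomForestRegressor(**hp)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError(f"feature matrix shape {X.shape}: need >=2 rows, "
                         ">=1 column")
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in X or y")
    return X, y


def fit_regressor(X, y, spec: ModelSpec):
    """Fit one regressor; deterministic given ``spec.seed``."""
    X, y = _check_xy(X, y)
    est = make_estimator(spec)
    est.fit(X, y)
    return est


@dataclass
class EvaluationResult:
    algorithm: str
    feature_source_set: tuple[str, ...]
    fold_maes: list[float]
    cv_seed: int

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_maes))


def cross_validate_mae(X, y, spec: ModelSpec, n_folds: int = 10,
                       cv_seed: int = 0,
                       folds: Sequence[tuple[np.ndarray, np.ndarray]] | None
                       = None) -> EvaluationResult:
    """Held-out MAE over a seeded shuffled k-fold partition.

    Passing precomputed ``folds`` lets several evaluations share one
    partition (paired comparison).
    """
    X, y = _check_xy(X, y)
    if folds is None:
        if len(y) < n_folds:
            raise ValueError(
                f"{len(y)} rows < {n_folds} folds")
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=cv_seed)
        folds = list(kf.split(X))
    maes = []
    for train_idx, test_idx in folds:
        est = make_estimator(spec)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        maes.append(float(np.mean(np.abs(pred - y[test_idx]))))
    return EvaluationResult(spec.algorithm, (), maes, cv_seed)


def compare_feature_sets(table, y, specs: Sequence[ModelSpec],
                         source_sets: Sequence[tuple[str, ...]],
                         n_folds: int = 10, cv_seed: int = 0,
                         ) -> tuple[pd.DataFrame, list[EvaluationResult]]:
    """CV-MAE grid: one row per algorithm, one column per source set,
    plus per-algorithm and per-source-set means.

    All cells share the same fold partition.  ``table`` is a
    :class:`~counselhelp.features.FeatureTable`.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < n_folds:
        raise ValueError(f"{len(y)} rows < {n_folds} folds")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=cv_seed)
    folds = list(kf.split(np.zeros((len(y), 1))))

    results: list[EvaluationResult] = []
    grid: dict[str, dict[str, float]] = {}
    for spec in specs:
        alg_label = ALGORITHM_LABELS[spec.algorithm]
        grid[alg_label] = {}
        for srcs in source_sets:
            if not srcs:
                raise ValueError("empty source set")
            cols = table.columns_for_source(srcs)
            if not cols:
                raise ValueError(f"no columns tagged with sources {srcs}")
            X = table.data[cols].to_numpy(dtype=float)
            res = cross_validate_mae(X, y, spec, n_folds, cv_seed,
                                     folds=folds)
            res.feature_source_set = tuple(srcs)
            results.append(res)
            label = SOURCE_SET_LABELS.get(tuple(srcs),
                                          "+".join(srcs))
            grid[alg_label][label] = res.mean_mae
    df = pd.DataFrame(grid).T
    df["algorithm_mean"] = df.mean(axis=1)
    df.loc["source_mean"] = df.mean(axis=0)
    df.index.name = "algorithm"
    return df, results
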