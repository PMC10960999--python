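"""Benchmark of tree-ensemble and nearest-neighbour regressors against
multiple linear regression on the coupled (ND, covariate) feature set.

Algorithms: decision tree (max depth 10), random forest (100 trees),
k-nearest neighbours (k = 3, features standardised with training-set
statistics), gradient-boosted trees (100 trees, depth 3, learning rate
0.1) and OLS.  Data are split once into 70% training / 30% testing with a
seeded random partition; R^2 and RMSE are reported for both partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .metrics import metrics
from .records import ValidationError

ALGORITHMS = ("DT", "RF", "KNN", "GBDT", "MLR")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "DT": {"max_depth": 10},
    "RF": {"n_estimators": 100, "max_depth": 10},
    "KNN": {"n_neighbors": 3},
    "GBDT": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "MLR": {},
}


@dataclass
class BenchmarkResult:
    algorithm: str
    r2_sim: float        # training ("simulating") partition
    rmse_sim: float
    r2_val: float        # testing ("verification") partition
    rmse_val: float
    seed: int
    train_fraction: float
    hyperparameters: dict = field(default_factory=dict)


def split_data(obs: pd.DataFrame, fraction: float = 0.7, seed: int = 0
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random train/test partition with ceil(fraction*n) training rows."""
    n = len(obs)
    if n < 10:
        raise ValidationError(f"need >= 10 rows to split, got {n}")
    n_train = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return obs.iloc[perm[:n_train]], obs.iloc[perm[n_train:]]


def _build(algorithm: str, hp: dict, seed: int):
    if algorithm == "DT":
        return DecisionTreeRegressor(random_state=seed, **hp)
    if algorithm == "RF":
        return RandomForestRegressor(random_state=seed, **hp)
    if algorithm == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsRegressor(**hp))
    if algorithm == "GBDT":
        if hp.get("n_estimators", 1) < 1:
            raise ValidationError("GBDT needs at least one tree")
        return GradientBoostingRegressor(random_state=seed, **hp)
    if algorithm == "MLR":
        return LinearRegression(**hp)
    raise ValidationError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def fit_predict(algorithm: str, train: pd.DataFrame, test: pd.DataFrame,
                features: list[str], target: str = "LWC", seed: int = 0,
                hyperparameters: dict | None = None) -> BenchmarkResult:
    """Fit one algorithm on ``train`` and score both partitions."""
    hp = dict(DEFAULT_HYPERPARAMETERS.get(algorithm, {}))
    if hyperparameters:
        hp.update(hyperparameters)
    y_train = train[target].to_numpy(float)
    if np.ptp(y_train) == 0:
        raise ValidationError("constant target; benchmark degenerate")
    model = _build(algorithm, hp, seed)
    model.fit(train[features].to_numpy(float), y_train)
    sim = metrics(y_train, model.predict(train[features].to_numpy(float)))
    val = metrics(test[target].to_numpy(float),
                  model.predict(test[features].to_numpy(float)))
    n = len(train) + len(test)
    return BenchmarkResult(algorithm=algorithm,
                           r2_sim=sim["r2"], rmse_sim=sim["rmse"],
                           r2_val=val["r2"], rmse_val=val["rmse"], seed=seed,
                           train_fraction=len(train) / n, hyperparameters=hp)


def run_benchmark(obs: pd.DataFrame, features: list[str], target: str = "LWC",
                  fraction: float = 0.7, seed: int = 0,
                  algorithms: tuple[str, ...] = ALGORITHMS
                  ) -> list[BenchmarkResult]:
    """Split once and fit every requested algorithm on the same partition."""
    train, test = split_data(obs, fraction, seed)
    return [fit_predict(a, train, test, features, target, seed) for a in algorithms]


def compare_to_mlr(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Per-algorithm ratios of R^2 and RMSE relative to the MLR run.

    Ratios are NaN (masked) when the MLR reference value is zero.
    """
    by_name = {r.algorithm: r for r in results}
    if "MLR" not in by_name:
        raise ValidationError("benchmark results must include an MLR run")
    mlr = by_name["MLR"]
    rows = []
    for r in results:
        if r.algorithm == "MLR":
            continue
        rows.append({
            "algorithm": r.algorithm,
            "r2_sim_ratio": r.r2_sim / mlr.r2_sim if mlr.r2_sim else np.nan,
            "r2_val_ratio": r.r2_val / mlr.r2_val if mlr.r2_val else np.nan,
            "rmse_sim_ratio": r.rmse_sim / mlr.rmse_sim if mlr.rmse_sim else np.nan,
            "rmse_val_ratio": r.rmse_val / mlr.rmse_val if mlr.rmse_val else np.nan,
        })
    return pd.DataFrame(rows)


def results_table(results: list[BenchmarkResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "algorithm": r.algorithm, "R2_S": r.r2_sim, "RMSE_S": r.rmse_sim,
        "R2_V": r.r2_val, "RMSE_V": r.rmse_val} for r in results])
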