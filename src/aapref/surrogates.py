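"""Per-target growth surrogates: featurization, hyperparameter tuning,
bootstrap-LOOCV evaluation and per-target algorithm selection.

Features are natural-log-transformed amino-acid concentrations,
ln(c + 1e-9), over the 19 variable amino acids (cysteine is fixed and
excluded); models for the two carbon sources are trained separately.

Eight regression families are compared; hyperparameters are tuned by
sequential GP-based optimization (Expected Improvement) with an
iteration budget scaled by model complexity and data size. Evaluation is
leave-one-out cross-validation with tuned hyperparameters held fixed,
followed by bootstrap resampling (200 resamples) of the paired
(observed, predicted) values to attach uncertainty to R^2, RMSE and MAE.
For each target, the algorithm with the lowest mean bootstrap RMSE is
selected (ties: higher mean R^2, then alphabetical).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .amino_acids import VARIABLE_AMINO_ACIDS
from .bayesopt import Categorical, Integer, Real, gp_minimize
from .oracle import MediumComposition

FEATURE_EPS = 1e-9
TARGETS = ("K", "r", "tau")


def featurize(comps: Sequence[MediumComposition]) -> pd.DataFrame:
    """ln(concentration + 1e-9) features over the 19 variable amino acids.

    All compositions must share one carbon source; column order is fixed
    (alphabetical three-letter codes).
    """
    comps = list(comps)
    if not comps:
        raise ValueError("no compositions")
    carbons = {c.carbon_source for c in comps}
    if len(carbons) > 1:
        raise ValueError(f"mixed carbon sources: {sorted(carbons)}")
    rows = []
    for c in comps:
        rows.append([math.log(c[aa] + FEATURE_EPS) for aa in VARIABLE_AMINO_ACIDS])
    return pd.DataFrame(rows, columns=list(VARIABLE_AMINO_ACIDS),
                        index=[c.condition_id for c in comps])


def featurize_levels(levels: np.ndarray) -> np.ndarray:
    """Same transform for a raw (n, 19) concentration matrix."""
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0):
        raise ValueError("negative concentration")
    return np.log(levels + FEATURE_EPS)


# ---------------------------------------------------------------------------
# Algorithm registry
# ---------------------------------------------------------------------------

def _make_xgboost(params: dict, seed: int):
    from xgboost import XGBRegressor
    return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0,
                        tree_method="hist", **params)


def _make_lightgbm(params: dict, seed: int):
    from lightgbm import LGBMRegressor
    return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1,
                         min_child_samples=params.pop("min_child_samples", 3),
                         **params)


def _make_hist_gb(params: dict, seed: int):
    return HistGradientBoostingRegressor(random_state=seed, **params)


def _make_rf(params: dict, seed: int):
    return RandomForestRegressor(random_state=seed, n_jobs=1, **params)


def _make_svr(params: dict, seed: int):
    return SVR(kernel="rbf", **params)


def _make_ridge(params: dict, seed: int):
    return Ridge(**params)


def _make_mlp(params: dict, seed: int):
    hidden = params.pop("hidden_units")
    return MLPRegressor(hidden_layer_sizes=(hidden,), solver="lbfgs",
                        max_iter=2000, random_state=seed, **params)


def _make_knn(params: dict, seed: int):
    return KNeighborsRegressor(**params)


@dataclass(frozen=True)
class _Algorithm:
    factory: object
    space: tuple
    complexity_mult: float


ALGORITHMS: dict[str, _Algorithm] = {
    "xgboost": _Algorithm(_make_xgboost, (
        Integer("n_estimators", 50, 400), Real("learning_rate", 0.01, 0.5, log=True),
        Integer("max_depth", 2, 8), Real("subsample", 0.5, 1.0),
        Real("colsample_bytree", 0.5, 1.0), Real("reg_lambda", 1e-3, 10.0, log=True),
    ), 2.0),
    "lightgbm": _Algorithm(_make_lightgbm, (
        Integer("n_estimators", 50, 400), Real("learning_rate", 0.01, 0.5, log=True),
        Integer("num_leaves", 4, 64), Integer("min_child_samples", 1, 20),
        Real("reg_lambda", 1e-3, 10.0, log=True),
    ), 2.0),
    "hist_gb": _Algorithm(_make_hist_gb, (
        Integer("max_iter", 50, 400), Real("learning_rate", 0.01, 0.5, log=True),
        Integer("max_depth", 2, 8), Real("l2_regularization", 1e-3, 10.0, log=True),
        Integer("min_samples_leaf", 1, 20),
    ), 2.0),
    "random_forest": _Algorithm(_make_rf, (
        Integer("n_estimators", 50, 300), Integer("max_depth", 2, 16),
        Integer("min_samples_leaf", 1, 8), Real("max_features", 0.2, 1.0),
    ), 1.0),
    "svr_rbf": _Algorithm(_make_svr, (
        Real("C", 1e-2, 1e3, log=True), Real("gamma", 1e-4, 10.0, log=True),
        Real("epsilon", 1e-4, 1.0, log=True),
    ), 1.0),
    "ridge": _Algorithm(_make_ridge, (
        Real("alpha", 1e-3, 1e3, log=True),
    ), 0.5),
    "mlp": _Algorithm(_make_mlp, (
        Integer("hidden_units", 8, 128), Real("alpha", 1e-6, 1e-1, log=True),
    ), 2.0),
    "knn": _Algorithm(_make_knn, (
        Integer("n_neighbors", 1, 15),
        Categorical("weights", ("uniform", "distance")),
    ), 0.5),
}

DEFAULT_ROSTER = tuple(sorted(ALGORITHMS))

BUDGET_MIN, BUDGET_MAX = 10, 300
BUDGET_BASE = 30
BUDGET_REF_N = 58


def iteration_budget(algorithm: str, n: int) -> int:
    """Tuning budget: base 30 x complexity multiplier x (n / 58), clamped
    to [10, 300]."""
    mult = ALGORITHMS[algorithm].complexity_mult
    return int(min(max(round(BUDGET_BASE * mult * n / BUDGET_REF_N),
                       BUDGET_MIN), BUDGET_MAX))


@dataclass
class ModelSpec:
    algorithm: str
    budget: int | None = None        # None -> complexity/data-size rule
    seed: int = 0
    tuned_params: dict | None = None
    space: tuple | None = None       # None -> registry default
    fixed_params: dict | None = None  # merged into every build (e.g. monotone constraints)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm: {self.algorithm!r}")
        if self.budget is not None and not BUDGET_MIN <= self.budget <= BUDGET_MAX:
            warnings.warn(
                f"iteration budget {self.budget} outside "
                f"[{BUDGET_MIN}, {BUDGET_MAX}]; clamped")
            self.budget = int(min(max(self.budget, BUDGET_MIN), BUDGET_MAX))


@dataclass
class FittedSurrogate:
    """A tuned model refit on all training data, with its provenance."""

    spec: ModelSpec
    model: object
    columns: tuple[str, ...]
    target: str = ""
    n_train: int = 0

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.columns)].to_numpy()
        return np.asarray(self.model.predict(np.asarray(X, dtype=float)),
                          dtype=float)


def _build(algorithm: str, params: dict, seed: int):
    return ALGORITHMS[algorithm].factory(dict(params), seed)


def tune_and_fit(spec: ModelSpec, X: pd.DataFrame, y: Sequence[float],
                 seed: int | None = None, cv: int = 3,
                 target: str = "") -> FittedSurrogate:
    """Tune hyperparameters by GP/EI over the algorithm's space, then refit
    on all data. The tuning objective is mean RMSE over a seeded K-fold
    split. Deterministic for a fixed seed."""
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 training points")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    seed = spec.seed if seed is None else seed
    budget = spec.budget or iteration_budget(spec.algorithm, y.size)
    Xa = X.to_numpy(dtype=float)
    n_splits = min(cv, y.size)
    folds = list(KFold(n_splits=n_splits, shuffle=True,
                       random_state=seed).split(Xa))

    fixed = spec.fixed_params or {}

    def objective(params: dict) -> float:
        errs = []
        for tr, te in folds:
            model = _build(spec.algorithm, {**fixed, **params}, seed)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(Xa[tr], y[tr])
                pred = model.predict(Xa[te])
            except ValueError:
                return float("inf")  # infeasible configuration (e.g. k > n)
            errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
        return float(np.mean(errs))

    space = spec.space or ALGORITHMS[spec.algorithm].space
    result = gp_minimize(objective, space, n_calls=budget, seed=seed)
    tuned = {**fixed, **result.best_params}
    spec.tuned_params = tuned
    model = _build(spec.algorithm, tuned, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xa, y)
    return FittedSurrogate(spec=spec, model=model,
                           columns=tuple(X.columns), target=target,
                           n_train=int(y.size))


def loocv_predictions(algorithm: str, params: dict, X: np.ndarray,
                      y: np.ndarray, seed: int) -> np.ndarray:
    """Leave-one-out predictions with hyperparameters held fixed."""
    n = y.size
    yhat = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = _build(algorithm, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[mask], y[mask])
        yhat[i] = model.predict(X[i:i + 1])[0]
        mask[i] = True
    return yhat


def _metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    mae = float(np.mean(np.abs(y - yhat)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst if sst > 0 else float("nan")
    return r2, rmse, mae


@dataclass
class CVEntry:
    algorithm: str
    target: str
    n: int
    rmse_mean: float
    rmse_ci: tuple[float, float]
    mae_mean: float
    mae_ci: tuple[float, float]
    r2_mean: float
    r2_ci: tuple[float, float]
    loocv_rmse: float
    yhat: np.ndarray = field(repr=False, default=None)


def bootstrap_metrics(y: Sequence[float], yhat: Sequence[float],
                      n_boot: int = 200, seed: int = 0
                      ) -> dict[str, tuple[float, float, float]]:
    """Bootstrap the paired (y, yhat) rows; return metric -> (mean, lo, hi)
    with 2.5/97.5 percentile intervals. R^2 is NaN for resamples with
    constant y."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    rng = np.random.default_rng(seed)
    n = y.size
    samples = {"r2": [], "rmse": [], "mae": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        r2, rmse, mae = _metrics(y[idx], yhat[idx])
        samples["r2"].append(r2)
        samples["rmse"].append(rmse)
        samples["mae"].append(mae)
    out = {}
    for k, v in samples.items():
        arr = np.asarray(v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[k] = (float(np.nanmean(arr)),
                      float(np.nanpercentile(arr, 2.5)),
                      float(np.nanpercentile(arr, 97.5)))
    return out


def bootstrap_loocv(spec: ModelSpec, X: pd.DataFrame, y: Sequence[float],
                    n_boot: int = 200, seed: int | None = None,
                    target: str = "", cv: int = 3) -> CVEntry:
    """Tune, run LOOCV with tuned hyperparameters fixed, and bootstrap the
    paired residuals."""
    y = np.asarray(y, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 points for LOOCV")
    seed = spec.seed if seed is None else seed
    if spec.tuned_params is None:
        tune_and_fit(spec, X, y, seed=seed, cv=cv, target=target)
    yhat = loocv_predictions(spec.algorithm, spec.tuned_params,
                             X.to_numpy(dtype=float), y, seed)
    boot = bootstrap_metrics(y, yhat, n_boot=n_boot, seed=seed)
    _, loocv_rmse, _ = _metrics(y, yhat)
    return CVEntry(
        algorithm=spec.algorithm, target=target, n=int(y.size),
        rmse_mean=boot["rmse"][0], rmse_ci=boot["rmse"][1:],
        mae_mean=boot["mae"][0], mae_ci=boot["mae"][1:],
        r2_mean=boot["r2"][0], r2_ci=boot["r2"][1:],
        loocv_rmse=loocv_rmse, yhat=yhat)


def select_best(entries: Iterable[CVEntry]) -> CVEntry:
    """Lowest mean bootstrap RMSE; ties broken by higher mean R^2, then
    alphabetical algorithm name."""
    entries = list(entries)
    if not entries:
        raise ValueError("no CV entries")
    def key(e: CVEntry):
        r2 = e.r2_mean if math.isfinite(e.r2_mean) else -math.inf
        return (e.rmse_mean, -r2, e.algorithm)
    return min(entries, key=key)


@dataclass
class CVReport:
    target: str
    entries: list[CVEntry]
    selected: str


def train_target_surrogate(
    X: pd.DataFrame, y: Sequence[float], target: str,
    roster: Sequence[str] = DEFAULT_ROSTER, seed: int = 0,
    n_boot: int = 200, budget: int | None = None, cv: int = 3,
    space_overrides: dict[str, tuple] | None = None,
    fixed_params: dict[str, dict] | None = None,
) -> tuple[FittedSurrogate, CVReport]:
    """Evaluate every algorithm in the roster for one target, select the
    best by bootstrap-LOOCV RMSE and refit it on all data."""
    y = np.asarray(y, dtype=float)
    entries = []
    specs = {}
    overrides = space_overrides or {}
    fixed = fixed_params or {}
    for i, alg in enumerate(sorted(roster)):
        spec = ModelSpec(algorithm=alg, budget=budget, seed=seed + i,
                         space=overrides.get(alg),
                         fixed_params=fixed.get(alg))
        entries.append(bootstrap_loocv(spec, X, y, n_boot=n_boot,
                                       target=target, cv=cv))
        specs[alg] = spec
    best = select_best(entries)
    spec = specs[best.algorithm]
    fitted = FittedSurrogate(
        spec=spec,
        model=None, columns=tuple(X.columns), target=target, n_train=y.size)
    model = _build(spec.algorithm, spec.tuned_params, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X.to_numpy(dtype=float), y)
    fitted.model = model
    return fitted, CVReport(target=target, entries=entries,
                            selected=best.algorithm)


def monotone_fixed_params(n_features: int, sense: int) -> dict[str, dict]:
    """Per-algorithm fixed parameters enforcing a monotone response in
    every feature (sense +1: non-decreasing, -1: non-increasing), for the
    learners that support shape constraints."""
    cst = [int(sense)] * n_features
    return {
        "xgboost": {"monotone_constraints": "(" + ",".join(str(c) for c in cst) + ")"},
        "lightgbm": {"monotone_constraints": cst},
        "hist_gb": {"monotone_cst": cst},
    }
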