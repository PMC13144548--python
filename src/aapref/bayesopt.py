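"""Sequential model-based hyperparameter optimization.

A small gp_minimize-style loop: random initial evaluations, then a
Gaussian-process surrogate (Matern 5/2) over the unit-cube-encoded search
space, with Expected Improvement maximized over a random candidate pool.
Fully seeded and deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class Categorical:
    name: str
    categories: tuple


Dimension = Real | Integer | Categorical


def _encode(dim: Dimension, value) -> float:
    """Map a parameter value to [0, 1]."""
    if isinstance(dim, Categorical):
        return dim.categories.index(value) / max(len(dim.categories) - 1, 1)
    lo, hi = dim.low, dim.high
    if dim.log:
        return (math.log(value) - math.log(lo)) / (math.log(hi) - math.log(lo))
    return (value - lo) / (hi - lo)


def _decode(dim: Dimension, u: float):
    if isinstance(dim, Categorical):
        i = int(round(u * (len(dim.categories) - 1)))
        return dim.categories[i]
    lo, hi = dim.low, dim.high
    if dim.log:
        v = math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
    else:
        v = lo + u * (hi - lo)
    if isinstance(dim, Integer):
        return int(min(max(round(v), lo), hi))
    return float(v)


def _sample(dims: Sequence[Dimension], rng: np.random.Generator) -> dict:
    return {d.name: _decode(d, u) for d, u in zip(dims, rng.random(len(dims)))}


@dataclass
class OptimizeResult:
    best_params: dict
    best_value: float
    params_history: list[dict]
    values_history: list[float]


def gp_minimize(
    func: Callable[[dict], float],
    dimensions: Sequence[Dimension],
    n_calls: int,
    seed: int = 0,
    n_initial: int | None = None,
    n_candidates: int = 256,
) -> OptimizeResult:
    """Minimize ``func`` over the search space with GP + Expected Improvement."""
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    rng = np.random.default_rng(seed)
    n_initial = n_initial or min(max(3, len(dimensions) + 1), n_calls)

    params_hist: list[dict] = []
    values: list[float] = []
    X: list[list[float]] = []

    def _evaluate(p: dict) -> None:
        v = float(func(p))
        if not math.isfinite(v):
            v = 1e12
        params_hist.append(p)
        values.append(v)
        X.append([_encode(d, p[d.name]) for d in dimensions])

    for _ in range(min(n_initial, n_calls)):
        _evaluate(_sample(dimensions, rng))

    kernel = ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5)
    while len(values) < n_calls:
        y = np.asarray(values)
        y_std = y.std()
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-6, normalize_y=True,
            n_restarts_optimizer=1, random_state=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(X), y)
        cand_params = [_sample(dimensions, rng) for _ in range(n_candidates)]
        C = np.asarray([[_encode(d, p[d.name]) for d in dimensions]
                        for p in cand_params])
        mu, sd = gp.predict(C, return_std=True)
        best = y.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best - mu) / sd
            ei = (best - mu) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
        ei[sd < 1e-12 * max(y_std, 1e-12)] = 0.0
        _evaluate(cand_params[int(np.argmax(ei))])

    i = int(np.argmin(values))
    return OptimizeResult(best_params=params_hist[i], best_value=values[i],
                         params_history=params_hist, values_history=values)
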