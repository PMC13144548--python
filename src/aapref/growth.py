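"""Rule-based growth-curve phenotyping: K, r and lag time from OD600 reads.

The estimation pipeline for one well:

1. baseline-correct by subtracting the initial OD;
2. K = mean of the maximum point and its two temporal neighbours
   (the three nearest points at a series boundary);
3. wells with K < 0.1 are "no growth" (r = 0, lag undefined);
4. lag time tau = earliest time with corrected OD > 0.02 followed by five
   strictly increasing points;
5. exponential-phase onset = first PELT changepoint of log-OD at or after
   tau; the phase ends when OD first reaches 60% of K; r is the
   least-squares slope of log(OD) versus time on that window. The PELT
   penalty is doubled until the regression reaches R^2 >= 0.999 (at most
   10 iterations); on exhaustion the best window seen is kept and flagged.

All thresholds are exposed as :class:`FitConfig` fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .changepoint import pelt_segment

NO_GROWTH_K = 0.1


@dataclass
class GrowthCurve:
    """One well's OD600 time series (hours, OD)."""

    time_h: np.ndarray
    od: np.ndarray
    well_id: str = ""
    condition_id: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.shape != self.od.shape:
            raise ValueError("time_h and od must be 1-D and the same length")
        if self.time_h.size == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time_h must be strictly increasing")

    def __len__(self) -> int:
        return self.time_h.size


@dataclass
class GrowthFit:
    """Estimated growth parameters for one well.

    ``tau`` is NaN when undefined. ``flags`` records rule fallbacks
    ('r2_target_not_met', 'fallback_window', 'no_lag_detected').
    """

    K: float
    r: float
    tau: float
    no_growth: bool
    exp_window: tuple[float, float] | None = None
    r2_exp: float = float("nan")
    penalty_used: float = float("nan")
    iterations_used: int = 0
    flags: tuple[str, ...] = ()
    well_id: str = ""
    condition_id: str = ""


@dataclass
class ReplicateSummary:
    condition_id: str
    n_wells: int
    K_mean: float
    K_sd: float
    r_mean: float
    r_sd: float
    tau_mean: float
    tau_sd: float
    n_tau: int


@dataclass
class FitConfig:
    no_growth_k: float = NO_GROWTH_K
    lag_threshold: float = 0.02
    lag_run: int = 5               # strictly increasing points after the threshold point
    frac_k: float = 0.6            # exponential phase ends at frac_k * K
    r2_target: float = 0.999
    max_iterations: int = 10
    penalty_start: float = 1.0
    penalty_factor: float = 2.0
    log_floor: float = 1e-3        # added before log to avoid log(<=0)
    min_points: int = 10


def baseline_correct(curve: GrowthCurve) -> GrowthCurve:
    """Subtract the initial OD so the first value is exactly zero."""
    return replace(curve, od=curve.od - curve.od[0])


def estimate_K(curve: GrowthCurve) -> float:
    """Maximum cell density: mean of the argmax point and its two temporal
    neighbours; at a series boundary the three nearest points are used."""
    od = curve.od
    if od.size < 3:
        raise ValueError("need at least 3 points to estimate K")
    i = int(np.argmax(od))
    lo = min(max(i - 1, 0), od.size - 3)
    return float(od[lo:lo + 3].mean())


def detect_lag(curve: GrowthCurve, config: FitConfig | None = None) -> float:
    """Lag time: earliest time t_i with corrected OD > threshold and the
    next ``lag_run`` points strictly increasing (od_i < od_{i+1} < ...).
    NaN when no such point exists."""
    cfg = config or FitConfig()
    od, t = curve.od, curve.time_h
    run = cfg.lag_run
    for i in range(od.size - run):
        if od[i] > cfg.lag_threshold and np.all(np.diff(od[i:i + run + 1]) > 0):
            return float(t[i])
    return float("nan")


def _linreg(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_exponential(
    curve: GrowthCurve,
    tau: float,
    K: float,
    config: FitConfig | None = None,
) -> tuple[float, tuple[float, float] | None, float, float, int, tuple[str, ...]]:
    """Estimate the specific growth rate on the exponential window.

    ``curve`` must be baseline-corrected, ``tau`` defined and ``K`` at
    least the growth threshold. Returns (r, window, r2, penalty_used,
    iterations_used, flags).
    """
    cfg = config or FitConfig()
    t, od = curve.time_h, curve.od
    mask = t >= tau
    idx = np.flatnonzero(mask)
    if idx.size < 4:
        # too short even to segment: regress on whatever is there
        return _window_fit(curve, float(tau), K, cfg, ("fallback_window",))

    logsig = np.log(od[idx] + cfg.log_floor)

    end_candidates = np.flatnonzero(od >= cfg.frac_k * K)
    end_i = int(end_candidates[0]) if end_candidates.size else int(t.size - 1)

    best: tuple[float, tuple] | None = None  # (r2, payload)
    penalty = cfg.penalty_start
    for it in range(1, cfg.max_iterations + 1):
        cps = pelt_segment(logsig, penalty)
        onset_i = int(idx[cps[0]]) if cps else int(idx[0])
        flags: tuple[str, ...] = () if cps else ("fallback_window",)
        sel = np.arange(onset_i, end_i + 1)
        if sel.size < 3:
            sel = np.arange(idx[0], end_i + 1)
            flags = flags + ("fallback_window",)
        if sel.size < 2:
            penalty *= cfg.penalty_factor
            continue
        y = np.log(np.maximum(od[sel], cfg.log_floor))
        slope, _, r2 = _linreg(t[sel], y)
        window = (float(t[sel[0]]), float(t[sel[-1]]))
        if best is None or r2 > best[0]:
            best = (r2, (slope, window, r2, penalty, it, flags))
        if r2 >= cfg.r2_target:
            return best[1]
        penalty *= cfg.penalty_factor

    assert best is not None
    slope, window, r2, pen, it, flags = best[1]
    return slope, window, r2, pen, it, flags + ("r2_target_not_met",)


def _window_fit(curve, start_t, K, cfg, flags):
    """Fallback regression on the [start, 0.6K] window without segmentation."""
    t, od = curve.time_h, curve.od
    end_candidates = np.flatnonzero(od >= cfg.frac_k * K)
    end_i = int(end_candidates[0]) if end_candidates.size else int(t.size - 1)
    sel = np.flatnonzero((t >= start_t) & (np.arange(t.size) <= end_i))
    if sel.size < 2:
        return 0.0, None, float("nan"), float("nan"), 0, flags + ("fallback_window",)
    y = np.log(np.maximum(od[sel], cfg.log_floor))
    slope, _, r2 = _linreg(t[sel], y)
    return slope, (float(t[sel[0]]), float(t[sel[-1]])), r2, float("nan"), 0, flags


def fit_growth(curve: GrowthCurve, config: FitConfig | None = None) -> GrowthFit:
    """Full per-well pipeline: baseline correction, K, no-growth rule, lag
    detection and exponential-phase regression."""
    cfg = config or FitConfig()
    if len(curve) < cfg.min_points:
        raise ValueError(f"need >= {cfg.min_points} points, got {len(curve)}")
    corrected = baseline_correct(curve)
    K = estimate_K(corrected)
    if K < cfg.no_growth_k:
        return GrowthFit(K=K, r=0.0, tau=float("nan"), no_growth=True,
                         well_id=curve.well_id, condition_id=curve.condition_id)
    tau = detect_lag(corrected, cfg)
    if math.isnan(tau):
        # growth without a clean lag signature: fit from the threshold crossing
        above = np.flatnonzero(corrected.od > cfg.lag_threshold)
        start_t = float(corrected.time_h[above[0]]) if above.size else float(corrected.time_h[0])
        r, window, r2, pen, its, flags = _window_fit(
            corrected, start_t, K, cfg, ("no_lag_detected",))
        return GrowthFit(K=K, r=r, tau=float("nan"), no_growth=False,
                         exp_window=window, r2_exp=r2, penalty_used=pen,
                         iterations_used=its, flags=flags,
                         well_id=curve.well_id, condition_id=curve.condition_id)
    r, window, r2, pen, its, flags = fit_exponential(corrected, tau, K, cfg)
    return GrowthFit(K=K, r=r, tau=tau, no_growth=False, exp_window=window,
                     r2_exp=r2, penalty_used=pen, iterations_used=its,
                     flags=flags, well_id=curve.well_id,
                     condition_id=curve.condition_id)


def summarize_replicates(fits: Iterable[GrowthFit]) -> ReplicateSummary:
    """Per-condition mean and sample SD (n-1) of K, r and tau.

    Lag statistics use only wells with a defined lag. SD is NaN for fewer
    than two wells.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarize")
    conditions = {f.condition_id for f in fits}
    if len(conditions) > 1:
        raise ValueError(f"mixed condition ids: {sorted(conditions)}")

    def _stats(vals: Sequence[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
        return float(arr.mean()), sd

    K_mean, K_sd = _stats([f.K for f in fits])
    r_mean, r_sd = _stats([f.r for f in fits])
    taus = [f.tau for f in fits if not math.isnan(f.tau)]
    tau_mean, tau_sd = _stats(taus)
    return ReplicateSummary(
        condition_id=fits[0].condition_id, n_wells=len(fits),
        K_mean=K_mean, K_sd=K_sd, r_mean=r_mean, r_sd=r_sd,
        tau_mean=tau_mean, tau_sd=tau_sd, n_tau=len(taus),
    )
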