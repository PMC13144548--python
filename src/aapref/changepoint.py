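"""Exact changepoint detection by PELT with an L2 (piecewise-mean) cost.

PELT (Pruned Exact Linear Time) minimizes

    sum_k cost(segment_k) + penalty * (number of changepoints)

over all segmentations, where cost(y[i:j]) is the within-segment sum of
squared deviations from the segment mean. The pruning step discards
candidate last-changepoint positions that can never be optimal; because
the L2 cost is additive and non-negative the pruned search remains exact,
so the result equals exhaustive dynamic programming.
"""

from __future__ import annotations

import numpy as np


def _seg_cost_factory(signal: np.ndarray):
    """Return cost(i, j) = SSE of signal[i:j] around its mean, O(1) per call."""
    s1 = np.concatenate(([0.0], np.cumsum(signal)))
    s2 = np.concatenate(([0.0], np.cumsum(signal**2)))

    def cost(i: int, j: int) -> float:
        n = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / n

    return cost


def pelt_segment(signal, penalty: float, min_size: int = 1) -> list[int]:
    """Exact penalized L2 segmentation of a 1-D signal.

    Parameters
    ----------
    signal : sequence of float
        Values to segment; must be finite, length >= 4.
    penalty : float
        Cost added per changepoint; must be > 0.
    min_size : int
        Minimum points per segment.

    Returns
    -------
    list of int
        Sorted interior changepoint indices ``t`` (``0 < t < n``), each the
        first index of a new segment. Empty list means one segment. Ties
        are broken toward the segmentation found with the smallest last
        changepoint, making the result deterministic.
    """
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("signal must be 1-D with length >= 4")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    if not penalty > 0:
        raise ValueError("penalty must be > 0")

    n = y.size
    cost = _seg_cost_factory(y)

    # F[t] = optimal cost of y[0:t] including penalty per changepoint
    F = np.full(n + 1, np.inf)
    F[0] = -penalty  # so the first segment carries no penalty
    last = np.zeros(n + 1, dtype=int)
    candidates: list[int] = []

    for t in range(min_size, n + 1):
        candidates.append(t - min_size)
        best, best_s = np.inf, 0
        vals = {}
        for s in candidates:
            v = F[s] + cost(s, t) + penalty
            vals[s] = v
            if v < best:  # strict: prefers the smallest candidate s
                best, best_s = v, s
        F[t] = best
        last[t] = best_s
        # pruning: keep s only if it could still start the optimal last segment
        candidates = [s for s in candidates if vals[s] - penalty <= F[t]]

    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)
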