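"""Candidate-medium proposal: four-objective NSGA-II over discrete
amino-acid levels, then two-stage knee-point selection.

Objectives: maximize predicted yield K and rate r, minimize predicted lag
tau and total amino-acid input (the 19 variables plus fixed cysteine).

Stage 1 scores every front member by three knee metrics — distance to the
ideal point in min-max-normalized objective space, discrete bend angle on
the (total-AA vs growth-composite) trade-off curve, and the number of
evaluated dominated candidates — and keeps the top 30 by mean rank.
Stage 2 applies percentile thresholds on the predicted objectives
(relaxed in 5-point steps until enough candidates survive) and a greedy
max-min diversity filter in feature space to pick the final 15.

The knee metrics and stage-2 filters are this package's reconstruction of
a selection procedure that is usually described only by name; all
parameters are exposed in :class:`ProposalConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .amino_acids import (LEVELS_UM, REFERENCE_CONCENTRATION_UM,
                          VARIABLE_AMINO_ACIDS)
from .nsga2 import NSGAResult, dominates, nsga2  # noqa: F401  (re-export)
from .oracle import MediumComposition, composition_from_levels
from .surrogates import FittedSurrogate, featurize_levels

#: objective senses: (K max, r max, tau min, total_aa min)
SENSES = (1, 1, -1, -1)
OBJECTIVE_NAMES = ("K_hat", "r_hat", "tau_hat", "total_aa")


@dataclass
class ProposalConfig:
    levels: tuple[float, ...] = LEVELS_UM
    pop_size: int = 200
    n_gen: int = 100
    cx_prob: float = 0.9
    mut_prob: float | None = None      # default 1/19
    stage1_n: int = 30
    stage2_n: int = 15
    percentile: float = 25.0           # K,r above this; tau below (100 - this)
    percentile_step: float = 5.0
    #: trust quantile of the measured screening distribution used by
    #: quality_gate: candidates predicted below the low decile of screened
    #: growth (or above its high-decile lag) are not worth testing
    gate_percentile: float = 10.0
    cys_um: float = REFERENCE_CONCENTRATION_UM


@dataclass
class ParetoFront:
    levels: np.ndarray        # (m, 19) concentrations
    objectives: np.ndarray    # (m, 4)
    archive_levels: np.ndarray = field(repr=False, default=None)
    archive_objectives: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return self.levels.shape[0]


@dataclass
class ScoredCandidates:
    """Stage-1 output: candidates ordered by combined knee score."""

    levels: np.ndarray
    objectives: np.ndarray
    distance: np.ndarray
    curvature: np.ndarray
    dominance: np.ndarray
    score: np.ndarray         # mean of the three rank-normalized metrics

    def __len__(self) -> int:
        return self.levels.shape[0]


def predict_objectives(models: dict[str, FittedSurrogate],
                       level_matrix: np.ndarray,
                       cys_um: float = REFERENCE_CONCENTRATION_UM
                       ) -> np.ndarray:
    """Predicted (K, r, tau, total_aa) for an (n, 19) concentration matrix.
    total_aa is computed exactly from the levels plus fixed cysteine."""
    X = featurize_levels(level_matrix)
    total = level_matrix.sum(axis=1) + cys_um
    return np.column_stack([
        models["K"].predict(X), models["r"].predict(X),
        models["tau"].predict(X), total])


def nsga2_front(models: dict[str, FittedSurrogate],
                config: ProposalConfig | None = None,
                seed: int = 0) -> ParetoFront:
    """Search the discrete composition space with NSGA-II."""
    cfg = config or ProposalConfig()
    for t in ("K", "r", "tau"):
        if t not in models:
            raise ValueError(f"missing surrogate for target {t!r}")

    def evaluate(levels: np.ndarray) -> np.ndarray:
        return predict_objectives(models, levels, cfg.cys_um)

    res = nsga2(evaluate, n_genes=len(VARIABLE_AMINO_ACIDS),
                levels=cfg.levels, senses=SENSES, pop_size=cfg.pop_size,
                n_gen=cfg.n_gen, cx_prob=cfg.cx_prob, mut_prob=cfg.mut_prob,
                seed=seed)
    return ParetoFront(res.front_genomes, res.front_objectives,
                       res.archive_genomes, res.archive_objectives)


def _normalize(objectives: np.ndarray) -> np.ndarray:
    """Min-max normalize objectives over the front, oriented so 1 = best."""
    F = np.asarray(objectives, float) * np.asarray(SENSES, float)
    lo, hi = F.min(axis=0), F.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (F - lo) / span


def knee_stage1(front: ParetoFront, n: int | None = None,
                config: ProposalConfig | None = None) -> ScoredCandidates:
    """Score front members by distance / curvature / dominance and keep the
    top n by mean rank."""
    cfg = config or ProposalConfig()
    n = cfg.stage1_n if n is None else n
    if len(front) == 0:
        raise ValueError("empty front")
    N = _normalize(front.objectives)

    # distance to the ideal point (1, 1, 1, 1); lower is better
    distance = np.sqrt(((1.0 - N) ** 2).sum(axis=1))

    # curvature: bend angle on the (AA-score, growth-composite) curve
    growth = N[:, :3].mean(axis=1)
    aa_score = N[:, 3]
    order = np.argsort(aa_score, kind="stable")
    curvature = np.zeros(len(front))
    if len(front) >= 3:
        pts = np.column_stack([aa_score[order], growth[order]])
        v1 = pts[1:-1] - pts[:-2]
        v2 = pts[2:] - pts[1:-1]
        norm = (np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        cosang = np.where(norm > 0,
                          (v1 * v2).sum(axis=1) / np.where(norm > 0, norm, 1.0),
                          1.0)
        # exterior (turn) angle: straight line -> 0, sharp knee -> pi
        curvature[order[1:-1]] = np.arccos(np.clip(cosang, -1.0, 1.0))

    # dominance: evaluated non-front candidates each member dominates
    dominance = np.zeros(len(front))
    if front.archive_objectives is not None and len(front.archive_objectives):
        A = front.archive_objectives * np.asarray(SENSES, float)
        B = front.objectives * np.asarray(SENSES, float)
        ge = np.all(B[:, None, :] >= A[None, :, :], axis=2)
        gt = np.any(B[:, None, :] > A[None, :, :], axis=2)
        dominance = (ge & gt).sum(axis=1).astype(float)

    m = len(front)
    ranks = (rankdata(-distance) + rankdata(curvature)
             + rankdata(dominance)) / (3.0 * m)   # higher = better
    top = np.argsort(-ranks, kind="stable")[: min(n, m)]
    return ScoredCandidates(
        levels=front.levels[top], objectives=front.objectives[top],
        distance=distance[top], curvature=curvature[top],
        dominance=dominance[top], score=ranks[top])


def knee_stage2(scored: ScoredCandidates, n: int | None = None,
                config: ProposalConfig | None = None,
                reference: dict[str, np.ndarray] | None = None
                ) -> ScoredCandidates:
    """Percentile thresholding plus greedy max-min diversity selection.

    ``reference`` optionally supplies measured K/r/tau values (e.g. the
    campaign's cumulative fitted parameters); the thresholds are then
    quantiles of the measured distributions, acting as an absolute
    quality gate on predicted performance. Without it the thresholds are
    relative to the stage-1 candidates themselves. In both cases the
    thresholds relax in ``percentile_step`` steps until enough
    candidates survive (ending with no filtering at all).
    """
    cfg = config or ProposalConfig()
    n = cfg.stage2_n if n is None else n
    m = len(scored)
    if m == 0:
        raise ValueError("no scored candidates")
    K, r, tau = (scored.objectives[:, 0], scored.objectives[:, 1],
                 scored.objectives[:, 2])
    if reference is not None:
        refK = np.asarray(reference["K"], float)
        refr = np.asarray(reference["r"], float)
        reftau = np.asarray(reference["tau"], float)
        reftau = reftau[np.isfinite(reftau)]
        if reftau.size == 0:
            reftau = tau
    else:
        refK, refr, reftau = K, r, tau

    q = cfg.percentile
    keep = np.arange(m)
    while q > 0:
        mask = ((K >= np.percentile(refK, q)) & (r >= np.percentile(refr, q))
                & (tau <= np.percentile(reftau, 100.0 - q)))
        if mask.sum() >= min(n, m):
            keep = np.flatnonzero(mask)
            break
        q -= cfg.percentile_step
    # q <= 0: no filtering

    feats = featurize_levels(scored.levels[keep])
    # greedy max-min, seeded by the best stage-1 score among survivors
    start = int(np.argmax(scored.score[keep]))
    chosen = [start]
    d = np.linalg.norm(feats - feats[start], axis=1)
    while len(chosen) < min(n, keep.size):
        i = int(np.argmax(d))
        if d[i] <= 0:
            break  # only duplicates left
        chosen.append(i)
        d = np.minimum(d, np.linalg.norm(feats - feats[i], axis=1))
    sel = keep[np.asarray(chosen)]
    return ScoredCandidates(
        levels=scored.levels[sel], objectives=scored.objectives[sel],
        distance=scored.distance[sel], curvature=scored.curvature[sel],
        dominance=scored.dominance[sel], score=scored.score[sel])


def quality_gate(front: ParetoFront, reference: dict[str, np.ndarray],
                 config: ProposalConfig | None = None,
                 min_keep: int | None = None) -> ParetoFront:
    """Restrict a front to candidates whose predicted performance clears
    quantiles of the measured K/r/tau distributions.

    Candidates must have predicted K and r at or above the ``percentile``
    quantile of the measured values and predicted tau at or below the
    complementary quantile; the quantile relaxes in steps until at least
    ``min_keep`` candidates survive (falling back to the whole front if
    none ever do). This is the absolute quality gate that keeps the
    propose-test-update loop from drifting into compositions predicted to
    grow much worse than anything already measured.
    """
    cfg = config or ProposalConfig()
    min_keep = cfg.stage2_n if min_keep is None else min_keep
    K, r, tau = (front.objectives[:, 0], front.objectives[:, 1],
                 front.objectives[:, 2])
    refK = np.asarray(reference["K"], float)
    refr = np.asarray(reference["r"], float)
    reftau = np.asarray(reference["tau"], float)
    reftau = reftau[np.isfinite(reftau)]
    if reftau.size == 0:
        reftau = tau

    q = cfg.gate_percentile
    thrK = np.percentile(refK, q)
    thrr = np.percentile(refr, q)
    thrtau = np.percentile(reftau, 100.0 - q)

    def _scale(x):
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        return iqr if iqr > 0 else max(np.std(x), 1e-9)

    # violation = scaled distance below/above the thresholds; 0 = passes
    violation = (np.clip(thrK - K, 0, None) / _scale(refK)
                 + np.clip(thrr - r, 0, None) / _scale(refr)
                 + np.clip(tau - thrtau, 0, None) / _scale(reftau))
    passing = np.flatnonzero(violation == 0)
    if passing.size >= min(min_keep, len(front)):
        keep = passing
    else:
        # nearest-feasible fallback: best-qualifying candidates only, so a
        # hard round never drags the gate toward poor growers
        keep = np.argsort(violation, kind="stable")[: min(min_keep, len(front))]
        keep = np.sort(keep)
    return ParetoFront(front.levels[keep], front.objectives[keep],
                       front.archive_levels, front.archive_objectives)


def propose(models: dict[str, FittedSurrogate],
            config: ProposalConfig | None = None, seed: int = 0,
            carbon_source: str = "glucose", id_prefix: str = "prop",
            reference: dict[str, np.ndarray] | None = None,
            ) -> tuple[list[MediumComposition], ScoredCandidates]:
    """Full proposal pipeline: NSGA-II -> stage-1 knee scoring -> stage-2
    filtering. Returns the selected compositions (cysteine fixed) with
    their predicted objectives. ``reference`` (measured K/r/tau arrays)
    anchors the stage-2 quality gate; see :func:`knee_stage2`."""
    cfg = config or ProposalConfig()
    front = nsga2_front(models, cfg, seed=seed)
    if reference is not None:
        # keep at least a full stage-1 slate so the candidate-relative
        # stage-2 percentile filter can still discard nearest-feasible fill
        front = quality_gate(front, reference, cfg, min_keep=cfg.stage1_n)
    stage1 = knee_stage1(front, config=cfg)
    stage2 = knee_stage2(stage1, config=cfg)
    comps = [
        composition_from_levels(stage2.levels[i], carbon_source,
                                condition_id=f"{id_prefix}_{i + 1:02d}",
                                cys_um=cfg.cys_um)
        for i in range(len(stage2))
    ]
    return comps, stage2
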