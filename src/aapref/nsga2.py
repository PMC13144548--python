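"""NSGA-II over discrete level vectors.

Standard elitist multi-objective GA: fast non-dominated sorting, crowding
distance, binary tournament with the crowded comparison operator, uniform
crossover and per-gene level-resample mutation. Objectives are evaluated
in batch over the whole population, and every evaluated genome is kept in
an archive (used downstream for dominance-count knee scoring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


def dominates(a: np.ndarray, b: np.ndarray, senses: Sequence[int]) -> bool:
    """True iff a dominates b: at least as good on every objective and
    strictly better on at least one. ``senses``: +1 maximize, -1 minimize."""
    a = np.asarray(a, float) * np.asarray(senses)
    b = np.asarray(b, float) * np.asarray(senses)
    return bool(np.all(a >= b) and np.any(a > b))


def non_dominated_sort(F: np.ndarray, senses: Sequence[int]) -> list[np.ndarray]:
    """Fast non-dominated sort; returns fronts as index arrays (best first)."""
    G = np.asarray(F, float) * np.asarray(senses, float)
    n = G.shape[0]
    # pairwise domination matrix
    ge = np.all(G[:, None, :] >= G[None, :, :], axis=2)
    gt = np.any(G[:, None, :] > G[None, :, :], axis=2)
    dom = ge & gt                      # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    counts = n_dominators.copy()
    while remaining.any():
        front = np.flatnonzero(remaining & (counts == 0))
        if front.size == 0:  # numerical safety; cannot happen for finite F
            front = np.flatnonzero(remaining)
        fronts.append(front)
        remaining[front] = False
        counts = counts - dom[front].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance within one front (any orientation: distances are
    orientation-invariant)."""
    F = np.asarray(F, float)
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return d


@dataclass
class NSGAResult:
    front_genomes: np.ndarray     # (m, n_genes) unique non-dominated genomes
    front_objectives: np.ndarray  # (m, n_obj)
    archive_genomes: np.ndarray   # every evaluated genome (unique)
    archive_objectives: np.ndarray


def nsga2(
    evaluate: Callable[[np.ndarray], np.ndarray],
    n_genes: int,
    levels: Sequence[float],
    senses: Sequence[int],
    pop_size: int = 200,
    n_gen: int = 100,
    cx_prob: float = 0.9,
    mut_prob: float | None = None,
    seed: int = 0,
) -> NSGAResult:
    """Run NSGA-II; ``evaluate`` maps an (n, n_genes) level matrix to an
    (n, n_obj) objective matrix. Returns the deduplicated first front and
    the archive of all evaluated points. Fully seeded."""
    rng = np.random.default_rng(seed)
    levels = np.asarray(levels, float)
    mut_prob = 1.0 / n_genes if mut_prob is None else mut_prob

    pop = rng.choice(levels, size=(pop_size, n_genes))
    fit = np.asarray(evaluate(pop), float)
    archive_g, archive_f = [pop.copy()], [fit.copy()]

    def rank_and_crowd(F):
        fronts = non_dominated_sort(F, senses)
        rank = np.empty(F.shape[0], dtype=int)
        crowd = np.empty(F.shape[0])
        for k, fr in enumerate(fronts):
            rank[fr] = k
            crowd[fr] = crowding_distance(F[fr])
        return rank, crowd, fronts

    rank, crowd, _ = rank_and_crowd(fit)

    for _ in range(n_gen):
        # binary tournaments (crowded comparison)
        i = rng.integers(0, pop_size, size=(pop_size, 2))
        better = np.where(
            (rank[i[:, 0]] < rank[i[:, 1]])
            | ((rank[i[:, 0]] == rank[i[:, 1]])
               & (crowd[i[:, 0]] >= crowd[i[:, 1]])),
            i[:, 0], i[:, 1])
        parents = pop[better]
        # uniform crossover on consecutive pairs
        children = parents.copy()
        for p in range(0, pop_size - 1, 2):
            if rng.random() < cx_prob:
                swap = rng.random(n_genes) < 0.5
                c1, c2 = children[p].copy(), children[p + 1].copy()
                c1[swap], c2[swap] = children[p + 1][swap], children[p][swap]
                children[p], children[p + 1] = c1, c2
        # per-gene level-resample mutation
        mut = rng.random(children.shape) < mut_prob
        resample = rng.choice(levels, size=children.shape)
        children[mut] = resample[mut]

        child_fit = np.asarray(evaluate(children), float)
        archive_g.append(children.copy())
        archive_f.append(child_fit.copy())

        # environmental selection over parents + children
        allg = np.vstack([pop, children])
        allf = np.vstack([fit, child_fit])
        rank_a, crowd_a, fronts = rank_and_crowd(allf)
        chosen: list[int] = []
        for fr in fronts:
            if len(chosen) + fr.size <= pop_size:
                chosen.extend(fr.tolist())
            else:
                order = np.argsort(-crowd_a[fr], kind="stable")
                chosen.extend(fr[order][: pop_size - len(chosen)].tolist())
                break
        idx = np.asarray(chosen)
        pop, fit = allg[idx], allf[idx]
        rank, crowd, _ = rank_and_crowd(fit)

    # deduplicated first front of the final population
    fronts = non_dominated_sort(fit, senses)
    fg, ff = pop[fronts[0]], fit[fronts[0]]
    _, uniq = np.unique(fg, axis=0, return_index=True)
    fg, ff = fg[np.sort(uniq)], ff[np.sort(uniq)]

    ag = np.vstack(archive_g)
    af = np.vstack(archive_f)
    _, uniq = np.unique(ag, axis=0, return_index=True)
    ag, af = ag[np.sort(uniq)], af[np.sort(uniq)]
    return NSGAResult(fg, ff, ag, af)
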