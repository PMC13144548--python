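"""Closed-loop medium optimization: round-0 design, propose-test-update
cycles, normalized performance metrics and optimum selection.

Round 0 titrates each of the 19 variable amino acids at {0, 4, 40} uM
against an all-400 background (the 400 level coincides with the ALL
reference), plus the ALL reference itself: 58 unique conditions. Each
subsequent round tests 15 NSGA-II/knee-selected proposals, appends the
fits to the cumulative dataset and retrains the surrogates, so a 6-round
campaign accumulates 58 + 6 x 15 = 148 conditions per carbon source.

Per-condition performance is normalized against the ALL reference:
K/K_ALL, r/r_ALL, 1/(tau/tau_ALL) and 1/(AA_total/AA_ALL) with
AA_ALL = 8000 uM. The composite performance score is the sum of the four
normalized metrics; the optimized composition is the highest-composite
condition within the round with the highest mean inverse-normalized
total amino-acid input (the "lowest-AA" round).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amino_acids import (AA_ALL_TOTAL_UM, AMINO_ACIDS,
                          REFERENCE_CONCENTRATION_UM, VARIABLE_AMINO_ACIDS)
from .growth import FitConfig, ReplicateSummary, fit_growth, summarize_replicates
from .oracle import (MediumComposition, OracleParams, all_medium,
                     composition_from_levels, default_params, simulate_curve,
                     true_params)
from .pareto import ProposalConfig, propose
from .surrogates import CVReport, FittedSurrogate, train_target_surrogate

R0_TITRATION_LEVELS = (0.0, 4.0, 40.0)


def design_round0(carbon_source: str = "glucose") -> list[MediumComposition]:
    """The 58-condition initial design (ALL reference + 19 x 3 titrations)."""
    comps = [all_medium(carbon_source, condition_id="R0_ALL")]
    for aa in VARIABLE_AMINO_ACIDS:
        for level in R0_TITRATION_LEVELS:
            levels = {x: REFERENCE_CONCENTRATION_UM for x in VARIABLE_AMINO_ACIDS}
            levels[aa] = level
            comps.append(composition_from_levels(
                levels, carbon_source,
                condition_id=f"R0_{aa}_{level:g}"))
    return comps


def reduction_percent(total_aa: float,
                      reference_total: float = AA_ALL_TOTAL_UM) -> float:
    """Total amino-acid reduction relative to the ALL medium, in percent."""
    if reference_total <= 0:
        raise ValueError("reference total must be positive")
    return 100.0 * (1.0 - total_aa / reference_total)


@dataclass
class NormalizedMetrics:
    k_norm: float
    r_norm: float
    tau_inv_norm: float
    aa_inv_norm: float


def normalized_metrics(summary: ReplicateSummary, all_ref: ReplicateSummary,
                       comp: MediumComposition,
                       aa_all_total: float = AA_ALL_TOTAL_UM
                       ) -> NormalizedMetrics:
    """Normalize one condition's fitted parameters against the ALL
    reference. The lag metric is NaN when the condition (or reference) has
    no defined lag."""
    for name, v in (("K", all_ref.K_mean), ("r", all_ref.r_mean)):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"ALL reference {name} must be positive")
    tau_inv = float("nan")
    if (math.isfinite(summary.tau_mean) and math.isfinite(all_ref.tau_mean)
            and summary.tau_mean > 0 and all_ref.tau_mean > 0):
        tau_inv = 1.0 / (summary.tau_mean / all_ref.tau_mean)
    return NormalizedMetrics(
        k_norm=summary.K_mean / all_ref.K_mean,
        r_norm=summary.r_mean / all_ref.r_mean,
        tau_inv_norm=tau_inv,
        aa_inv_norm=1.0 / (comp.total_aa / aa_all_total),
    )


def composite_score(m: NormalizedMetrics) -> float:
    """Sum of the four normalized metrics; NaN when the lag metric is
    undefined (such conditions are excluded from selection)."""
    total = m.k_norm + m.r_norm + m.tau_inv_norm + m.aa_inv_norm
    return total


# ---------------------------------------------------------------------------
# Testers
# ---------------------------------------------------------------------------

class OracleTester:
    """The simulated "wet lab": renders noisy replicate curves for each
    proposed condition and runs the full rule-based fitting pipeline."""

    def __init__(self, params: OracleParams | None = None,
                 replicates: int = 4,
                 fit_config: FitConfig | None = None) -> None:
        self.params = params or default_params()
        self.replicates = replicates
        self.fit_config = fit_config or FitConfig()

    def test(self, comps: list[MediumComposition],
             seed: int) -> dict[str, ReplicateSummary]:
        out = {}
        for i, comp in enumerate(comps):
            truth = true_params(comp, self.params)
            fits = []
            for rep in range(self.replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), i, rep]))
                curve = simulate_curve(truth, self.params, rng,
                                       well_id=f"{comp.condition_id}_w{rep+1}")
                fits.append(fit_growth(curve, self.fit_config))
            out[comp.condition_id] = summarize_replicates(fits)
        return out


class PlateFileTester:
    """Tester backed by measured plate files (long/wide OD tables)."""

    def __init__(self, summaries: dict[str, ReplicateSummary]) -> None:
        self.summaries = summaries

    @classmethod
    def from_plate(cls, curves, fit_config: FitConfig | None = None):
        by_cond: dict[str, list] = {}
        for c in curves:
            by_cond.setdefault(c.condition_id, []).append(
                fit_growth(c, fit_config))
        return cls({k: summarize_replicates(v) for k, v in by_cond.items()})

    def test(self, comps, seed=0):
        missing = [c.condition_id for c in comps
                   if c.condition_id not in self.summaries]
        if missing:
            raise ValueError(f"no measurements for conditions: {missing}")
        return {c.condition_id: self.summaries[c.condition_id] for c in comps}


# ---------------------------------------------------------------------------
# Campaign state
# ---------------------------------------------------------------------------

@dataclass
class CampaignConfig:
    roster: tuple[str, ...] = ("hist_gb", "knn", "lightgbm", "mlp",
                               "random_forest", "ridge", "svr_rbf", "xgboost")
    budget: int | None = None          # None -> complexity/data-size rule
    cv_folds: int = 3
    n_boot: int = 200
    replicates: int = 4
    rounds: int = 6
    proposal: ProposalConfig = field(default_factory=ProposalConfig)
    space_overrides: dict[str, tuple] | None = None
    #: shape prior: growth responses are monotone in every amino acid
    #: (K, r non-decreasing; tau non-increasing), applied to tree learners
    monotone: bool = True


def fast_config(rounds: int = 6) -> CampaignConfig:
    """Reduced-budget preset for simulation studies: a light roster, a
    small tuning budget and a compact NSGA-II population."""
    from .bayesopt import Categorical, Integer, Real
    return CampaignConfig(
        roster=("ridge", "xgboost"), budget=10, n_boot=50, replicates=4,
        rounds=rounds,
        proposal=ProposalConfig(pop_size=128, n_gen=35),
        # boosted stumps: additive in the features, so per-amino-acid
        # titration effects compose correctly at jointly-reduced media
        space_overrides={"xgboost": (
            Integer("n_estimators", 120, 250),
            Real("learning_rate", 0.25, 0.8, log=True),
            Categorical("max_depth", (1,)),
            Real("reg_lambda", 1e-3, 0.1, log=True))})


@dataclass
class RoundRecord:
    index: int
    conditions: list[MediumComposition]
    summaries: dict[str, ReplicateSummary]
    cv_reports: dict[str, CVReport] = field(default_factory=dict)
    proposals: list[MediumComposition] = field(default_factory=list)


@dataclass
class CampaignState:
    carbon_source: str
    config: CampaignConfig
    seed: int
    rounds: list[RoundRecord] = field(default_factory=list)
    models: dict[str, FittedSurrogate] = field(default_factory=dict)
    all_ref: ReplicateSummary | None = None

    @property
    def conditions(self) -> list[MediumComposition]:
        return [c for rec in self.rounds for c in rec.conditions]

    @property
    def summaries(self) -> dict[str, ReplicateSummary]:
        out = {}
        for rec in self.rounds:
            out.update(rec.summaries)
        return out

    def conditions_table(self) -> pd.DataFrame:
        """Cumulative per-condition table: composition, fits, normalized
        metrics and composite score."""
        rows = []
        for rec in self.rounds:
            for comp in rec.conditions:
                s = rec.summaries[comp.condition_id]
                row = {"condition_id": comp.condition_id, "round": rec.index,
                       "carbon_source": self.carbon_source}
                for aa in AMINO_ACIDS:
                    row[aa] = comp[aa]
                row.update(total_aa=comp.total_aa, n_wells=s.n_wells,
                           K=s.K_mean, K_sd=s.K_sd, r=s.r_mean, r_sd=s.r_sd,
                           tau=s.tau_mean, tau_sd=s.tau_sd)
                if self.all_ref is not None:
                    m = normalized_metrics(s, self.all_ref, comp)
                    row.update(k_norm=m.k_norm, r_norm=m.r_norm,
                               tau_inv_norm=m.tau_inv_norm,
                               aa_inv_norm=m.aa_inv_norm,
                               composite=composite_score(m))
                rows.append(row)
        return pd.DataFrame(rows)


def _stage_seed(seed: int, round_index: int, stage: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(round_index), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _train_models(state: CampaignState, seed: int
                  ) -> tuple[dict[str, FittedSurrogate], dict[str, CVReport]]:
    from .surrogates import featurize, monotone_fixed_params
    comps = state.conditions
    summaries = state.summaries
    X = featurize(comps)
    cfg = state.config
    models, reports = {}, {}
    for t_i, target in enumerate(("K", "r", "tau")):
        y, keep = [], []
        for i, comp in enumerate(comps):
            s = summaries[comp.condition_id]
            v = {"K": s.K_mean, "r": s.r_mean, "tau": s.tau_mean}[target]
            if math.isfinite(v):
                y.append(v)
                keep.append(i)
        fixed = None
        if cfg.monotone:
            sense = -1 if target == "tau" else 1
            fixed = monotone_fixed_params(X.shape[1], sense)
        fitted, report = train_target_surrogate(
            X.iloc[keep], np.asarray(y), target=target, roster=cfg.roster,
            seed=seed + 101 * t_i, n_boot=cfg.n_boot, budget=cfg.budget,
            cv=cfg.cv_folds, space_overrides=cfg.space_overrides,
            fixed_params=fixed)
        models[target], reports[target] = fitted, report
    return models, reports


def run_round(state: CampaignState, proposals: list[MediumComposition],
              tester, seed: int | None = None) -> CampaignState:
    """One propose-test-update cycle: measure the proposals, append them,
    retrain the surrogates and stage the next round's proposals."""
    k = len(state.rounds)
    seed = state.seed if seed is None else seed
    summaries = tester.test(proposals, _stage_seed(seed, k, 1))
    missing = [c.condition_id for c in proposals if c.condition_id not in summaries]
    if missing:
        raise ValueError(f"tester returned no summary for: {missing}")
    rec = RoundRecord(index=k, conditions=list(proposals), summaries=summaries)
    state.rounds.append(rec)
    if state.all_ref is None and "R0_ALL" in summaries:
        state.all_ref = summaries["R0_ALL"]
    state.models, rec.cv_reports = _train_models(state, _stage_seed(seed, k, 2))
    # quality-gate reference: the round-0 screening measurements (fixed for
    # the whole campaign, so later exploratory rounds cannot erode the gate)
    screen = state.rounds[0].summaries.values()
    reference = {
        "K": np.asarray([s.K_mean for s in screen]),
        "r": np.asarray([s.r_mean for s in screen]),
        "tau": np.asarray([s.tau_mean for s in screen]),
    }
    comps, _ = propose(state.models, state.config.proposal,
                       seed=_stage_seed(seed, k, 3),
                       carbon_source=state.carbon_source,
                       id_prefix=f"R{k + 1}", reference=reference)
    rec.proposals = comps
    return state


def run_campaign(carbon_source: str = "glucose", rounds: int | None = None,
                 tester=None, seed: int = 0,
                 config: CampaignConfig | None = None) -> CampaignState:
    """Design round 0, then run the requested number of propose-test-update
    cycles. Fully seeded and reproducible."""
    config = config or CampaignConfig()
    rounds = config.rounds if rounds is None else rounds
    if tester is None:
        tester = OracleTester(replicates=config.replicates)
    state = CampaignState(carbon_source=carbon_source, config=config, seed=seed)
    run_round(state, design_round0(carbon_source), tester, seed)
    for _ in range(rounds):
        proposals = state.rounds[-1].proposals
        run_round(state, proposals, tester, seed)
    return state


def select_optimum(state: CampaignState
                   ) -> tuple[MediumComposition, float, dict]:
    """Pick the optimized composition: within the round with the highest
    mean inverse-normalized total-AA input, the condition with the highest
    composite score. Returns (composition, reduction percent, details)."""
    if state.all_ref is None:
        raise ValueError("campaign has no ALL reference")
    round_mean_aa: list[tuple[float, int]] = []
    per_round: dict[int, list[tuple[float, MediumComposition]]] = {}
    for rec in state.rounds:
        scores, aa_invs = [], []
        for comp in rec.conditions:
            m = normalized_metrics(rec.summaries[comp.condition_id],
                                   state.all_ref, comp)
            aa_invs.append(m.aa_inv_norm)
            c = composite_score(m)
            if math.isfinite(c):
                scores.append((c, comp))
        round_mean_aa.append((float(np.mean(aa_invs)), rec.index))
        per_round[rec.index] = scores
    # highest mean aa_inv_norm first; fall back if a round has no
    # scoreable (growing) condition
    for mean_aa, idx in sorted(round_mean_aa, reverse=True):
        if per_round[idx]:
            best_score, best = max(per_round[idx], key=lambda t: t[0])
            red = reduction_percent(best.total_aa)
            return best, red, {"round": idx, "composite": best_score,
                               "round_mean_aa_inv": mean_aa}
    raise ValueError("no growing condition in any round")
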