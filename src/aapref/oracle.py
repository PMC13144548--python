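"""Synthetic growth oracle: medium composition -> true (K, r, tau) -> noisy
OD600 plate reads.

The oracle is a statistical stand-in for plate-reader experiments, built
for testability rather than mechanistic fidelity. Its structure encodes
the qualitative biology of the modelled organism:

* cysteine is essential — any medium without it yields no growth;
* every other amino acid contributes a saturating (Monod-form) benefit,
  additively: yield K rises, lag tau falls and rate r rises with
  concentration, each amino acid with its own weight;
* K-weights are concentrated (tyrosine largest), tau-weights are
  dominated by glutamate, leucine and valine, r-weights are diffuse;
* lactose multiplies r by a fixed factor < 1 and shifts a few K-weights
  (alanine/histidine up, phenylalanine down) relative to glucose.

Weight scales are calibrated so the ALL medium (20 amino acids at 400 uM)
reproduces the reference growth parameters exactly at zero noise:
K=1.304, r=0.590, tau=13.20 h (glucose); K=1.258, r=0.462, tau=14.07 h
(lactose).

The noiseless curve is a three-phase model — flat at the inoculum OD
until the lag ends, exponential from the detection threshold upward, then
a stationary plateau with a slight linear drift — so that the rule-based
estimators in :mod:`aapref.growth` are consistent estimators of the
simulated parameters. A logistic shape is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amino_acids import (AA_ALL_TOTAL_UM, AMINO_ACIDS, CARBON_SOURCES,
                          CYSTEINE, REFERENCE_CONCENTRATION_UM,
                          VARIABLE_AMINO_ACIDS)
from .growth import GrowthCurve

#: Reference ("ALL" medium) growth anchors per carbon source.
ANCHORS = {
    "glucose": {"K": 1.304, "r": 0.590, "tau": 13.20},
    "lactose": {"K": 1.258, "r": 0.462, "tau": 14.07},
}


@dataclass
class MediumComposition:
    """Amino-acid concentrations (uM) plus a carbon source."""

    concentrations: dict[str, float]
    carbon_source: str = "glucose"
    condition_id: str = ""

    def __post_init__(self) -> None:
        if self.carbon_source not in CARBON_SOURCES:
            raise ValueError(f"unknown carbon source: {self.carbon_source!r}")
        conc = {aa: 0.0 for aa in AMINO_ACIDS}
        for aa, c in self.concentrations.items():
            if aa not in conc:
                raise ValueError(f"unknown amino acid: {aa!r}")
            if c < 0:
                raise ValueError(f"negative concentration for {aa}: {c}")
            conc[aa] = float(c)
        self.concentrations = conc

    @property
    def total_aa(self) -> float:
        return float(sum(self.concentrations.values()))

    def __getitem__(self, aa: str) -> float:
        return self.concentrations[aa]


def all_medium(carbon_source: str = "glucose",
               condition_id: str = "ALL") -> MediumComposition:
    return MediumComposition(
        {aa: REFERENCE_CONCENTRATION_UM for aa in AMINO_ACIDS},
        carbon_source, condition_id)


def cys_only_medium(carbon_source: str = "glucose",
                    condition_id: str = "Cys") -> MediumComposition:
    return MediumComposition({CYSTEINE: REFERENCE_CONCENTRATION_UM},
                             carbon_source, condition_id)


def none_medium(carbon_source: str = "glucose",
                condition_id: str = "None") -> MediumComposition:
    return MediumComposition({}, carbon_source, condition_id)


def composition_from_levels(levels: Mapping[str, float] | Sequence[float],
                            carbon_source: str = "glucose",
                            condition_id: str = "",
                            cys_um: float = REFERENCE_CONCENTRATION_UM,
                            ) -> MediumComposition:
    """Build a composition from the 19 variable amino acids; cysteine fixed."""
    if not isinstance(levels, Mapping):
        if len(levels) != len(VARIABLE_AMINO_ACIDS):
            raise ValueError("expected one level per variable amino acid")
        levels = dict(zip(VARIABLE_AMINO_ACIDS, levels))
    conc = dict(levels)
    conc[CYSTEINE] = cys_um
    return MediumComposition(conc, carbon_source, condition_id)


# -- default relative preference weights (dimensionless; scaled at build) ----
#
# Concentrated on a small core set: the reference optimized media keep a
# handful of amino acids at the full 400 uM, eliminate several entirely,
# and still grow like the complete medium at roughly a third of the total
# input — so most of the yield/lag response must sit on few amino acids,
# with near-dummy weights for the rest.

_A_REL_GLUCOSE = {"Tyr": 0.32, "Glu": 0.14, "Leu": 0.14, "Val": 0.12,
                  "Phe": 0.09, "Ile": 0.07, "Trp": 0.06, "His": 0.06,
                  "Cys": 0.10}
_A_REL_LACTOSE = {"Tyr": 0.32, "Glu": 0.12, "Leu": 0.12, "Val": 0.10,
                  "Phe": 0.02, "Ile": 0.06, "Trp": 0.05, "His": 0.10,
                  "Ala": 0.08, "Cys": 0.10}
_A_REL_MINOR = 0.005
_B_REL = {"Glu": 0.32, "Leu": 0.29, "Val": 0.26, "Ile": 0.04, "His": 0.02,
          "Cys": 0.03}
_B_REL_MINOR = 0.0015
_G_REL = {"Tyr": 0.115, "Glu": 0.115, "Leu": 0.115, "Val": 0.115,
          "Phe": 0.115, "Ile": 0.115, "Trp": 0.115, "His": 0.115,
          "Gln": 0.01, "Pro": 0.01, "Cys": 0.06}
_G_REL_MINOR = 0.002


@dataclass
class OracleParams:
    """Parameters of the synthetic growth response."""

    h: dict[str, float]                      # half-saturation per AA (uM)
    a: dict[str, dict[str, float]]           # K weights, per carbon source
    b: dict[str, dict[str, float]]           # tau weights, per carbon source
    g: dict[str, float]                      # r weights (shared)
    K0: float = 0.40                         # yield with cysteine alone, base
    r0: float = 0.25                         # rate floor (per hour)
    tau_max: float = 30.0                    # lag with cysteine alone (h)
    tau_min: float = 6.0                     # shortest achievable lag (h)
    carbon_r_factor: dict[str, float] = field(
        default_factory=lambda: {"glucose": 1.0, "lactose": 1.0})
    noise_mult_sd: float = 0.02              # lognormal multiplicative SD
    noise_add_sd: float = 0.005              # additive Gaussian SD (OD units)
    od0: float = 0.01                        # inoculum OD600
    no_growth_K: float = 0.03                # residual "K" without cysteine
    stationary_drift: float = 2e-4           # relative OD drift per hour in plateau
    shape: str = "exp3"                      # "exp3" or "logistic"
    detection_od: float = 0.021              # corrected OD at the end of lag

    def __post_init__(self) -> None:
        for w in (self.a["glucose"], self.a["lactose"],
                  self.b["glucose"], self.b["lactose"], self.g, self.h):
            if any(v < 0 for v in w.values()):
                raise ValueError("oracle weights must be non-negative")


def _sat(c: float, h: float) -> float:
    return c / (c + h) if c > 0 else 0.0


def default_params(h_um: float = 40.0) -> OracleParams:
    """Build the calibrated default oracle.

    Relative weight templates are scaled so the ALL medium hits the
    per-carbon anchors exactly (K and tau per carbon source; r via a
    multiplicative lactose factor on the glucose-calibrated rate).
    """
    h = {aa: h_um for aa in AMINO_ACIDS}
    sat_ref = _sat(REFERENCE_CONCENTRATION_UM, h_um)
    K0, r0, tau_max = 0.40, 0.25, 30.0

    a: dict[str, dict[str, float]] = {}
    for carbon, rel in (("glucose", _A_REL_GLUCOSE), ("lactose", _A_REL_LACTOSE)):
        template = {aa: rel.get(aa, _A_REL_MINOR) for aa in AMINO_ACIDS}
        scale = (ANCHORS[carbon]["K"] - K0) / (sum(template.values()) * sat_ref)
        a[carbon] = {aa: v * scale for aa, v in template.items()}

    b: dict[str, dict[str, float]] = {}
    for carbon in CARBON_SOURCES:
        template = {aa: _B_REL.get(aa, _B_REL_MINOR) for aa in AMINO_ACIDS}
        scale = (tau_max - ANCHORS[carbon]["tau"]) / (sum(template.values()) * sat_ref)
        b[carbon] = {aa: v * scale for aa, v in template.items()}

    g_template = {aa: _G_REL.get(aa, _G_REL_MINOR) for aa in AMINO_ACIDS}
    g_scale = (ANCHORS["glucose"]["r"] - r0) / (sum(g_template.values()) * sat_ref)
    g = {aa: v * g_scale for aa, v in g_template.items()}
    r_factor = {"glucose": 1.0,
                "lactose": ANCHORS["lactose"]["r"] / ANCHORS["glucose"]["r"]}

    return OracleParams(h=h, a=a, b=b, g=g, K0=K0, r0=r0, tau_max=tau_max,
                        carbon_r_factor=r_factor)


@dataclass
class OracleTruth:
    condition_id: str
    K_true: float
    r_true: float
    tau_true: float
    grew: bool


def true_params(comp: MediumComposition, params: OracleParams) -> OracleTruth:
    """Map a composition to its true growth parameters."""
    carbon = comp.carbon_source
    if comp[CYSTEINE] <= 0:
        return OracleTruth(comp.condition_id, params.no_growth_K, 0.0,
                           float("nan"), grew=False)
    sats = {aa: _sat(comp[aa], params.h[aa]) for aa in AMINO_ACIDS}
    K = params.K0 + sum(params.a[carbon][aa] * sats[aa] for aa in AMINO_ACIDS)
    tau = params.tau_max - sum(params.b[carbon][aa] * sats[aa]
                               for aa in AMINO_ACIDS)
    tau = max(tau, params.tau_min)
    r = params.carbon_r_factor[carbon] * (
        params.r0 + sum(params.g[aa] * sats[aa] for aa in AMINO_ACIDS))
    return OracleTruth(comp.condition_id, K, r, tau, grew=True)


def _noiseless_od(truth: OracleTruth, params: OracleParams,
                  t: np.ndarray) -> np.ndarray:
    if not truth.grew:
        return np.full_like(t, params.od0)
    K, r, tau = truth.K_true, truth.r_true, truth.tau_true
    if params.shape == "logistic":
        c = np.where(
            t < tau, 0.0,
            K / (1.0 + ((K - params.od0) / params.od0)
                 * np.exp(-r * (t - tau))) - params.od0)
        return params.od0 + np.clip(c, 0.0, None)
    # three-phase: lag / exponential from the detection threshold / plateau
    expo = params.detection_od * np.exp(r * (t - tau))
    t_hit = tau + math.log(K / params.detection_od) / r if K > params.detection_od else tau
    plateau = K * (1.0 + params.stationary_drift * np.clip(t - t_hit, 0.0, None))
    c = np.where(t < tau, 0.0, np.minimum(expo, plateau))
    return params.od0 + c


def simulate_curve(truth: OracleTruth, params: OracleParams,
                   seed: int | np.random.Generator | None = None,
                   times: np.ndarray | None = None,
                   well_id: str = "") -> GrowthCurve:
    """Render one well: noiseless shape plus multiplicative-lognormal and
    additive-Gaussian read noise. Seeded and reproducible."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = np.arange(0.0, 73.0) if times is None else np.asarray(times, float)
    od = _noiseless_od(truth, params, t)
    if params.noise_mult_sd > 0:
        od = od * np.exp(rng.normal(0.0, params.noise_mult_sd, size=t.size))
    if params.noise_add_sd > 0:
        od = od + rng.normal(0.0, params.noise_add_sd, size=t.size)
    return GrowthCurve(time_h=t, od=np.clip(od, 0.0, None),
                       well_id=well_id, condition_id=truth.condition_id)


def simulate_plate(conditions: Iterable[MediumComposition],
                   replicates: int, params: OracleParams,
                   seed: int) -> pd.DataFrame:
    """Simulate a plate: one noisy curve per condition x replicate.

    Per-well seeds are derived deterministically from ``seed``. Returns a
    long-format table (condition_id, well_id, time_h, od) compatible with
    :func:`aapref.plateio.read_plate`.
    """
    conditions = list(conditions)
    if not 1 <= replicates <= 8:
        raise ValueError("replicates must be in [1, 8]")
    frames = []
    for i, comp in enumerate(conditions):
        truth = true_params(comp, params)
        for rep in range(replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), i, rep]))
            well = f"{comp.condition_id}_w{rep + 1}"
            curve = simulate_curve(truth, params, rng, well_id=well)
            frames.append(pd.DataFrame({
                "condition_id": comp.condition_id, "well_id": well,
                "time_h": curve.time_h, "od": curve.od}))
    return pd.concat(frames, ignore_index=True)


def sample_level_compositions(n: int, seed: int = 0,
                              carbon_source: str = "glucose",
                              levels: Sequence[float] = (0.0, 4.0, 40.0, 400.0),
                              ) -> list[MediumComposition]:
    """Seeded uniform sample of the design level grid (cysteine fixed).

    Used e.g. as the explanation set for feature importance, so every
    amino acid varies across its tested concentration levels regardless
    of which compositions the campaign happened to test.
    """
    rng = np.random.default_rng(seed)
    return [
        composition_from_levels(rng.choice(np.asarray(levels, float),
                                           size=len(VARIABLE_AMINO_ACIDS)),
                                carbon_source, condition_id=f"grid_{i}")
        for i in range(n)
    ]


def truth_table(conditions: Iterable[MediumComposition],
                params: OracleParams) -> pd.DataFrame:
    rows = []
    for comp in conditions:
        tr = true_params(comp, params)
        rows.append({"condition_id": tr.condition_id, "K_true": tr.K_true,
                     "r_true": tr.r_true, "tau_true": tr.tau_true,
                     "grew": tr.grew, "total_aa": comp.total_aa})
    return pd.DataFrame(rows)
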