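# Methods

This note documents the models, rules and design choices behind
`aapref`, in the spirit of a methods section: what each stage assumes,
which parameters matter, and what the synthetic data can and cannot
establish.

## Growth-curve parameter estimation

Each well's OD600 series (default 73 hourly reads over 72 h) is reduced
to three parameters by a fixed rule set, applied in order:

1. **Baseline correction** subtracts the initial OD, so all later rules
   operate on corrected OD. The pipeline is therefore invariant to a
   constant offset in the raw reads.
2. **Maximum cell density** K is the mean of the maximum point and its
   two temporal neighbours (the three nearest points at a series
   boundary). Averaging suppresses single-read spikes.
3. **No-growth rule**: wells with K < 0.1 are classified as no growth;
   r is set to 0 and the lag is undefined (NaN).
4. **Lag time** τ is the earliest time at which corrected OD exceeds
   0.02 and the next five points are strictly increasing. Strict
   inequality resists flat noise plateaus; the run length and threshold
   are `FitConfig` fields. With 1-h sampling the rule's resolution is
   one sampling interval, and it cannot assign a lag to a curve whose
   entire exponential phase spans fewer than ~6 reads.
5. **Specific growth rate** r is the least-squares slope of log(OD)
   versus time on the exponential window. The window starts at the first
   PELT changepoint of log(OD + 10⁻³) at or after τ and ends at the
   first read with OD ≥ 0.6 K. If the regression's R² is below 0.999 the
   PELT penalty is doubled (starting from 1.0) and the segmentation
   retried, at most 10 times; on exhaustion the best window seen is kept
   and flagged (`r2_target_not_met`). Degenerate windows (< 3 points)
   fall back to the τ-to-0.6K window, flagged.

PELT is implemented exactly (L2 / piecewise-mean cost with per-change
penalty). Because the cost is subadditive, pruning with constant 0 is
exact, so the result always equals exhaustive dynamic programming; the
test suite verifies this equality on random signals.

Replicate summaries report per-condition means and sample SDs (n−1);
lag statistics use only wells with a defined lag.

## The synthetic growth oracle

Raw plate traces for the modelled organism are not redistributable, so
the package ships a generator that plays the wet lab's role. It is a
statistical stand-in built for testability, not a mechanistic model.

**Composition → true parameters.** With sat(c; h) = c/(c+h) (default
half-saturation h = 40 µM for every amino acid, so the design levels
{0, 4, 40, 400} µM span the response):

* K = K₀ + Σⱼ aⱼ·sat(cⱼ), gated to a sub-threshold residual (0.03 OD)
  when cysteine is absent — cysteine is strictly required;
* τ = τ_max − Σⱼ bⱼ·sat(cⱼ), floored at τ_min = 6 h (τ_max = 30 h);
* r = f_carbon·(r₀ + Σⱼ gⱼ·sat(cⱼ)), with f_lactose = 0.462/0.590.

All three responses are monotone in every concentration by
construction. The relative weights encode the study system's qualitative
structure: tyrosine carries the largest yield weight; glutamate, leucine
and valine dominate the lag weights; rate weights are spread over ~10
amino acids with no single dominant one. Weights are concentrated on a
core set with near-dummy minors so that the landscape contains
compositions matching complete-medium growth at roughly one third of the
total amino-acid input — the defining property of the reference
optimized media (2684 µM under glucose, 1824 µM under lactose, growth
comparable to the 8000 µM complete medium). Scale factors are solved so
the ALL medium reproduces the reference anchors exactly at zero noise:
K = 1.304, r = 0.590 /h, τ = 13.20 h (glucose) and K = 1.258,
r = 0.462 /h, τ = 14.07 h (lactose). Cysteine-only media grow
(K ≈ 0.48) with a much longer lag (≈ 29.5 h).

**True parameters → curves.** The noiseless shape is a three-phase
model: flat at the inoculum OD (0.01) until τ, exact exponential from
the detection threshold (corrected OD 0.021 at τ) at rate r, then a
plateau at K with a slight linear drift (2×10⁻⁴·K per hour, mimicking
the small continued OD increase of stationary cultures). This shape was
chosen deliberately so that the rule-based estimators above are
*consistent* estimators of the simulated parameters: with a logistic
shape, the log-slope declines from r to 0.4r across the prescribed
regression window, biasing r̂ low by 15–20% at any noise level, and a
threshold-crossing lag systematically trails a logistic's shift
parameter — no estimator following the published rules could then
recover the generator's parameters to tight tolerances. A logistic
shape remains available (`OracleParams(shape="logistic")`) for
robustness studies. Read noise is multiplicative lognormal (SD 2%) plus
additive Gaussian (SD 0.005 OD), chosen so replicate SDs resemble the
reference ±SD magnitudes.

**What the oracle does not emulate:** plate-position effects,
condensation artefacts, interactions between amino acids (off by
default; the additive structure makes surrogate learning easier than
real data would be), death phases, and carbon-source effects beyond a
multiplicative rate factor and a few shifted yield weights. Passing
tests therefore demonstrate that the pipeline's logic is correct and
self-consistent, not that it would achieve the same quantitative
performance on real plate data.

**Recovery guarantees.** At zero noise, over all (K, r, τ) combinations
whose curves reach stationary phase within the 72-h assay
(τ + ln(K/0.021)/r + 2 ≤ 72 and an exponential phase of at least 6 h),
the estimators recover K within 2%, r within 5% (in practice exactly)
and τ within one sampling interval. Curves that cannot finish within
the assay are excluded because their plateau is unobservable — an assay
limitation, not an estimator property.

## Surrogate models

Features are ln(c + 10⁻⁹) over the 19 variable amino acids (cysteine is
fixed and excluded); carbon sources are modelled separately. Eight
regression families are compared: XGBoost, LightGBM, histogram gradient
boosting, random forest, RBF-kernel SVR, ridge, a one-hidden-layer MLP
and k-nearest neighbours. Hyperparameters are tuned by a sequential
GP-based optimizer (Matérn 5/2, Expected Improvement over a random
candidate pool) against seeded 3-fold CV RMSE, with an iteration budget
of round(30 × complexity × n/58) clamped to [10, 300] (complexity 0.5
for ridge/kNN, 1 for SVR/forest, 2 for boosted models and the MLP).

Evaluation is leave-one-out cross-validation with tuned hyperparameters
held fixed, followed by 200 bootstrap resamples of the paired
(observed, predicted) values; the mean and 2.5/97.5 percentiles of R²,
RMSE and MAE are reported. Re-tuning inside every resample would be the
stricter protocol but is computationally prohibitive; resampling the
LOOCV residual pairs measures the same selection signal. Per target the
algorithm with the lowest mean bootstrap RMSE is selected (ties: higher
mean R², then alphabetical). Lag models are fit only on conditions with
a defined lag; no-growth conditions contribute their estimated K and
r = 0 to the yield and rate targets.

**Monotone shape prior.** Campaign-trained tree surrogates apply
monotone constraints (K and r non-decreasing, τ non-increasing in every
amino acid) by default. The constraint encodes genuine domain structure
— adding a nutrient does not hurt growth in this system — and markedly
improves out-of-distribution prediction at jointly-reduced compositions,
where unconstrained small-sample fits otherwise overpredict growth.

## Proposal: NSGA-II and knee-point selection

NSGA-II (in-package: fast non-dominated sorting, crowding distance,
binary tournaments, uniform crossover p = 0.9, per-gene level-resample
mutation p = 1/19) searches the discrete space {0, 4, 40, 400}¹⁹ with
four objectives: maximize predicted K and r, minimize predicted τ and
the exactly-computed total amino-acid input (including fixed cysteine,
so the complete medium totals 8000 µM). Defaults are population 200 for
100 generations; every evaluated genome is archived.

Selection from the front proceeds in stages, all reconstructions of
procedures that are usually described only by name, and all
config-exposed (`ProposalConfig`):

* **Quality gate** (campaign mode): candidates must have predicted K and
  r at or above the low decile of the round-0 screening measurements and
  predicted τ at or below the screening high decile. The gate quantile
  is a trust parameter: it excludes candidates predicted to grow worse
  than essentially anything already measured, which is what keeps the
  propose–test–update loop from drifting into compositions that trade
  all growth for amino-acid savings. The reference is the fixed round-0
  screen (not cumulative data) so exploratory rounds cannot erode the
  gate, and shortfalls are ranked by scaled violation distance rather
  than relaxing the thresholds jointly — relaxing all three until enough
  candidates pass lets one unreachable threshold collapse the others.
* **Stage 1** scores front members by (i) Euclidean distance to the
  ideal point in min-max-normalized objective space, (ii) the discrete
  bend angle on the (total-AA score vs growth-composite) trade-off curve
  and (iii) the number of archived evaluated candidates each member
  dominates, ranks by the mean of the three rank-normalized scores, and
  keeps the top 30.
* **Stage 2** applies candidate-relative percentile thresholds (K̂ and
  r̂ above the 25th percentile, τ̂ below the 75th, relaxed in 5-point
  steps until enough survive) and then greedy max–min diversity
  selection in feature space, seeded at the best stage-1 score, down to
  15 proposals. Duplicate compositions collapse (max–min distance 0).

## The campaign

Round 0 titrates each variable amino acid at {0, 4, 40} µM against an
all-400 background plus the ALL reference — 58 unique conditions (the
400 µM titration level coincides with ALL). Each subsequent round tests
15 proposals (4 replicate wells each by default), appends the fits,
retrains the surrogates on all accumulated data and proposes the next
batch; six rounds accumulate 148 conditions per carbon source. All
randomness is derived from a single campaign seed.

Per-condition metrics are normalized against the campaign's ALL
reference: K/K_ALL, r/r_ALL, 1/(τ/τ_ALL) and 1/(AA/8000). The composite
performance score is their sum; conditions without a defined lag are
excluded from composite ranking. The optimized composition is the
highest-composite condition within the round with the highest mean
inverse-normalized total amino acid (the "lowest-AA" round), falling
back to the next-best round if no condition there grew. The reported
reduction is 100·(1 − total/8000).

**Problem sizes.** The packaged simulation studies (tests and the
reproduction script) use a reduced preset (`fast_config`): roster
{ridge, xgboost} with xgboost restricted to monotone boosted stumps
(depth 1, 120–250 trees — stumps are additive in the features, so
per-amino-acid titration effects compose correctly at jointly-reduced
media), tuning budget 10, bootstrap 50, NSGA-II population 128 for 35
generations. These sizes are the package's own choice for simulation
studies; the full defaults remain available via `CampaignConfig()`.
Under the preset, 20 seeded glucose campaigns reach a median total-AA
reduction of ~67% with median optimized-medium yield ~0.92 of the ALL
reference.

## Shapley attribution

Contributions are computed in feature space against a background of up
to 100 training rows with the interventional value function
v(S) = E_B[f(x_S, B_rest)]. For small feature counts (≤ 10) the package
enumerates all subsets exactly (efficiency holds to machine precision);
otherwise it uses antithetic permutation sampling, growing the
permutation count until the worst-row efficiency residual is below 1%
of the prediction range. Importance is the mean absolute contribution
per amino acid across explained rows, with percentile CIs from 200
bootstrap resamples over rows. Exports annotate each explained point
with its original concentration level.

Importance is evaluated over an explanation set that spans the tested
concentration levels: a seeded uniform sample of the {0, 4, 40, 400} µM
grid (`sample_level_compositions`), with the training features as the
background. Explaining only the campaign's tested conditions would
starve the variance of amino acids the proposals hold fixed — tyrosine,
precisely because it matters, is kept at 400 µM by almost every
proposal, and a feature that never varies gets no attribution no matter
how large its effect. On campaign-trained surrogates
the yield model's importance ranks tyrosine first and the lag model's
top three are glutamate, leucine and valine — by construction of the
oracle, which is exactly why this check validates the attribution
chain rather than the biology.

## Numerical details and edge cases

* Ties in PELT are broken toward the earliest candidate changepoint;
  the segmentation is deterministic.
* The K rule at a series boundary uses the three nearest points.
* ln(0 + 10⁻⁹) ≈ −20.7 gives the zero level high leverage in linear
  models; this is the published transform and is kept as the model
  interface. It is the main reason purely linear/neighbour surrogates
  extrapolate poorly to jointly-reduced media.
* Bootstrap R² is NaN for resamples with constant observed values and
  is aggregated with NaN-aware means.
* `select_optimum` requires at least one condition with a defined lag
  in some round; otherwise it raises.
* All stages take explicit integer seeds; identical seeds reproduce
  identical campaigns byte-for-byte.

## Known limitations

* The oracle is additive and smooth; real dose–response surfaces have
  interactions and thresholds the surrogate comparison never faces
  here. The interaction-free default therefore likely flatters simpler
  models.
* The knee metrics, gate quantile and stage-2 thresholds are
  reconstructions of components the source methodology names but does
  not define; they were chosen to reproduce the published round-level
  behaviour (growth held near the reference while total amino acid
  falls) and are all configuration-exposed rather than claimed as the
  original implementation.
* The packaged pathway definitions are a curation constrained to the
  published entry/step counts (21 entries, 72 unique steps, cysteine as
  two alternative routes sharing the serine O-acetyltransferase step);
  the exact step granularity of the original curation is not public.
  The shipped KO table is synthetic: it reproduces the published
  summary pattern, not the genome's actual gene-to-KO map.
* Lag estimation at 1-h sampling has a hard resolution floor of one
  sampling interval, and very fast, low-yield curves (exponential phase
  shorter than the monotone-run rule) receive no lag by design.
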