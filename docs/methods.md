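# Methods

This note documents the models implemented in `kinemark`, their
assumptions, the tunable parameters and defaults, and the design choices
made where the procedure was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and normalization

A cohort is a long table of patient × assessment-day records: 35 RMK
features (17 bilateral metrics × two sides + affected-side shoulder
strength), the four clinical scales, patient id, site, and day ∈
{3, 7, 14, 21, 30, 90}. Missing values are blank CSV cells / NaN.

Every RMK feature is min-max normalized to [0, 1], with the minimum and
maximum taken over **all patients and time points** for that feature:
x′ = (x − min)/(max − min). The per-feature (min, max) pairs are stored
(sidecar JSON next to the CSV) so the mapping is invertible and can be
applied to new data. A constant feature maps to 0 with a warning rather
than crashing: it is uninformative but should not abort a pipeline.

Training tables for a scale keep only rows with all 35 features and the
target present; the assessment day is never a predictor, so each patient
contributes at most 6 exchangeable rows. The modified Rankin scale is
administered only at days 30 and 90, so MR models train on those visits
only.

**Completers** are patients with complete day-7 and day-90 records.
Because MR structurally does not exist at day 7, a scale is required at a
visit only if it is administered on that day (MR at day 90 only);
otherwise no patient could ever qualify. Completers form the
training/cross-validation population; non-completers serve as an external
validation set of patients the models never saw.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with fully known ground truth:

- **Latent recovery.** Each patient has a severity trajectory
  b + s·log(day/7) + per-visit wobble, with a random positive-mean slope
  (default slope ~ N(0.35, 0.25) per log-day unit). Log-day drift is a
  deliberately simple monotone recovery shape, not a claim of clinical
  realism.
- **Correlated feature clusters.** Each feature loads on the shared
  severity factor (0.60 affected side, 0.30 non-affected), one cluster
  factor (0.55; clusters mirror the correlated groups seen in real
  robotic assessments: sub-movement shape, resistance/accuracy, speed,
  tempo), and unique noise; values are logistic-squashed and affinely
  mapped to divergent "raw" spans so normalization is exercised.
- **Scale links.** Each scale is a scaled logistic of the weighted mean
  of its 8-feature true support (steepness 6), producing the saturation
  and floor/ceiling behavior ordinal instruments show. NIH and MR are
  inverted (higher = more impaired) so sign conventions get exercised.
  Scores get Gaussian noise with sd = 0.5 × sd(signal) — a theoretical
  R² ceiling of 1/(1 + 0.25) = 0.8 — then are clipped to the documented
  ranges and rounded to integers. The *realized* ceiling (squared
  correlation of noiseless vs observed score) is stored per scale;
  rounding makes the 6-level MR ceiling markedly lower, mirroring that
  scale's coarseness.
- **Missingness.** Whole visits drop (30% at day 90, 5% at interior
  days) and individual cells blank at 0.6%; with 208 patients this
  yields ≈ 90–100 completers, the stratum sizes the analysis expects.
- **Historical registry.** Day-7 NIH scores drawn from the cohort's own
  day-7 histogram (configurable), day-90 improvement ~ N(2.1, 3.1)
  rounded and clipped — the printed summary of the historical comparator.

What the generator does **not** emulate: biomechanics of reaching, site
effects beyond a label, informative missingness correlated with severity,
rater drift, or any attempt to reproduce real descriptive statistics
numerically. Passing tests therefore demonstrate that the *pipeline*
recovers planted structure under realistic noise — not that the models
would achieve any particular accuracy on real patients.

## Ant-colony feature selection

Parameters: 3,000 ants, w₀ = 0.01, Δw = 0.1, 10 restarts (protocol
values); subsets of prescribed size K. The path length
L(R²) = (10⁵−1)/(10^(5R²)−1) maps training R² to the quantity ants
minimize; L(1) = 1 and L grows ≈10-fold per 0.2 drop in R² while both
arguments stay above ≈0.4 (exactly 11× at the 0.2/0.4 pair — the 10×
rule is an asymptotic property of the formula). At R² = 0 the expression
diverges; a configurable large cap (10¹²) substitutes, and degenerate
fits (R² < 0) are clamped to 0 first.

Open choices, resolved as follows (all configurable):

- **Evaporation coefficient ρ** is named but not valued in the source
  description; default 0.1, the same order as Δw, so stale trails decay
  over tens of ants.
- **Evaporation scope:** all weights evaporate each ant (matching the
  physical metaphor of pheromone evaporating everywhere), deposit only to
  selected features; a selected-only variant sits behind
  `evaporate_all=False`.
- **Subset sampling** is sequential without replacement with
  renormalization after each draw — the marginal pull is p_k = w_k/Σw_k,
  and the without-replacement mechanics are otherwise unspecified.
- **Ant-phase evaluator:** a single fixed-seed network's training R²,
  not a full ensemble — ensembles are built in a subsequent step from
  the winning subsets. Results are memoized per subset, which makes
  converged colonies cheap.
- Weights are floored at 10⁻⁶ so probabilities stay well-defined.

An exhaustive K-subset search (capped at 10,000 combinations) provides
the test oracle. Note that a *single* colony run can converge prematurely
onto a good-but-suboptimal subset once evaporation has starved the
alternatives — this is exactly what the protocol's independent restarts
guard against, and the oracle-equivalence tests run with restarts.

## Neural networks and ensembles

Three-layer fully connected nets: K inputs, h logistic hidden units
(default 2), one logistic output; online (per-pattern) squared-error
backprop for 100 epochs, learning rate linearly annealed 1.0 → 0.01,
momentum 0.8, presentation order reshuffled every epoch from the seeded RNG.
Online updates follow from the randomized per-epoch presentation order;
a batch variant is not provided. Bias units on both layers and uniform
[−0.5, 0.5] weight initialization are standard choices the source
description leaves open.

Because the logistic output lives in (0, 1), targets are affinely mapped
from their observed training range to [0.1, 0.9] (margins avoid
saturated gradients); predictions are inverse-mapped and clipped to the
representable interval. An ensemble is 10 members sharing topology and
schedule, differing only by seed (member i uses base_seed + i);
prediction is the arithmetic mean of member outputs. Training is exactly
reproducible from (table, config, seed); the inner loop is
numba-compiled.

## Validation

R²_CV is the squared Pearson correlation between pooled out-of-fold
predictions and actual scores from a 10-fold jackknife: rows shuffled,
split into 10 near-equal disjoint subsets, each predicted by a model
trained on the rest. The procedure repeats 10 times with fresh shuffles;
mean ± sd are reported. Constant predictions define R²_CV = 0 (Pearson
undefined). A 1 − SSE/SST variant exists as `r_squared_sse`. Folds are
assigned at the row (pattern) level to match the protocol, although rows
of one patient are correlated; patient-grouped folds can be had by
filtering tables per patient before CV.

External validation freezes a completer-trained ensemble and scores its
squared Pearson correlation on non-completer rows (≥ 3 required).

The experiment grid crosses scales × K ∈ {2,4,6,8,10,12,14} × h ∈
{1,2,3} × 5 selection restarts, each followed by a 10-member ensemble
and 10 × 10-fold CV; the bookkeeping product
scales·|K|·|h|·restarts·ensemble·(reps+1)·folds reproduces the
conventional tally of 462,000 network trainings for the default plan
(the "+1" counts each network's training run alongside its CV runs, with
folds multiplying both, as the protocol tallies it).

**Apo-model importance:** for each feature, drop it from the pool, rerun
selection (still K features) + ensemble + repeated CV, and compare the
replicate R²_CV distributions of full vs apo model with a two-sided
Welch t-test at α = 0.05 (small replicate counts, unequal variances; the
test is swappable). Redundant features — those with correlated stand-ins
in the pool — correctly show no significant drop, which is why apo
importance and univariate correlation disagree.

## Composite endpoints

On the completers, the per-patient change matrix Δ holds day-90 minus
day-7 normalized feature values. For weights w, the composite change is
Δw and d(w) = mean(Δw)/sd(Δw) (sample sd, n−1). d is homogeneous of
degree 0 in w and sign-flips with w, so optimization fixes max|w| = 1
and the sign making d ≥ 0.

- **Greedy forward:** first feature = largest |single-feature d|, weight
  ±1; each later step adds the (feature, weight) pair maximizing d over
  the discrete grid {−1 … +1 step 0.1, 0 excluded — 20 values; the
  originating description's "18 discrete weights" over the same range is
  arithmetically inconsistent and the grid is configurable} with prior
  weights frozen. If no non-zero weight improves d the feature enters at
  weight 0, so the training-d curve is non-decreasing in size by
  construction. After each addition, cyclic coordinate refinement over
  the grid (plus 0) runs until a full pass yields no improvement (cap
  100 passes). Ties break by pool order, then smaller |weight|.
- **Backward elimination:** Newton–Raphson maximization of d over
  continuous weights (analytic gradient and Hessian; pseudo-inverse
  Newton step with a line-searched gradient-ascent fallback when the
  step is unusable — the Hessian is necessarily singular at the optimum
  because of scale invariance), renormalizing max|w| = 1 each step; then
  repeatedly drop the smallest-|w| feature and re-optimize down to one
  feature, returning the best composite on the path. The continuous
  optimum is the generalized Rayleigh solution w* ∝ S⁻¹μ, which the
  tests use as an independent oracle.
- **Validation:** 100 repeats of an 80/20 patient-level split (patients,
  not rows, are the sampling unit for paired changes); composites built
  on the training 80%, d evaluated on both partitions, aggregated per
  composite size. Validation d sits below training d — the optimism gap
  the repeated holdout exists to measure.
- **Registry comparison:** for each index patient, `ratio` registry
  subjects with the identical day-7 NIH score are drawn without
  replacement, so the matched cohort reproduces the index histogram
  exactly; its day-7→90 improvement yields the historical effect size.
  Required-n arithmetic uses n ∝ 1/d².

Eq-wise the composite is strictly linear in the features; a squared-term
variant can be explored by squaring columns of the change matrix before
optimization, but linearity is the designed behavior (a nonlinear
effect-size maximizer is ill-posed — d has no intrinsic upper bound).

## Correlation map and baselines

Correlation distances d_ij = 1 − |Pearson R_ij| over the 35 features + 4
scales, computed pairwise-complete (MR exists only at days 30/90;
listwise deletion would discard most rows); pairs with < 3 joint
observations are flagged missing and excluded from the embedding stress.
Stochastic proximity embedding places the 39 points in 2-D by repeated
random-pair updates moving both points by λ(d_target − d_current)/
(d_current + ε)/2 along their difference, λ annealed 1.0 → 0.01 over
50·n² steps (ε = 10⁻⁹); normalized stress Σ(d_t − d_c)²/Σd_t². Stress is
invariant to rigid motions of the output, and exactly planar
configurations embed with stress < 0.01.

PCA profiling reports eigenvalue fractions of the correlation matrix and
the component counts reaching 90/95/99% cumulative variance. The
PCA-based feature picker walks down successive components taking the
not-yet-chosen variable with the largest |loading| — one defensible
reading of an under-specified "PCA selects the most important features"
procedure, documented as such. The MLR baseline is ordinary least
squares (minimum-norm on collinear designs, with a warning),
cross-validated with the identical jackknife so nonlinear-vs-linear and
selection-vs-filter comparisons are like for like.

## Problem sizes and numerical choices

The package's own desk-scale defaults — 300 ants, 2 restarts, 3 CV
repetitions, 100 holdout repeats, 208 synthetic patients, 30,000
registry subjects — run the full chain in seconds to minutes on one CPU
and are the sizes at which the shipped tests and acceptance script
operate; the `--full-scale` flag restores the original protocol sizes.
Key numerical rules: degenerate normalization → 0 with warning; R² < 0
clamped to 0 before the path-length transform; L capped at 10¹² at
R² = 0; constant predictions → R²_CV = 0; zero-spread composite
candidates skipped; weights floored at 10⁻⁶; holdout repeats with < 2
validation patients redrawn.

## Known limitations

- Row-level CV folds let repeated measures of one patient straddle
  folds; R²_CV is accordingly optimistic relative to patient-grouped CV.
- The generator's missingness is non-informative; real non-completers
  differ systematically from completers.
- Ordinal scales are modeled as rounded continuous links; threshold
  (cumulative-link) structure is not simulated.
- SPE is run once per seed; multi-start stress minimization is left to
  the caller.
- The synthetic registry shares its improvement distribution across all
  day-7 strata, which real registries do not.
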