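# Methods

This note documents the models and procedures implemented in `clinautoml`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions that make runs reproducible.

## 1. The model-selection problem

A candidate pipeline ("configuration") is a point in the cross product of a
learning algorithm, a feature-selection technique, and the active
hyper-parameters of both.  The feature-selection technique — always a
(feature evaluator, feature search method) pair — is encoded as one special
categorical hyper-parameter, so a single search handles the joint choice.
Conditional hyper-parameters (e.g. the polynomial degree, active only for a
polynomial kernel) are assigned only when their parent condition holds;
condition chains must be acyclic.

The default registry covers 6 classification and 5 regression learners
(penalized logistic/linear model, SVM, decision tree, random forest,
gradient-boosted trees, k-NN) with 1–5 hyper-parameters each, and 5
feature-selection techniques ("none", ANOVA-F ranking, mutual-information
ranking, correlation-based greedy-forward subset, tree-importance ranking).
Hyper-parameter ranges are registry policy, not fixed by any external
source; the registry is user-extensible through its YAML serialization.
Scale conventions: regularization-type constants search uniformly in log10;
counts and depths uniformly on integer ranges.

### Configuration distance and encoding

The spacing constraint and the surrogate both need geometry:

* **distance** — mean over the union of active dimensions (plus the
  technique id as a categorical dimension) of per-dimension distances:
  numeric dims use |difference on the spec's scale| normalized by the span;
  categorical/boolean dims are 0/1; a dimension active on only one side
  counts 1.  The mean (not max) keeps added dimensions from inflating
  separation; treating one-sided activity as maximal treats structural
  difference as maximal.  The result is a pseudometric on encodings.
* **encoding** — numeric dims map to their [0, 1] scale position (−1 when
  inactive), categoricals one-hot; technique ids one-hot over the registry.

## 2. The staged search

Stages use nested training samples (progressive sampling).  Default
schedule: geometric ×2 growth from max(500, 5% of the dataset) to the full
training size.  Allocation policies:

* `fixed_validation` (default for n ≥ 4000): two equal, disjoint validation
  samples drawn once (20% of the data in total) and reused across stages;
* `resampled_validation`: validation samples redrawn per stage from the
  instances outside that stage's training sample — an alternative guard
  against validation reuse; the two policies can be compared empirically,
  neither is hard-coded;
* `dynamic_allocation` (default for n < 4000): every non-training instance
  goes to validation, split evenly, making small-data error estimates as
  robust as possible.

**Stage 1** evaluates, per algorithm, the default configuration plus
`stage1_random_per_algorithm` (default 20) random ones.  When an algorithm's
configuration space is finite and fits that budget it is enumerated
exhaustively in canonical order instead — tiny spaces then coincide exactly
with brute force.  Test counts per feature evaluator and per feature search
method are topped up to `min_tests_per_component` (default 3) so no
component goes unmeasured.

**Elimination** ranks surviving algorithms by their best guarded error among
the just-completed stage's records and keeps the best
`elimination_keep_fraction` (default 0.5, ceiling); the incumbent's
algorithm is always protected (it may rank low at the current stage while
holding the overall best from an earlier one — never discard the current
best).  The "promising error" threshold reported for the next stage is the
worst surviving per-algorithm best.

**Sharing**: after each non-final stage the feature-selection side
(technique + its hyper-parameter values, carried verbatim) of the `n1 = 3`
best full combinations is extracted (duplicates collapse, so n₂ ≤ n₁) and
each surviving algorithm is guaranteed one evaluation with each shared
combination at the next stage, attached to that algorithm's best-known
algorithm-side values (defaults if none).

**Response-surface rounds**: per surviving algorithm, a 50-tree random
forest regresses guarded error on encoded configurations; a 500-point random
pool is filtered greedily so every retained candidate is at least
`min_distance` (default 0.1, ×0.8 per stage) from every other retained
candidate and from configurations already tested this stage; retained
candidates are ranked by expected improvement over the algorithm's best
error, with the ensemble's per-tree spread as the predictive standard
deviation.  With fewer than two records the proposal falls back to random
sampling.  An unsatisfiable spacing constraint returns the maximal spaced
subset found.

**Final stage** re-evaluates the `final_top_f = 5` best distinct
configurations at the full training size and returns the argmin.

**Overfitting guard** (`guarded_error`): with first/second-validation errors
e₁, e₂ and the stage's e₁ history, return e₁ if e₁ exceeds the history's
median (`stage_quantile = 0.5`); else e₁ if e₂ − e₁ < `gap_threshold`; else
e₂.  The gap threshold is 0.05 in *absolute error-rate points* (the natural
reading of a "5%" gap between error rates), configurable.  An empty history
makes the first branch inactive, so a stage's first evaluations cannot be
short-circuited.  Regression tasks use the normalized loss 1 − R² clipped to
[0, 1] so the same thresholds stay meaningful.

**Failures as data**: any training exception or non-finite score yields a
record with error 1.0 and a failure flag, steering the search away instead
of aborting.  A per-fit wall-clock is recorded; hard in-process timeouts of
a running fit are not enforced (single-machine scope) — long-running
algorithm families should be bounded via their registry ranges.

**Determinism**: every evaluation's seed is a CRC32 hash of (base seed,
stage, canonical configuration key), so identical configurations get
identical records regardless of visit order; ties break by (error, stage,
configuration key).  Budgets run on wall-clock by default, with an
evaluation-count mode for exactly reproducible tests.

**Anytime output**: after every evaluation the (elapsed, best-error-so-far)
curve is extended; the forecast fits e(t) = a + b·t^(−c) by bounded least
squares (a ≥ 0) and reports a residual-RMS band.  Fewer than three distinct
curve points → forecast unavailable.  The inverse power law is a display
convention, not a modeling claim.

## 3. Temporal aggregation

Input is a minimal long-format schema (person, attribute, ISO-8601 or
numeric-day timestamp, value) plus per-patient index dates — an
OMOP-inspired shape without vocabulary handling, since the aggregation math
is terminology-independent.  Windows are half-open lookbacks
`(index − period, index]`: a record exactly `period` days before the index
date is excluded; a record on the index date is included.  Operators are
order-invariant in the (timestamp, value) multiset (inputs are canonically
sorted, so permuting file rows is a bit-exact no-op).  Singleton/empty
conventions: count-family operators return 0 on empty windows, everything
else is missing; SD and slope need ≥ 2 points; the increasing-trend
indicator is 1 iff values are non-decreasing in time with ≥ 2 points (0 for
singletons); categorical mode breaks ties lexicographically.

Pair choice per attribute enters the search as a categorical
hyper-parameter whose domain enumerates (operator, period) pairs (default
period grid 30/90/180/365/730 days); choose-1 per attribute is the default
to bound the space, choose-k is available (k-subsets as tokens).  An
optional per-attribute restriction of allowed operators/periods stands in
for clinician-curated disease-specific knowledge.  Expanded columns are
cached per (attribute, pair), so a search touching the same pair twice pays
once.

## 4. Impact simulation

Scenario: units adopt with probability L = p₁·p₂; binary outcomes use the
odds-scale transform r₁ = OR·r₀/(1−r₀) / (1 + OR·r₀/(1−r₀)) in adopting
units (for rare outcomes r₁/r₀ → OR, the risk-ratio reading); count outcomes
scale the per-unit Poisson mean (unit total days / unit patient count when
given) by 1 − reduction.  Per-unit totals are multiplied by survey weights
and summed to national estimates; multiple runs are averaged.  The default
baseline rate 0.05 is a placeholder scenario parameter, not an empirical
value.  Unit-specific baseline rates are supported (a `rate` column);
otherwise the national rate applies everywhere.

Pairing: the two arms share the unit structure, patient indexing, and
adoption stream, but outcome draws are independent per arm from dedicated
seeded streams.  Two consequences, both deliberate: the without-tool arm is
bit-invariant to (p₁, p₂, OR) under a fixed seed, and the paired 2×2 table
has both discordant cells populated, so the McNemar test is calibrated
(fully common outcome draws would make the arms comonotone and empty the
discordant cells the test lives on).  The McNemar statistic is the
continuity-corrected chi-square on the discordant pair counts
(cross-checked against statsmodels); zero discordant pairs returns p = 1
with a flag.  Count outcomes use a paired t test.  The sensitivity grid
spans 5×5 (p₁, p₂) levels (linearly spaced min→max; the middle level is the
default), sharing the seed across cells (common random numbers at the
structure level).  A helper converts an observed success proportion and n
into p₁ levels via a normal fit's 2.5/97.5 percentile points.

## 5. Power computations

Each routine documents its lineage and exposes variants, because protocol
design numbers are typically produced by software with unstated internals:

* `binom_lower_cl`: continuity-corrected Wald
  max(0, p̂ − z·√(p̂(1−p̂)/n) − 1/(2n)) and exact Clopper–Pearson
  (beta-quantile).  At n = 25, p̂ = 0.60 they give 0.4188 and 0.4168 — the
  methods disagree in the third decimal; both round to 42%.
* `mcnemar_power` / `mcnemar_n`: unconditional normal approximation with
  p₁₀ = ψ·OR/(1+OR), p₀₁ = ψ/(1+OR), d = p₁₀ − p₀₁ and
  power = Φ((√n|d| − z_{α/2}√ψ)/√(ψ − d²)) plus the (negligible away from
  the null) opposite-tail mass, which makes power equal α exactly at OR = 1.
  A conditional variant (binomial split of the expected discordant count) is
  exposed.  Sample size is the ceiling of the continuous inversion; at
  ψ = 0.10, OR = 0.53, α = 0.05, 90% power this is n = 1110 (continuous
  solution 1109.3), while the power at the commonly quoted n = 1152 is
  0.910.  The Monte-Carlo cross-check scores simulated tables with the
  uncorrected chi-square the formula approximates.
* `r2_increment_power`: Cohen-style noncentral F with
  f² = ΔR²/(1 − R²_full) and λ = f²(u + v + 1), v = n − u − other − 1.  A
  baseline model entering as one fixed score contributes through R²_reduced,
  not the denominator df (`other_predictors = 0`); counting its 300 raw
  features instead (`other_predictors = 300`) drops the power at n = 443
  from 0.93 to about 0.33 — the difference is documented, both readings are
  computable.
* `auc_diff_power`: two-sided Z test with Hanley–McNeil per-subject
  variances v(A) = (Q₁ − A²) + (Q₂ − A²), Q₁ = A/(2−A), Q₂ = 2A²/(1+A), and
  Var(ΔA) = (v₁ + v₂ − 2r√(v₁v₂))/n per class.  The baseline AUC pair is a
  required input — no default is assumed.

## 6. Synthetic generators

All generators are pure functions of their arguments (seed included) and
return planted ground truth sufficient for recovery tests.

* **Tabular**: standard-normal features; linear-logit signal on an
  informative subset, or an XOR-of-signs signal invisible to univariate
  screens and linear models.  Effect sizes are stated in AUC units: an
  internal bisection (fixed internal seed, 200k draws) finds the logit scale
  whose latent AUC matches the target; `target_auc = 1.0` gives a noiseless
  threshold rule.  Missingness is completely at random only.
* **Longitudinal**: irregular visits over 2 years ending at the index date;
  the signal attribute is flat before the planted lookback window (default
  180 days) and ramps linearly inside it with a patient-specific slope that
  alone drives the outcome logit (calibrated to a target AUC of 0.85).  The
  patient's mean level is independent of the outcome by construction, so a
  (mean, 365 d) aggregation is weak (AUC ≤ 0.65 in practice) while slope
  pairs reach ≥ 0.80.  Because the pre-window segment is flat, slopes over
  windows containing the planted one (e.g. 365 d) remain informative —
  recovery tests therefore accept any slope pair, not only the exact planted
  period.
* **Unit table**: log-normal unit sizes, weight = inverse sampling fraction
  (uniform), per-unit rates logit-normal and day-means log-normal around
  national values; sizes rescale to match a configured national patient
  count up to integer rounding.

What the generators do **not** emulate: realistic clinical value
distributions, coding systems, informative missingness, or inter-attribute
correlation beyond the planted signal.  Passing recovery tests therefore
demonstrates that the machinery finds planted structure at stated effect
sizes — not performance on real clinical data.

## 7. Validation experiments and problem sizes

`clinautoml.experiments` packages the studies the reproducibility script
runs; sizes are chosen for minutes-scale single-CPU runs:

* *Exhaustive-search equivalence*: 2 algorithms × 3 finite settings each
  (6 configurations), n = 500, single stage — the staged search must return
  exactly the independent exhaustive argmin under shared splits and seeds.
* *Planted-pair recovery*: 20 replicates of 240 patients; pair domain of
  4 operators × 3 periods crossed with a 3-point regularization grid (36
  configurations, enumerated at stage 1, leaders re-tested at the final
  stage).  Reported: fraction of replicates where the searched pipeline's
  final validation error beats the forced (mean, 365 d) baseline, and both
  pipelines' cross-validated AUCs.
* *Simulator calibration*: 200 units × ~500 patients × 50 runs at L = 1;
  the with-tool mortality rate is compared with the odds-scale target within
  Monte-Carlo standard error.
* *Type-I calibration*: 1000 replicates of a 500-patient null scenario
  (OR = 1); the continuity-corrected McNemar test rejects at ~4%, the mild
  conservatism expected of the correction.

## 8. Known limitations

Single-machine execution (evaluations within a batch are independent by
contract, but no distributed backend ships); no in-fit hard timeouts; no
class-imbalance resampling beyond what individual learners offer; choose-k
aggregation enumerates k-subsets and grows combinatorially; the conditional
McNemar variant uses a normal approximation rather than exact enumeration;
the impact simulator models adoption and outcome rates, not costs.
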