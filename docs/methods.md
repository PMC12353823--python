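# Methods

## Scope and model

`extarm` implements the estimation workflow for augmenting a small
single-arm trial with an external control cohort. The estimand is the
average treatment effect among the treated (ATT) on 1-year changes in
functional endpoints, chiefly the NSAA total score (17 items scored
0/1/2, total 0–34, higher = better function). The assumed identification
conditions are the usual ones for propensity-score methods: no unmeasured
confounding given the four prespecified covariates (screening age,
baseline NSAA total, rise-from-floor velocity, 10-m run/walk velocity),
positivity, and correct specification of either the propensity model
(IPTW) or the outcome regression (AIPW — consistent if either is right).

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions
under which the estimators are validated.

**Covariates.** Treated: age uniform on [4, 12]; NSAA total, rise
velocity and 10-m velocity from truncated normals with means 25.8, 0.28
(1/s) and 2.29 (m/s) and s.d. 4.5, 0.10 and 0.45 (bounds [5, 34],
[0.145, 1.0], [0.5, 4.5]). The external pool draws from the same
families with means shifted by `confounding_strength ×
(+0.3, +0.2, −0.06, −0.33)` — the velocity shifts match the baseline
differences in the emulated trial's results table. Because the shifted
truncated normals share their truncation bounds, their log-density ratio
is linear, so a linear-logistic propensity model is essentially correctly
specified (the clipped age shift departs mildly; measured balance shows
no systematic residual).

**Outcomes.** The NSAA 1-year change is
`drift + att·treated + β·(x − μ_ref) + ε` with defaults
`att = 3.4`, `drift = −2.7`, `β = (−0.8, 0.1, 8.0, 2.0)` centered at the
treated covariate means, and arm-specific noise s.d. 4.0 (treated) / 5.3
(external) matching the emulated trial's observed change dispersions.
Totals are rounded and clipped to [0, 34]. The six secondary endpoints
(rise, 10-m and four-stair velocities, 6-min walk distance, PUL 2.0,
%pFVC) use endpoint-specific drift/effect/noise values anchored to the
same results table, without covariate terms: they share the analysis
weights but are not needed to stress confounding removal twice.

**Eligibility.** Each pool member passes all selection rules with
probability `pass_fraction` (default 0.4, close to the emulated 59/156);
a failing member receives one violated rule at random (slow rise, low
LVEF, short steroid exposure, missing 1-year NSAA, or non-ambulatory
items). This makes the selected count exactly reproduce the generator's
Bernoulli indicator — a deliberately sharp oracle for the selection
logic — at the cost of not modeling covariate-dependent eligibility
beyond the rise-time rule.

**NSAA items.** A participant's total is spread over the 17 items by
weighted sampling without replacement over two unit slots per item
(Gumbel top-k), with weights decreasing in a fixed difficulty ordering
(walking and standing easiest). Item sums equal totals exactly at every
visit. Real item trajectories are more autocorrelated than this; the
worked-example fixture (below) therefore pins the item-level statistics
the package must reproduce, independent of this model.

**Fibers and LC-MS.** Per-fiber mean stain density is a two-component
log-normal mixture: background LN(0, 0.5), positive component
LN(2.5, 0.4) (essentially disjoint from the background's upper tail),
mixing fraction 0 / 0.20 / 0.35 at baseline / 2 months / 1 year, 800
fibers per section, two sections per biopsy. LC-MS concentrations are
log-normal around visit means 41.5 / 656.7 / 1192.3 fmol mg⁻¹ with a
control-tissue mean of 2964 (so baseline sits near 1.4% of normal) and
an LLOQ of 10.

**What the generator does not emulate:** longitudinal visit structure
beyond two time points, item-level measurement error, informative
missingness (missingness generators default to off), site effects, or
any safety data. Passing tests demonstrate the estimators' statistical
properties under these conditions, not performance on real trial data.

## Worked-example fixture

`worked_example_fixture()` deterministically constructs item vectors for
16 treated and 59 external participants such that 7 and 17 participants
respectively have at least one baseline-zero item, 5 of each group gain
at least one skill (71.4% vs 29.4%), and the medians of skills
improved-or-maintained are 16.0 and 12.0. Each participant is built from
a triple (baseline zeros, gains, improved-or-maintained count); the
construction sets nonzero baseline items to 2 and drops declined items to
0, which is stylized but fully determined.

## Numerical and procedural choices

- **Propensity fit:** statsmodels maximum-likelihood logistic regression
  (Newton, tolerance 1e-8, max 100 iterations), linear terms only.
  Constant covariates are dropped so the degenerate case reduces to an
  intercept-only fit. Separation is detected both from the optimizer and
  from fitted probabilities within 1e-10 of 0/1, and reported with the
  offending covariate where one covariate alone separates the arms.
- **Quantiles:** linear interpolation between order statistics
  throughout (weight-trim cap, fiber threshold); the convention is
  recorded in the output metadata.
- **Trimming/renormalization:** external weights are capped at their
  95th percentile and divided by their post-trim sum. All estimators use
  weighted means, which are invariant to the within-arm scale, so the
  unit-sum convention is cosmetic but fixed.
- **Trim-induced imbalance:** capping the largest external weights
  systematically under-represents the most treated-like controls. Under
  the default confounding this leaves a persistent ≈ +0.1 weighted SMD
  on the strongly confounded covariates that does not vanish with sample
  size. Balance of the propensity weighting itself is therefore assessed
  on untrimmed (renormalized) ATT weights; the trimmed analysis weights
  trade this bias for variance control, and the validation suite reports
  both.
- **Bootstrap:** stratified within arms with fixed arm sizes (the arms
  are design-fixed); every replicate refits the propensity model and
  re-trims, so the s.e. carries design-stage uncertainty. Replicates
  with a degenerate propensity fit are redrawn, capped at 20 × B
  attempts. The replicate loop uses an array-form implementation proven
  identical (to 1e-12) to the DataFrame pipeline by test.
- **BC interval:** bias-corrected percentile interval with
  `z₀ = Φ⁻¹(#{θ*_b < θ̂}/B)` (clamped away from 0/1 by 1/(B+1)) and no
  acceleration term (no jackknife is involved anywhere in the
  procedure). With z₀ = 0 it reduces to the plain percentile interval.
- **p-value:** one-sided in the beneficial direction, computed on the
  null-centered bootstrap distribution — `p = #{θ*_b − θ̄* ≥ θ̂}/B`,
  floored at 1/(B+1). An uncentered reading of "proportion of bootstrap
  samples more extreme than the observed value" returns ≈ 0.5 for any
  data and was rejected as self-defeating.
- **Seed streams:** every endpoint in the battery draws from a
  counter-based stream keyed by (seed, CRC32 of the endpoint name), so
  per-endpoint results are independent of battery order.
- **Skill definitions:** "same or higher nonzero score" is read with the
  nonzero requirement on the 1-year score, so a 0→1 transition counts as
  both gained and improved; `strict=True` switches to requiring a
  nonzero baseline. Items missing at either visit are excluded from both
  counts.
- **Ambulation rule:** the three-part rule contains a literally-read
  disjunct under which any observed item-17 score (including 0)
  qualifies; the default is the charitable reading (item 17 ∈ {1, 2}, or
  item 2 ∈ {1, 2} only when item 17 is missing), with
  `literal_ambulation=True` available.
- **Boundaries:** LVEF ≥ 55% inclusive (switchable to strict), rise time
  ≤ 7 s inclusive, ages 4 and 12 inclusive. Missing LVEF never excludes
  ("data permitting"). Date arithmetic uses calendar months with
  day-of-month clamping.
- **Fiber positivity:** strictly above the threshold; ties are negative.
  Cohort summaries average per-participant percentages (not pooled
  fibers) and use a two-sided t-interval; a log-scale option produces an
  asymmetric interval about the geometric mean for expression endpoints.
- **Complete-case analysis:** missing changes or covariates are excluded
  per endpoint; no outcome imputation. No multiplicity adjustment across
  the endpoint battery.

## Validation studies and problem sizes

`extarm.validation` runs the repeated-study checks (also exercised by the
acceptance suite and `scripts/acceptance.py`):

- **Recovery/coverage:** 200 trial-sized studies (16 treated, pool 156),
  B = 500; the Monte-Carlo mean IPTW-ATT estimate and the coverage of
  the BC 95% interval against the generating +3.4.
- **Type-I error:** the same design with a null effect; one-sided
  rejection rate at α = 0.05.
- **Balance:** 200 enlarged studies (400 treated, pool 4000, external
  arm ≈ 1500 after selection) because in-sample balance is a
  large-sample property; fraction of datasets with all four weighted
  |SMD| ≤ 0.1 on untrimmed ATT weights, with the trimmed-weights rate
  reported alongside.
- **Threshold:** the fraction of pooled baseline fibers strictly above
  the fitted 99th percentile, which equals 1% up to discreteness.

## Known limitations

Single-knob confounding (a mean shift plus a fixed linear outcome
dependence) cannot represent interactions or non-linear selection; the
AIPW double-robustness check misspecifies the propensity model by
replacing it with unit weights rather than by distorting its functional
form; bootstrap inference with 16 treated participants is fragile to
separation in replicates (handled by redraw, which slightly biases the
bootstrap distribution toward separable-free configurations); and the
asymmetric confidence intervals reported for expression endpoints in
real trials are of unstated construction — the package offers t- and
log-t intervals only.
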