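# extarm

External-control-arm analytics for small single-arm trials, built around
the statistical workflow of a phase 1b gene-therapy trial in ambulatory
boys with Duchenne muscular dystrophy (DMD): derivation of an external
control cohort from placebo participants of prior trials, propensity-score
weighted estimation of 1-year functional treatment effects, doubly robust
sensitivity analysis, stratified bootstrap inference, item-level North
Star Ambulatory Assessment (NSAA) skill analytics, and quantification of
dystrophin expression from per-fiber immunofluorescence intensities and
LC-MS concentrations. A synthetic-data module with known ground truth
stands in for participant-level trial data, so every estimator can be
validated by parameter recovery.

## The statistical problem

A single-arm trial with n = 16 treated participants cannot estimate a
treatment effect without a comparator. The workflow implemented here:

1. **Eligibility selection.** From a pool of 156 placebo participants of
   prior randomized trials, retain those aged 4–12 years at screening
   (inclusive), ambulatory by NSAA items (item 17 scoring 1–2, or item 2
   rescuing a missing item 17), able to rise from the floor in ≤ 7 s,
   with LVEF ≥ 55% where cardiac data exist, a stable steroid regimen for
   ≥ 6 months (missing start dates imputed as 6 months before screening),
   and nonmissing NSAA totals at baseline and 1 year.
2. **IPTW-ATT weighting.** Estimate the propensity score `P_i` — the
   probability of being treated given four prespecified covariates
   (screening age, baseline NSAA total, rise-from-floor velocity, 10-m
   run/walk velocity) — by logistic regression, then weight

   `W_i = 1` (treated), `W_i = P_i / (1 − P_i)` (external),

   cap external weights at their 95th percentile and renormalize them to
   sum to one. Balance is checked with standardized mean differences
   (SMD).
3. **Estimation.** The IPTW-ATT effect is the difference of weighted mean
   1-year changes (equivalently, weighted least squares on a treatment
   indicator). The doubly robust (AIPW) effect adds the four covariates
   to the weighted outcome regression.
4. **Inference.** B stratified bootstrap resamples (within-arm, arm sizes
   fixed) re-run the whole pipeline; reported are the bootstrap s.e., the
   bias-corrected (BC) percentile 95% CI, and a one-sided empirical
   p-value from the null-centered bootstrap distribution.
5. **Item-level NSAA.** A *skill gained* is an item scoring 0 at baseline
   and 1–2 at 1 year; a *skill improved-or-maintained* has the same or
   higher nonzero score at 1 year.
6. **Dystrophin quantification.** The fiber-positivity threshold is the
   99th percentile of pooled baseline mean-stain-density values; a fiber
   is positive strictly above it. Section percentages are averaged per
   biopsy; LC-MS concentrations below the LLOQ are imputed at half the
   LLOQ and normalized to the control-tissue mean.

## Worked example

```sh
python examples/04_effect_estimation.py
```

```
IPTW: LS means -1.69 vs -2.78, difference +1.09 (s.e. 1.33, 95% CI -1.50 to 3.68, one-sided p = 0.1945)
AIPW: LS means -1.69 vs -2.65, difference +0.97 (s.e. 1.10, 95% CI -1.07 to 3.17, one-sided p = 0.1905)
```

This synthetic study (seed 42) was generated with a true treated-group
benefit of +3.4 NSAA points over a control drift of −2.7; a single trial
with 16 treated participants estimates it with a standard error of about
1.4, so individual runs scatter widely around the truth — the Monte-Carlo
suites below show the estimator is centered correctly. The other example
scripts cover simulation (`01`), cohort selection (`02`), weighting and
balance (`03`), and skill/expression analytics (`05`); each prints the
numbers it computes with a line on what they mean.

A thin CLI wraps the same pipeline for file-based runs:

```sh
extarm simulate --seed 1 --out data/
extarm run-all --seed 1 --out results/ --input-dir data/
```

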