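"""Treatment-effect estimation with stratified bootstrap inference.

The IPTW-ATT estimate is the difference of weighted mean 1-year changes
(treated minus external); the AIPW estimate adds the propensity
covariates to the weighted outcome regression for double robustness.
Every bootstrap replicate resamples within arms and re-runs the entire
pipeline, propagating the design-stage uncertainty into the standard
error, the bias-corrected 95% CI and the one-sided p-value.
"""

from extarm import SimConfig, bootstrap_infer, generate_study
from extarm.pipeline import derive_analysis

study = generate_study(SimConfig(seed=42))
analysis = derive_analysis(study)

for estimator in ("iptw", "aipw"):
    est, boot = bootstrap_infer(analysis, B=2000, seed=42,
                                estimator=estimator)
    print(f"{estimator.upper():4s}: LS means "
          f"{est.ls_mean_treated:+.2f} vs {est.ls_mean_external:+.2f}, "
          f"difference {est.difference:+.2f} "
          f"(s.e. {est.se_boot:.2f}, "
          f"95% CI {est.ci_low:.2f} to {est.ci_high:.2f}, "
          f"one-sided p = {est.p_one_sided:.4f})")
# The generating truth for this configuration is +3.4 NSAA points; a
# CI excluding 0 with small p indicates the weighted comparison detects
# the treatment benefit over the external cohort's decline.
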