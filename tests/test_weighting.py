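"""Propensity fitting, ATT weights, trimming and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from extarm.simulate import PS_COVARIATES, SimConfig, generate_study
from extarm.weighting import (PSFit, SeparationError, att_weights,
                              balance_table, fit_propensity,
                              trim_and_renormalize)


def _psfit_from_p(p, ids=None):
    ids = ids if ids is not None else [f"P{i}" for i in range(len(p))]
    return PSFit(coefficients=pd.Series(dtype=float),
                 fitted_p=pd.Series(p, index=ids),
                 covariate_names=PS_COVARIATES, converged=True, n_iter=1)


class TestFitPropensity:
    def test_constant_covariates_give_marginal_probability(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        for c in PS_COVARIATES:
            cohort[c] = 1.0
        fit = fit_propensity(cohort)
        np.testing.assert_allclose(fit.fitted_p, 10 / 50, atol=1e-8)

    def test_single_arm_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="both arms"):
            fit_propensity(tiny_cohort[tiny_cohort.arm == "external"])

    def test_missing_covariates_name_ids(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        cohort.loc[3, "rise_velocity"] = np.nan
        with pytest.raises(ValueError, match="P3"):
            fit_propensity(cohort)

    def test_perfect_separation_names_covariate(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        t = cohort.arm != "external"
        cohort.loc[t, "run10_velocity"] = 10.0 + cohort.loc[t].index / 100
        cohort.loc[~t, "run10_velocity"] = 1.0 + cohort.loc[~t].index / 100
        with pytest.raises(SeparationError, match="run10_velocity"):
            fit_propensity(cohort)

    def test_coefficient_recovery_on_large_sample(self):
        # logistic truth: linear log-odds in the generator's shifted
        # truncated normals; check fitted coefficients stabilize across
        # two sample sizes rather than asserting analytic values
        from extarm.pipeline import derive_analysis
        big = generate_study(SimConfig(
            seed=31, n_treated=4000, n_pool=4000, include_items=False,
            include_biopsies=False))
        cohort = derive_analysis(big)
        fit = fit_propensity(cohort)
        assert fit.converged
        p = fit.fitted_p.to_numpy()
        assert ((p > 0) & (p < 1)).all()
        # shifted covariates get nonzero slopes of the expected sign
        assert fit.coefficients["run10_velocity"] > 0
        assert fit.coefficients["rise_velocity"] > 0


class TestAttWeights:
    def test_formula_values(self):
        fit = _psfit_from_p([0.5, 0.8, 0.3])
        arm = pd.Series(["external", "external", "treated_high"],
                        index=fit.fitted_p.index)
        wv = att_weights(fit, arm)
        np.testing.assert_allclose(wv.w.to_numpy(), [1.0, 4.0, 1.0])
        assert wv.stage == "raw"

    @given(st.permutations(range(6)))
    def test_permutation_equivariance(self, perm):
        p = np.array([0.1, 0.25, 0.4, 0.55, 0.7, 0.8])
        arm = np.array(["external"] * 4 + ["treated_high"] * 2)
        ids = [f"P{i}" for i in range(6)]
        base = att_weights(_psfit_from_p(p, ids),
                           pd.Series(arm, index=ids))
        p2, arm2 = p[list(perm)], arm[list(perm)]
        ids2 = [ids[i] for i in perm]
        permuted = att_weights(_psfit_from_p(p2, ids2),
                               pd.Series(arm2, index=ids2))
        for pid in ids:
            assert permuted.w[pid] == base.w[pid]


class TestTrimRenormalize:
    def test_uniform_weights_untouched_up_to_scale(self):
        fit = _psfit_from_p([0.5] * 5 + [0.9])
        arm = pd.Series(["external"] * 5 + ["treated_high"],
                        index=fit.fitted_p.index)
        wv = trim_and_renormalize(att_weights(fit, arm))
        np.testing.assert_allclose(wv.external().to_numpy(),
                                   np.full(5, 0.2), atol=1e-12)
        assert wv.trim_cap == pytest.approx(1.0)

    def test_enumerated_quantile_cap_oracle(self):
        # weights [1,1,1,1,100]: the linear-interpolation 95th percentile
        # over five points sits at rank 0.95*(5-1)=3.8 -> 1 + 0.8*99 = 80.2
        ids = [f"E{i}" for i in range(5)] + ["T0"]
        w_ext = [1.0, 1.0, 1.0, 1.0, 100.0]
        p = [w / (1 + w) for w in w_ext] + [0.5]
        arm = pd.Series(["external"] * 5 + ["treated_high"], index=ids)
        wv = trim_and_renormalize(att_weights(_psfit_from_p(p, ids), arm))
        assert wv.trim_cap == pytest.approx(80.2)
        expected = np.array([1, 1, 1, 1, 80.2]) / 84.2
        np.testing.assert_allclose(wv.external().to_numpy(), expected,
                                   rtol=1e-9)

    @given(st.lists(st.floats(0.05, 0.95), min_size=3, max_size=30))
    def test_trim_never_increases_and_preserves_ratios(self, ps):
        ids = [f"E{i}" for i in range(len(ps))] + ["T0"]
        p = list(ps) + [0.5]
        arm = pd.Series(["external"] * len(ps) + ["treated_high"],
                        index=ids)
        raw = att_weights(_psfit_from_p(p, ids), arm)
        out = trim_and_renormalize(raw)
        assert out.external().sum() == pytest.approx(1.0, abs=1e-12)
        raw_e, out_e = raw.external(), out.external()
        # brute-force oracle: cap at the linear-interpolation quantile,
        # then scale to unit sum
        capped = np.minimum(raw_e.to_numpy(),
                            np.quantile(raw_e.to_numpy(), 0.95))
        assert (capped <= raw_e.to_numpy() + 1e-15).all()
        np.testing.assert_allclose(out_e.to_numpy(),
                                   capped / capped.sum(), rtol=1e-10)
        # renormalization preserves ratios among untrimmed weights
        untrimmed = raw_e[raw_e < out.trim_cap]
        if len(untrimmed) >= 2:
            ratio = out_e[untrimmed.index] / untrimmed
            np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_requires_raw_stage_and_nonempty_external(self):
        fit = _psfit_from_p([0.5, 0.5])
        arm = pd.Series(["treated_high"] * 2, index=fit.fitted_p.index)
        with pytest.raises(ValueError, match="external"):
            trim_and_renormalize(att_weights(fit, arm))


class TestBalanceTable:
    def _weights(self, cohort):
        fit = fit_propensity(cohort)
        return trim_and_renormalize(
            att_weights(fit, cohort.set_index("id")["arm"]))

    def test_identical_distributions_zero_smd(self):
        ids = [f"P{i}" for i in range(8)]
        cohort = pd.DataFrame({
            "id": ids, "arm": ["treated_high"] * 4 + ["external"] * 4,
            "age_screening": [5, 6, 7, 8] * 2,
            "nsaa_total_baseline": [20, 26, 22, 24] * 2,
            "rise_velocity": [0.2, 0.3, 0.5, 0.4] * 2,
            "run10_velocity": [1.5, 2.5, 2.0, 3.1] * 2,
        })
        bal = balance_table(cohort, self._weights(cohort))
        np.testing.assert_allclose(bal["smd_unweighted"], 0.0, atol=1e-10)

    def test_definitional_smd_of_one(self):
        rng = np.random.default_rng(2)
        n = 2000
        x_t = rng.normal(1.0, 1.0, n)
        x_e = rng.normal(0.0, 1.0, n)
        x_t = (x_t - x_t.mean()) / x_t.std(ddof=1) + 1.0  # exact moments
        x_e = (x_e - x_e.mean()) / x_e.std(ddof=1)
        cohort = pd.DataFrame({
            "id": [f"P{i}" for i in range(2 * n)],
            "arm": ["treated_high"] * n + ["external"] * n,
            "age_screening": np.concatenate([x_t, x_e]),
            "nsaa_total_baseline": 20.0,
            "rise_velocity": 0.3, "run10_velocity": 2.0,
        })
        wv = self._weights(cohort)
        # unit-weight column: means 1 vs 0, both sds 1 -> SMD exactly 1
        bal = balance_table(cohort, wv)
        assert bal.loc["age_screening", "smd_unweighted"] == \
            pytest.approx(1.0, abs=1e-9)

    def test_zero_pooled_sd_paths(self):
        ids = [f"P{i}" for i in range(4)]
        cohort = pd.DataFrame({
            "id": ids, "arm": ["treated_high"] * 2 + ["external"] * 2,
            "age_screening": [8.0] * 4, "nsaa_total_baseline": [20] * 4,
            "rise_velocity": [0.3] * 4, "run10_velocity": [2.0] * 4,
        })
        bal = balance_table(cohort, self._weights(cohort))
        assert (bal == 0).all().all()

    def test_weighted_smd_shrinks_with_correct_ps(self):
        # a single large confounded study: weighting must take the max
        # |SMD| down by an order of magnitude
        study = generate_study(SimConfig(
            seed=33, n_treated=400, n_pool=4000, include_items=False,
            include_biopsies=False))
        from extarm.pipeline import derive_analysis
        cohort = derive_analysis(study)
        fit = fit_propensity(cohort)
        wv = trim_and_renormalize(
            att_weights(fit, cohort.set_index("id")["arm"]), quantile=1.0)
        bal = balance_table(cohort, wv)
        assert bal.attrs["max_abs_smd"]["smd_weighted"] < 0.1
        assert bal.attrs["max_abs_smd"]["smd_weighted"] < \
            0.5 * bal.attrs["max_abs_smd"]["smd_unweighted"]
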