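"""Effect estimators and bootstrap inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from extarm.effects import (_estimate_once, _replicate_diff,
                            age_stratified_changes, aipw_estimate,
                            bootstrap_infer, endpoint_battery,
                            iptw_estimate)
from extarm.pipeline import derive_analysis
from extarm.simulate import PS_COVARIATES, SimConfig, generate_study
from extarm.weighting import (att_weights, fit_propensity,
                              trim_and_renormalize, WeightVector)


def _wv(w, arm):
    ids = [f"P{i}" for i in range(len(w))]
    return WeightVector(
        w=pd.Series(w, index=ids, dtype=float),
        arm=pd.Series(arm, index=ids), stage="renormalized")


def _changes(values):
    return pd.Series(values, index=[f"P{i}" for i in range(len(values))],
                     dtype=float)


class TestIptw:
    def test_unit_weight_means(self):
        wv = _wv([1, 1, 1, 1], ["treated", "treated",
                                "external", "external"])
        est = iptw_estimate(_changes([1, 1, -1, -1]), wv)
        assert est.difference == pytest.approx(2.0)
        assert est.ls_mean_treated == pytest.approx(1.0)
        assert est.ls_mean_external == pytest.approx(-1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_equals_weighted_least_squares(self, seed):
        # independent oracle: statsmodels WLS of change on treatment
        rng = np.random.default_rng(seed)
        n_t, n_e = 6, 12
        w = np.concatenate([np.ones(n_t), rng.uniform(0.01, 5, n_e)])
        y = rng.normal(size=n_t + n_e)
        t = np.array([1.0] * n_t + [0.0] * n_e)
        wv = _wv(w, ["treated"] * n_t + ["external"] * n_e)
        est = iptw_estimate(_changes(y), wv)
        wls = sm.WLS(y, sm.add_constant(t), weights=w).fit()
        assert est.difference == pytest.approx(wls.params[1], abs=1e-10)
        # and the closed-form weighted means
        oracle = (np.average(y[:n_t], weights=w[:n_t])
                  - np.average(y[n_t:], weights=w[n_t:]))
        assert est.difference == pytest.approx(oracle, abs=1e-10)

    def test_scale_invariance_in_external_weights(self):
        y = [2.0, 0.5, -1.0, 0.0, 1.0]
        arms = ["treated", "treated", "external", "external", "external"]
        a = iptw_estimate(_changes(y), _wv([1, 1, 0.2, 0.3, 0.5], arms))
        b = iptw_estimate(_changes(y), _wv([1, 1, 2.0, 3.0, 5.0], arms))
        assert a.difference == pytest.approx(b.difference, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        wv = _wv([1, 1], ["treated", "treated"])
        with pytest.raises(ValueError):
            iptw_estimate(_changes([1, 2]), wv)
        wv0 = _wv([1, 0.0], ["treated", "external"])
        with pytest.raises(ValueError, match="zero"):
            iptw_estimate(_changes([1, 2]), wv0)


class TestAipw:
    def test_constant_covariates_reduce_to_iptw(self):
        rng = np.random.default_rng(3)
        arms = ["treated"] * 4 + ["external"] * 8
        w = np.concatenate([np.ones(4), rng.uniform(0.05, 1, 8)])
        y = rng.normal(size=12)
        cov = pd.DataFrame(
            {c: 1.0 for c in PS_COVARIATES},
            index=[f"P{i}" for i in range(12)])
        wv = _wv(w, arms)
        assert aipw_estimate(_changes(y), wv, cov).difference == \
            pytest.approx(iptw_estimate(_changes(y), wv).difference,
                          abs=1e-10)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(4)
        arms = ["treated"] * 5 + ["external"] * 10
        ids = [f"P{i}" for i in range(15)]
        cov = pd.DataFrame({
            "age_screening": rng.normal(8, 2, 15),
            "nsaa_total_baseline": rng.normal(25, 4, 15),
            "rise_velocity": rng.normal(0.3, 0.05, 15),
            "run10_velocity": rng.normal(2, 0.4, 15)}, index=ids)
        cov["run10_velocity"] = 2 * cov["age_screening"] - 1
        wv = _wv(np.ones(15), arms)
        with pytest.raises(ValueError, match="run10_velocity"):
            aipw_estimate(_changes(rng.normal(size=15)), wv, cov)

    def test_doubly_robust_recovery_with_misspecified_ps(self):
        # outcome regression is correctly specified (linear covariate
        # effects), so AIPW recovers the truth even with unit weights
        # standing in for a badly misspecified propensity model
        diffs = []
        for r in range(200):
            study = generate_study(SimConfig(
                seed=60_000 + r, include_items=False,
                include_biopsies=False))
            a = derive_analysis(study)
            wv = _wv(np.ones(len(a)),
                     np.where(a.arm != "external", "treated", "external"))
            wv.w.index = a["id"].to_numpy()
            wv.arm.index = a["id"].to_numpy()
            cov = a.set_index("id")[list(PS_COVARIATES)]
            diffs.append(aipw_estimate(
                a.set_index("id")["change"], wv, cov).difference)
        mean = np.mean(diffs)
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert mean == pytest.approx(3.4, abs=3 * mc_se + 0.15)

    def test_null_generator_centered_at_zero(self):
        diffs = []
        for r in range(100):
            study = generate_study(SimConfig(
                seed=61_000 + r, true_att=0.0, include_items=False,
                include_biopsies=False))
            a = derive_analysis(study)
            diffs.append(_estimate_once(a, "aipw", 0.95, PS_COVARIATES))
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * mc_se + 0.15


class TestBootstrap:
    def test_array_and_frame_paths_identical(self, default_analysis):
        X = default_analysis[list(PS_COVARIATES)].to_numpy(float)
        t = (default_analysis.arm != "external").to_numpy(float)
        y = default_analysis.change.to_numpy(float)
        for estimator in ("iptw", "aipw"):
            fast = _replicate_diff(X, t, y, estimator, 0.95)
            slow = _estimate_once(default_analysis, estimator, 0.95,
                                  PS_COVARIATES)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_constant_outcomes_degenerate_interval(self):
        rng = np.random.default_rng(8)
        n = 30
        frame = pd.DataFrame({
            "id": [f"P{i}" for i in range(n)],
            "arm": ["treated"] * 10 + ["external"] * 20,
            "change": [2.0] * 10 + [-1.0] * 20,
            "age_screening": 8.0, "nsaa_total_baseline": 25.0,
            "rise_velocity": 0.3, "run10_velocity": 2.0})
        est, res = bootstrap_infer(frame, B=100, seed=1)
        assert est.se_boot == 0.0
        assert est.ci_low == est.ci_high == est.difference == \
            pytest.approx(3.0)

    def test_bc_interval_reduces_to_percentile_when_unbiased(self):
        # force z0 = 0 by symmetrizing: if exactly half the replicates
        # fall below the observed value the BC levels are (2.5%, 97.5%)
        boots = np.concatenate([np.linspace(-1, -0.01, 50),
                                np.linspace(0.01, 1, 50)])
        from scipy import stats
        z0 = stats.norm.ppf(np.mean(boots < 0.0))
        assert z0 == pytest.approx(0.0)
        a1 = stats.norm.cdf(2 * z0 + stats.norm.ppf(0.025))
        a2 = stats.norm.cdf(2 * z0 + stats.norm.ppf(0.975))
        np.testing.assert_allclose([a1, a2], [0.025, 0.975], atol=1e-12)

    def test_seed_reproducibility_and_B_stability(self, default_analysis):
        est1, _ = bootstrap_infer(default_analysis, B=400, seed=5)
        est2, _ = bootstrap_infer(default_analysis, B=400, seed=5)
        assert est1.se_boot == est2.se_boot
        est3, _ = bootstrap_infer(default_analysis, B=800, seed=6)
        assert est3.se_boot == pytest.approx(est1.se_boot, rel=0.15)

    def test_minimum_B_enforced(self, default_analysis):
        with pytest.raises(ValueError):
            bootstrap_infer(default_analysis, B=50, seed=1)

    def test_p_value_lower_bound(self, default_analysis):
        est, _ = bootstrap_infer(default_analysis, B=200, seed=2)
        assert est.p_one_sided >= 1 / 201


class TestBattery:
    def test_single_endpoint_single_row(self, default_study):
        cohort = derive_analysis(default_study).drop(columns="change")
        merged = default_study.participants[
            default_study.participants.id.isin(cohort.id)]
        table = endpoint_battery(merged, default_study.visits, B=100,
                                 seed=3, endpoints=("nsaa_total",))
        assert len(table) == 1
        assert table.iloc[0].endpoint == "nsaa_total"

    def test_unadjusted_columns_are_arithmetic_means(self, default_study):
        cohort_ids = derive_analysis(default_study)["id"]
        parts = default_study.participants[
            default_study.participants.id.isin(cohort_ids)]
        table = endpoint_battery(parts, default_study.visits, B=100,
                                 seed=3, endpoints=("walk6_distance",))
        sub = default_study.visits.query("endpoint == 'walk6_distance'")
        sub = sub[sub.id.isin(parts.id)].dropna(subset=["change"])
        t = sub.id.str.startswith("T")
        assert table.iloc[0].mean_change_treated == \
            pytest.approx(sub[t].change.mean())
        assert table.iloc[0].mean_change_external == \
            pytest.approx(sub[~t].change.mean())

    def test_order_independent_per_endpoint_streams(self, default_study):
        cohort_ids = derive_analysis(default_study)["id"]
        parts = default_study.participants[
            default_study.participants.id.isin(cohort_ids)]
        full = endpoint_battery(parts, default_study.visits, B=100, seed=4,
                                endpoints=("nsaa_total", "pfvc"))
        solo = endpoint_battery(parts, default_study.visits, B=100, seed=4,
                                endpoints=("pfvc",))
        row_full = full[full.endpoint == "pfvc"].iloc[0]
        row_solo = solo.iloc[0]
        assert row_full.se_boot == row_solo.se_boot
        assert row_full.difference == row_solo.difference


class TestAgeStrata:
    def _setup(self, default_study):
        cohort = derive_analysis(default_study)
        parts = default_study.participants[
            default_study.participants.id.isin(cohort.id)]
        fit = fit_propensity(cohort)
        wv = trim_and_renormalize(
            att_weights(fit, cohort.set_index("id")["arm"]))
        return parts, default_study.visits, wv

    def test_strata_partition_counts(self, default_study):
        parts, visits, wv = self._setup(default_study)
        table = age_stratified_changes(
            parts, visits, wv, strata=((4.0, 7.0), (8.0, 12.0)))
        n_total = table.n_treated.sum()
        treated = parts[parts.arm != "external"]
        assert n_total == len(treated)

    def test_empty_stratum_row(self, default_study):
        parts, visits, wv = self._setup(default_study)
        table = age_stratified_changes(
            parts, visits, wv, strata=((0.0, 1.0), (4.0, 12.0)))
        empty = table.iloc[0]
        assert empty.n_treated == 0 and np.isnan(empty.mean_change_treated)

    def test_age_gradient_matches_generator(self):
        # the generator makes older boys decline faster
        # (negative age coefficient), so young-stratum changes exceed old
        means_young, means_old = [], []
        for r in range(40):
            study = generate_study(SimConfig(
                seed=70_000 + r, n_treated=60, include_items=False,
                include_biopsies=False))
            cohort = derive_analysis(study)
            parts = study.participants[
                study.participants.id.isin(cohort.id)]
            fit = fit_propensity(cohort)
            wv = trim_and_renormalize(
                att_weights(fit, cohort.set_index("id")["arm"]))
            table = age_stratified_changes(parts, study.visits, wv)
            means_young.append(table.iloc[0].mean_change_treated)
            means_old.append(table.iloc[1].mean_change_treated)
        assert np.nanmean(means_young) > np.nanmean(means_old)
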