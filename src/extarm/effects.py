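"""Treatment-effect estimation with bootstrap inference.

Point estimators
----------------
* ``iptw_estimate`` — weighted least squares of the 1-year change on a
  treatment indicator using the trimmed, renormalized IPTW-ATT weights.
  The least-squares means are exactly the weighted mean changes per arm,
  and the difference is treated minus external.
* ``aipw_estimate`` — doubly robust augmentation: the same weighted
  regression with the four propensity-score covariates added; the
  treatment coefficient is the adjusted difference.  Consistent when
  either the propensity model or the outcome regression is correct.

Inference
---------
``bootstrap_infer`` draws stratified resamples (with replacement within
each arm, arm sizes fixed) and re-runs the entire design per replicate —
propensity fit, ATT weights, trimming/renormalization, estimator — so the
standard error propagates design-stage uncertainty.  It reports the
bootstrap s.e., the bias-corrected (BC) percentile 95% CI and a one-sided
empirical p-value computed on the null-centered bootstrap distribution,
lower-bounded by 1/(B+1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import PS_COVARIATES, ENDPOINTS
from .weighting import (SeparationError, WeightVector, att_weights,
                        fit_propensity, trim_and_renormalize)

__all__ = [
    "EffectEstimate",
    "BootstrapResult",
    "iptw_estimate",
    "aipw_estimate",
    "bootstrap_infer",
    "endpoint_battery",
    "age_stratified_changes",
]

_BOOT_RETRY_FACTOR = 20


@dataclass
class EffectEstimate:
    ls_mean_treated: float
    ls_mean_external: float
    difference: float
    method: str                    # "iptw" | "aipw"
    se_boot: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_one_sided: float | None = None
    B: int | None = None
    seed: int | None = None


@dataclass
class BootstrapResult:
    estimates: np.ndarray          # B replicate differences
    bias_correction_z0: float
    percentiles: tuple[float, float]
    n_redrawn: int = 0


def _check_weights(weights: WeightVector) -> None:
    if weights.stage != "renormalized":
        raise ValueError("expected renormalized weights")
    if not np.all(weights.w.to_numpy() >= 0):
        raise ValueError("negative weights")


def _arm_masks(weights: WeightVector) -> tuple[np.ndarray, np.ndarray]:
    t = (weights.arm == "treated").to_numpy()
    if not t.any() or t.all():
        raise ValueError("both arms required")
    return t, ~t


def iptw_estimate(changes: pd.Series, weights: WeightVector
                  ) -> EffectEstimate:
    """IPTW-ATT difference of weighted mean changes (treated - external).

    Equivalent to weighted least squares of the change on a treatment
    indicator; the LS means are the per-arm weighted means and are
    invariant to rescaling the weights within an arm.
    """
    _check_weights(weights)
    t, e = _arm_masks(weights)
    y = changes.loc[weights.w.index].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("changes must be complete (complete-case analysis)")
    w = weights.w.to_numpy()
    if w[t].sum() == 0 or w[e].sum() == 0:
        raise ValueError("all-zero weights in one arm")
    mean_t = float(np.average(y[t], weights=w[t]))
    mean_e = float(np.average(y[e], weights=w[e]))
    return EffectEstimate(ls_mean_treated=mean_t, ls_mean_external=mean_e,
                          difference=mean_t - mean_e, method="iptw")


def aipw_estimate(changes: pd.Series, weights: WeightVector,
                  covariates: pd.DataFrame) -> EffectEstimate:
    """Doubly robust adjusted difference via weighted outcome regression.

    Fits WLS of the change on [1, treatment, covariates] with the
    IPTW-ATT weights; the treatment coefficient is the doubly robust
    difference.  Constant covariates are dropped (the estimate then
    coincides with :func:`iptw_estimate`); genuinely collinear covariates
    raise a ``ValueError`` naming the dependency.
    """
    _check_weights(weights)
    t, e = _arm_masks(weights)
    idx = weights.w.index
    y = changes.loc[idx].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("changes must be complete (complete-case analysis)")
    X = covariates.loc[idx].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("covariates must be complete")
    names = list(covariates.columns)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    Xk = X[:, keep]
    design = np.column_stack([np.ones(len(y)), t.astype(float), Xk])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # locate a covariate linearly dependent on the preceding columns
        for j in range(Xk.shape[1]):
            sub = np.column_stack(
                [np.ones(len(y)), t.astype(float), Xk[:, :j + 1]])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise ValueError(
                    f"collinear covariate {names[keep[j]]!r}: linearly "
                    "dependent on intercept/treatment/preceding covariates")
        raise ValueError("collinear design")
    w = weights.w.to_numpy()
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    diff = float(beta[1])
    # LS means evaluated at the weighted treated covariate profile (ATT)
    xbar_t = np.average(Xk[t], axis=0, weights=w[t]) if Xk.shape[1] else \
        np.empty(0)
    base = float(beta[0] + xbar_t @ beta[2:])
    return EffectEstimate(ls_mean_treated=base + diff, ls_mean_external=base,
                          difference=diff, method="aipw")


def _estimate_once(frame: pd.DataFrame, estimator: str,
                   trim_quantile: float,
                   covariates: tuple[str, ...]) -> float:
    psfit = fit_propensity(frame, covariates)
    wv = trim_and_renormalize(att_weights(psfit, frame.set_index("id")["arm"]),
                              trim_quantile)
    changes = frame.set_index("id")["change"]
    if estimator == "iptw":
        return iptw_estimate(changes, wv).difference
    if estimator == "aipw":
        cov = frame.set_index("id")[list(covariates)]
        return aipw_estimate(changes, wv, cov).difference
    raise ValueError(f"unknown estimator {estimator!r}")


def _replicate_diff(X: np.ndarray, t: np.ndarray, y: np.ndarray,
                    estimator: str, trim_quantile: float) -> float:
    """Array-form replicate of the full pipeline (PS fit -> ATT weights ->
    trim/renormalize -> estimator), mathematically identical to
    :func:`_estimate_once` but without per-replicate frame construction.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)

    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    design = np.column_stack([np.ones(len(t)), X[:, keep]])
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation surfaces as degenerate fitted probabilities below
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(t, design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0,
                warn_convergence=False)
            p = np.asarray(res.predict(design))
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    eps = 1e-10
    if (p <= eps).any() or (p >= 1 - eps).any():
        raise SeparationError("degenerate propensity scores")
    w = np.where(t == 1.0, 1.0, p / (1.0 - p))
    ext = w[t == 0.0]
    cap = np.quantile(ext, trim_quantile)
    wext = np.minimum(ext, cap)
    wext = wext / wext.sum()
    w = w.copy()
    w[t == 0.0] = wext
    if estimator == "iptw":
        return float(np.average(y[t == 1.0], weights=w[t == 1.0])
                     - np.average(y[t == 0.0], weights=w[t == 0.0]))
    design_o = np.column_stack([np.ones(len(y)), t, X[:, keep]])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design_o * sw[:, None], y * sw, rcond=None)
    return float(beta[1])


def _point_estimate(frame: pd.DataFrame, estimator: str,
                    trim_quantile: float,
                    covariates: tuple[str, ...]) -> EffectEstimate:
    psfit = fit_propensity(frame, covariates)
    wv = trim_and_renormalize(att_weights(psfit, frame.set_index("id")["arm"]),
                              trim_quantile)
    changes = frame.set_index("id")["change"]
    if estimator == "iptw":
        return iptw_estimate(changes, wv)
    cov = frame.set_index("id")[list(covariates)]
    return aipw_estimate(changes, wv, cov)


def bootstrap_infer(analysis: pd.DataFrame, *, B: int = 2000,
                    seed: int = 0, estimator: str = "iptw",
                    trim_quantile: float = 0.95,
                    covariates: tuple[str, ...] = PS_COVARIATES,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[EffectEstimate, BootstrapResult]:
    """Stratified bootstrap of the full weighting-and-estimation pipeline.

    ``analysis`` holds one row per participant with columns ``id``,
    ``arm``, ``change`` and the four propensity covariates.  Each of the
    ``B`` replicates resamples with replacement *within* each arm (arm
    sizes fixed), refits the propensity model, recomputes trimmed
    renormalized weights and re-applies the estimator.  Replicates whose
    propensity fit degenerates (separation) are redrawn, up to
    ``20 * B`` total attempts.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if estimator not in ("iptw", "aipw"):
        raise ValueError(f"unknown estimator {estimator!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    est = _point_estimate(analysis, estimator, trim_quantile, covariates)
    observed = est.difference

    t_idx = np.flatnonzero(analysis["arm"].astype(str) != "external")
    e_idx = np.flatnonzero(analysis["arm"].astype(str) == "external")
    X_all = analysis[list(covariates)].to_numpy(dtype=float)
    y_all = analysis["change"].to_numpy(dtype=float)
    t_all = (analysis["arm"].astype(str) != "external").to_numpy(float)
    boots = np.empty(B)
    attempts = 0
    n_redrawn = 0
    filled = 0
    max_attempts = _BOOT_RETRY_FACTOR * B
    while filled < B:
        if attempts >= max_attempts:
            raise RuntimeError(
                "bootstrap retry cap exceeded: propensity fit degenerates "
                "in too many replicates")
        attempts += 1
        take = np.concatenate([
            rng.choice(t_idx, size=len(t_idx), replace=True),
            rng.choice(e_idx, size=len(e_idx), replace=True)])
        try:
            boots[filled] = _replicate_diff(
                X_all[take], t_all[take], y_all[take], estimator,
                trim_quantile)
        except SeparationError:
            n_redrawn += 1
            continue
        filled += 1

    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        result = BootstrapResult(boots, 0.0, (0.025, 0.975), n_redrawn)
        est.se_boot, est.ci_low, est.ci_high = 0.0, observed, observed
        est.p_one_sided = 1.0 if observed <= 0 else 1.0 / (B + 1)
        est.B, est.seed = B, seed
        return est, result

    # bias-corrected percentile interval
    prop_below = np.mean(boots < observed)
    prop_below = min(max(prop_below, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = float(stats.norm.ppf(prop_below))
    z_lo, z_hi = stats.norm.ppf([0.025, 0.975])
    a1 = float(stats.norm.cdf(2 * z0 + z_lo))
    a2 = float(stats.norm.cdf(2 * z0 + z_hi))
    ci_low, ci_high = np.quantile(boots, [a1, a2])

    centered = boots - boots.mean()
    p = float(np.mean(centered >= observed))
    p = max(p, 1.0 / (B + 1))

    est.se_boot, est.ci_low, est.ci_high = se, float(ci_low), float(ci_high)
    est.p_one_sided, est.B, est.seed = p, B, seed
    return est, BootstrapResult(boots, z0, (a1, a2), n_redrawn)


def _endpoint_seed(seed: int, endpoint: str) -> np.random.Generator:
    # counter-based stream: per-endpoint results independent of battery order
    return np.random.default_rng(
        [seed, zlib.crc32(endpoint.encode()) & 0x7FFFFFFF])


def endpoint_battery(participants: pd.DataFrame, visits: pd.DataFrame,
                     *, B: int = 2000, seed: int = 0,
                     estimator: str = "iptw",
                     trim_quantile: float = 0.95,
                     endpoints: tuple[str, ...] = ENDPOINTS
                     ) -> pd.DataFrame:
    """One bootstrap-inferred effect estimate per functional endpoint.

    Mirrors a trial results table: per arm the unadjusted mean +/- s.d.
    and median change, then the IPTW-ATT least-squares means, difference,
    bias-corrected 95% CI and one-sided p-value.  Complete-case per
    endpoint.  Each endpoint draws from its own seed-derived stream.
    """
    rows = []
    base_cols = ["id", "arm", *PS_COVARIATES]
    for endpoint in endpoints:
        sub = visits[visits["endpoint"] == endpoint]
        if sub.empty:
            continue
        merged = participants[base_cols].merge(
            sub[["id", "change"]], on="id", how="inner")
        merged = merged.dropna(subset=["change", *PS_COVARIATES])
        t = merged["arm"].astype(str) != "external"
        raw_t, raw_e = merged.loc[t, "change"], merged.loc[~t, "change"]
        est, _ = bootstrap_infer(
            merged, B=B, seed=seed, estimator=estimator,
            trim_quantile=trim_quantile,
            rng=_endpoint_seed(seed, endpoint))
        rows.append({
            "endpoint": endpoint,
            "n_treated": int(t.sum()),
            "n_external": int((~t).sum()),
            "mean_change_treated": raw_t.mean(),
            "sd_change_treated": raw_t.std(ddof=1),
            "median_change_treated": raw_t.median(),
            "mean_change_external": raw_e.mean(),
            "sd_change_external": raw_e.std(ddof=1),
            "median_change_external": raw_e.median(),
            "ls_mean_treated": est.ls_mean_treated,
            "ls_mean_external": est.ls_mean_external,
            "difference": est.difference,
            "se_boot": est.se_boot,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "p_one_sided": est.p_one_sided,
            "method": est.method,
            "B": B,
            "seed": seed,
        })
    return pd.DataFrame(rows)


def age_stratified_changes(participants: pd.DataFrame, visits: pd.DataFrame,
                           weights: WeightVector,
                           strata: tuple[tuple[float, float], ...] = (
                               (6.0, 7.0), (8.0, 12.0)),
                           endpoint: str = "nsaa_total") -> pd.DataFrame:
    """Per-age-stratum treated change statistics and weighted differences.

    For each ``[lo, hi]`` age stratum (inclusive; ages are truncated to
    whole years before comparison): treated n, mean and s.d. of the
    change, plus the stratum-restricted weighted treated-minus-external
    difference using the supplied renormalized weights.  Empty strata
    yield n = 0 rows with missing statistics.
    """
    _check_weights(weights)
    sub = visits[visits["endpoint"] == endpoint][["id", "change"]]
    frame = participants.merge(sub, on="id", how="inner")
    frame = frame.dropna(subset=["change"])
    frame = frame.set_index("id")
    age_years = np.floor(frame["age_screening"].to_numpy(dtype=float))
    t = frame["arm"].astype(str) != "external"
    rows = []
    for lo, hi in strata:
        in_stratum = (age_years >= lo) & (age_years <= hi)
        tr = frame[in_stratum & t.to_numpy()]
        ex = frame[in_stratum & ~t.to_numpy()]
        row = {"stratum": f"{lo:g}-{hi:g}", "n_treated": len(tr),
               "n_external": len(ex),
               "mean_change_treated": np.nan, "sd_change_treated": np.nan,
               "weighted_difference": np.nan}
        if len(tr) > 0:
            row["mean_change_treated"] = float(tr["change"].mean())
            row["sd_change_treated"] = float(tr["change"].std(ddof=1)) \
                if len(tr) > 1 else np.nan
        if len(tr) > 0 and len(ex) > 0:
            w = weights.w
            wt = w.loc[tr.index].to_numpy()
            we = w.loc[ex.index].to_numpy()
            row["weighted_difference"] = float(
                np.average(tr["change"], weights=wt)
                - np.average(ex["change"], weights=we))
        rows.append(row)
    return pd.DataFrame(rows)
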