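"""Propensity-score IPTW-ATT weighting and balance diagnostics.

The propensity score ``P_i`` is the probability of being in the treated
arm conditional on four prespecified baseline covariates (screening age,
NSAA total score, rise-from-floor velocity, 10-m run/walk velocity),
estimated by maximum-likelihood logistic regression with linear terms
only.  Weights target the average treatment effect among the treated
(ATT): treated participants receive weight 1 and external controls the
odds ``P_i / (1 - P_i)``.  External weights above their 95th percentile
are capped at that percentile and then renormalized to sum to one; all
downstream estimators use weighted means, so the renormalization scale is
cosmetic but fixed for reproducibility.

Covariate balance is summarized with standardized mean differences (SMD):
the (weighted) between-arm mean difference divided by the pooled
*unweighted* standard deviation, so the weighted and unweighted columns
share a denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from .simulate import PS_COVARIATES

__all__ = [
    "PSFit",
    "WeightVector",
    "SeparationError",
    "fit_propensity",
    "att_weights",
    "trim_and_renormalize",
    "balance_table",
]

_FIT_TOL = 1e-8
_MAX_ITER = 100


class SeparationError(RuntimeError):
    """Raised when the treated/external arms are (near-)separable."""


@dataclass
class PSFit:
    coefficients: pd.Series        # intercept first, then covariates
    fitted_p: pd.Series            # P_i per participant, indexed by id
    covariate_names: tuple[str, ...]
    converged: bool
    n_iter: int


@dataclass
class WeightVector:
    w: pd.Series                   # per-participant weight, indexed by id
    arm: pd.Series                 # "treated" / "external"
    trim_cap: float | None = None
    stage: str = "raw"             # raw | renormalized

    def external(self) -> pd.Series:
        return self.w[self.arm == "external"]

    def treated(self) -> pd.Series:
        return self.w[self.arm == "treated"]


def _treatment_indicator(arm: pd.Series) -> np.ndarray:
    return (arm.astype(str) != "external").to_numpy().astype(float)


def _find_separating_covariate(X: pd.DataFrame, t: np.ndarray) -> str | None:
    for name in X.columns:
        a, b = X[name][t == 1], X[name][t == 0]
        if a.min() > b.max() or b.min() > a.max():
            return name
    return None


def fit_propensity(cohort: pd.DataFrame,
                   covariates: tuple[str, ...] = PS_COVARIATES) -> PSFit:
    """Maximum-likelihood logistic propensity model with linear terms.

    ``cohort`` needs an ``id`` column, an ``arm`` column (any non-
    ``"external"`` value counts as treated) and complete values for the
    four covariates.  Raises :class:`SeparationError` naming the
    offending covariate under perfect separation, and ``ValueError``
    listing ids with missing covariates.
    """
    t = _treatment_indicator(cohort["arm"])
    if t.all() or not t.any():
        raise ValueError("cohort must contain both arms")
    X = cohort[list(covariates)].astype(float)
    missing = X.isna().any(axis=1)
    if missing.any():
        ids = cohort.loc[missing, "id"].tolist()
        raise ValueError(f"missing covariate values for ids: {ids}")
    # constant covariates carry no information; drop them so the fit
    # degenerates gracefully to (at the limit) an intercept-only model
    active = [c for c in covariates if np.ptp(X[c].to_numpy()) > 0]
    design = sm.add_constant(X[active].to_numpy(), has_constant="add") \
        if active else np.ones((len(X), 1))
    model = sm.Logit(t, design)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected from degenerate fitted P_i below
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(method="newton", maxiter=_MAX_ITER, tol=_FIT_TOL,
                            disp=0, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        culprit = _find_separating_covariate(X, t)
        raise SeparationError(
            "singular design or perfect separation"
            + (f"; separating covariate {culprit!r}" if culprit else "")
        ) from exc
    p = np.asarray(res.predict(design))
    eps = 1e-10
    if (p <= eps).any() or (p >= 1 - eps).any():
        culprit = _find_separating_covariate(X, t)
        raise SeparationError(
            "fitted propensity scores degenerate at 0 or 1"
            + (f"; separating covariate {culprit!r}" if culprit else ""))
    coef = pd.Series(0.0, index=["intercept", *covariates])
    coef[["intercept", *active]] = res.params
    return PSFit(
        coefficients=coef,
        fitted_p=pd.Series(p, index=cohort["id"].to_numpy(), name="Pi"),
        covariate_names=tuple(covariates),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", 0)),
    )


def att_weights(psfit: PSFit, arm: pd.Series) -> WeightVector:
    """ATT weights: treated -> 1, external -> odds ``P_i / (1 - P_i)``."""
    p = psfit.fitted_p.to_numpy()
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    t = _treatment_indicator(arm)
    w = np.where(t == 1.0, 1.0, p / (1.0 - p))
    arm_std = pd.Series(np.where(t == 1.0, "treated", "external"),
                        index=psfit.fitted_p.index, name="arm")
    return WeightVector(
        w=pd.Series(w, index=psfit.fitted_p.index, name="w"),
        arm=arm_std, stage="raw")


def trim_and_renormalize(weights: WeightVector,
                         quantile: float = 0.95) -> WeightVector:
    """Cap external weights at their ``quantile`` and renormalize to sum 1.

    The cap is the linear-interpolation quantile of the external weights.
    Treated weights stay at 1.  Requires a raw-stage input.
    """
    if weights.stage != "raw":
        raise ValueError("expected raw-stage weights")
    ext = weights.external()
    if len(ext) == 0:
        raise ValueError("empty external arm")
    cap = float(np.quantile(ext.to_numpy(), quantile))
    trimmed = np.minimum(ext.to_numpy(), cap)
    renorm = trimmed / trimmed.sum()
    w = weights.w.copy()
    w[weights.arm == "external"] = renorm
    return replace(weights, w=w, trim_cap=cap, stage="renormalized")


def _smd(x: np.ndarray, t: np.ndarray, w: np.ndarray) -> float:
    """Weighted SMD with a pooled unweighted-s.d. denominator."""
    xt, xe = x[t == 1], x[t == 0]
    wt, we = w[t == 1], w[t == 0]
    mean_t = np.average(xt, weights=wt)
    mean_e = np.average(xe, weights=we)
    var_t = np.var(xt, ddof=1) if len(xt) > 1 else 0.0
    var_e = np.var(xe, ddof=1) if len(xe) > 1 else 0.0
    pooled = np.sqrt((var_t + var_e) / 2.0)
    diff = mean_t - mean_e
    if pooled == 0.0:
        if np.isclose(diff, 0.0):
            return 0.0
        raise ValueError("zero pooled s.d. with unequal means")
    return diff / pooled


def balance_table(cohort: pd.DataFrame, weights: WeightVector,
                  covariates: tuple[str, ...] = PS_COVARIATES
                  ) -> pd.DataFrame:
    """Unweighted and weighted SMD per covariate.

    Returns a DataFrame indexed by covariate with columns
    ``smd_unweighted`` and ``smd_weighted``; ``.attrs["max_abs_smd"]``
    carries the per-column maxima of ``|SMD|``.
    """
    if weights.stage != "renormalized":
        raise ValueError("expected renormalized weights")
    t = (weights.arm == "treated").to_numpy().astype(float)
    w = weights.w.to_numpy()
    ones = np.ones_like(w)
    rows = {}
    indexed = cohort.set_index("id")
    for name in covariates:
        x = indexed.loc[weights.w.index, name].to_numpy(dtype=float)
        rows[name] = {
            "smd_unweighted": _smd(x, t, ones),
            "smd_weighted": _smd(x, t, w),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.attrs["max_abs_smd"] = {
        col: float(table[col].abs().max()) for col in table.columns}
    return table
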