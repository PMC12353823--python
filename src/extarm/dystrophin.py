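"""Dystrophin / mini-dystrophin expression quantification.

Immunofluorescence arm: each biopsy section yields a table of per-fiber
mean stain density (MSD) values.  A single global positivity threshold is
the 99th percentile of the pooled baseline MSD distribution across all
participants and sections; any fiber with MSD strictly above the
threshold is positive.  Percent-positive values are computed per section
and averaged over the (up to) two sections of a biopsy.

LC-MS arm: per-biopsy dystrophin concentrations (fmol per mg total
protein) are normalized to the mean of non-dystrophic control tissue;
values below the assay's lower limit of quantification (LLOQ) are imputed
at half the LLOQ before normalization.

Cohort summaries average the per-participant percentages (not pooled
fibers) and attach a two-sided 95% t-interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdModel",
    "fit_threshold",
    "pct_positive",
    "average_sections",
    "lcms_percent_normal",
    "expression_summary",
]


@dataclass
class ThresholdModel:
    threshold: float
    source_n_fibers: int
    source_n_participants: int
    quantile: float = 0.99
    quantile_method: str = "linear"


def fit_threshold(baseline_fibers: pd.DataFrame) -> ThresholdModel:
    """Global positivity threshold from pooled baseline MSD values.

    The threshold is the linear-interpolation 99th percentile of all
    baseline fibers, pooled across participants and sections.  Warns
    below 100 fibers; errors on an empty table.
    """
    msd = baseline_fibers["msd"].to_numpy(dtype=float)
    if len(msd) == 0:
        raise ValueError("no baseline fibers")
    if (msd <= 0).any():
        raise ValueError("MSD values must be positive")
    if len(msd) < 100:
        warnings.warn(
            f"only {len(msd)} baseline fibers; the 99th percentile is "
            "poorly determined", stacklevel=2)
    return ThresholdModel(
        threshold=float(np.quantile(msd, 0.99)),
        source_n_fibers=len(msd),
        source_n_participants=baseline_fibers["participant_id"].nunique(),
    )


def pct_positive(fibers: pd.DataFrame, model: ThresholdModel
                 ) -> pd.DataFrame:
    """Percent of fibers strictly above the threshold, per section.

    Returns one row per (participant, visit, section) with the fiber
    count and the positive percentage; ties at the threshold count as
    negative.
    """
    if fibers.empty:
        raise ValueError("empty fiber table")
    grouped = fibers.groupby(["participant_id", "visit", "section"],
                             sort=True)
    rows = []
    for (pid, visit, section), grp in grouped:
        msd = grp["msd"].to_numpy(dtype=float)
        rows.append({
            "participant_id": pid, "visit": visit, "section": section,
            "n_fibers": len(msd),
            "pct_positive": 100.0 * float(np.mean(msd > model.threshold)),
        })
    return pd.DataFrame(rows)


def average_sections(per_section: pd.DataFrame) -> pd.DataFrame:
    """Average section percentages into one value per biopsy.

    One or two sections per (participant, visit); single-section biopsies
    pass through flagged.  More than two sections is an error.
    """
    rows = []
    for (pid, visit), grp in per_section.groupby(
            ["participant_id", "visit"], sort=True):
        if len(grp) > 2:
            raise ValueError(
                f"more than two sections for {pid!r} at {visit!r}")
        rows.append({
            "participant_id": pid, "visit": visit,
            "n_sections": len(grp),
            "pct_positive_mean": float(grp["pct_positive"].mean()),
            "single_section": len(grp) == 1,
        })
    return pd.DataFrame(rows)


def lcms_percent_normal(conc, control_mean: float, lloq: float
                        ) -> pd.DataFrame:
    """Percent-of-normal dystrophin from LC-MS concentrations.

    Concentrations below ``lloq`` are imputed at ``0.5 * lloq`` before
    dividing by the control-tissue mean.  Returns imputed concentration,
    percent of normal and an imputation flag per input value.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    if lloq < 0:
        raise ValueError("lloq must be nonnegative")
    c = np.asarray(conc, dtype=float)
    if (c < 0).any():
        raise ValueError("negative concentration")
    imputed_flag = c < lloq
    imputed = np.where(imputed_flag, 0.5 * lloq, c)
    return pd.DataFrame({
        "conc": c,
        "imputed_conc": imputed,
        "pct_normal": 100.0 * imputed / control_mean,
        "lloq_imputed": imputed_flag,
    })


def expression_summary(values, confidence: float = 0.95,
                       log_scale: bool = False) -> dict:
    """Mean and two-sided t-interval over per-participant values.

    With ``log_scale=True`` the interval is formed on log-transformed
    values and back-transformed (an asymmetric interval about the
    geometric mean); values must then be positive.  With n < 2 the mean
    is returned and the interval is missing.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n == 0:
        raise ValueError("no values")
    out = {"n": n, "mean": float(v.mean()), "ci_low": None, "ci_high": None}
    if n < 2:
        return out
    if log_scale:
        if (v <= 0).any():
            raise ValueError("log-scale summary requires positive values")
        lv = np.log(v)
        half = stats.t.ppf(0.5 + confidence / 2, n - 1) * lv.std(ddof=1) \
            / np.sqrt(n)
        out["ci_low"] = float(np.exp(lv.mean() - half))
        out["ci_high"] = float(np.exp(lv.mean() + half))
    else:
        half = stats.t.ppf(0.5 + confidence / 2, n - 1) * v.std(ddof=1) \
            / np.sqrt(n)
        out["ci_low"] = float(v.mean() - half)
        out["ci_high"] = float(v.mean() + half)
    return out
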