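"""External-control cohort selection.

Applies the eligibility rules used to derive an external control cohort
from a pool of placebo participants of prior trials: age 4-12 years at
screening (inclusive), independent ambulation established from NSAA items,
rise from the floor within 7 s, LVEF of at least 55% where cardiac data
exist ("data permitting"), a stable steroid regimen for at least 6 months
at screening, and nonmissing NSAA total scores at baseline and 1 year.
Missing steroid start dates are imputed as 6 calendar months before the
screening day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionReport",
    "impute_steroid_start",
    "is_ambulatory_by_nsaa",
    "apply_eligibility",
    "RULES",
]

#: Selection rules, in the order they are reported.
RULES = ("age_4_12", "ambulatory", "rise_7s", "lvef_55", "steroid_6mo",
         "nsaa_baseline", "nsaa_year1")


@dataclass
class SelectionReport:
    """Per-participant rule flags and aggregate exclusion tallies."""

    flags: pd.DataFrame            # index: id; columns: RULES + "selected"
    n_in: int
    n_selected: int
    exclusions: dict = field(default_factory=dict)  # rule -> n failing

    def __post_init__(self):
        assert self.n_selected <= self.n_in


def impute_steroid_start(participants: pd.DataFrame) -> pd.DataFrame:
    """Fill missing steroid start dates as 6 calendar months pre-screening.

    Dates are ISO-8601 strings or timestamps; month arithmetic clamps the
    day of month (e.g. 2020-08-31 maps to 2020-02-29).  Adds a boolean
    ``steroid_start_imputed`` column; present values are untouched.
    """
    out = participants.copy()
    screening = pd.to_datetime(out["screening_date"])
    if screening.isna().any():
        bad = out.loc[screening.isna(), "id"].tolist()
        raise ValueError(f"missing screening_date for: {bad}")
    steroid = pd.to_datetime(out.get("steroid_start"))
    missing = steroid.isna()
    imputed = screening - pd.DateOffset(months=6)
    steroid = steroid.where(~missing, imputed)
    out["steroid_start"] = steroid.dt.strftime("%Y-%m-%d")
    out["steroid_start_imputed"] = missing.to_numpy()
    return out


def is_ambulatory_by_nsaa(items: np.ndarray | pd.Series,
                          literal: bool = False) -> bool:
    """Independent ambulation from a 17-item NSAA vector.

    Ambulation holds when item 17 (10-m run/walk) scores 1 or 2; when item
    17 is missing, a score of 1 or 2 on item 2 (walk) rescues the
    participant.  Under ``literal=True`` any *observed* item-17 score
    (including 0) also qualifies, matching a literal transcription of the
    rule; the default charitable reading treats an observed 0 as
    non-ambulatory.
    """
    v = np.asarray(items, dtype=float)
    if v.shape[-1] != 17:
        raise ValueError("expected 17 NSAA item scores")
    item17, item2 = v[16], v[1]
    if np.isfinite(item17):
        if item17 in (1.0, 2.0):
            return True
        return bool(literal)  # observed 0
    # item 17 missing: fall back to walking item
    if np.isfinite(item2) and item2 in (1.0, 2.0):
        return True
    return False


def _months_between(later: pd.Series, earlier: pd.Series) -> pd.Series:
    """Whole calendar months from ``earlier`` to ``later`` (vectorized)."""
    later = pd.to_datetime(later)
    earlier = pd.to_datetime(earlier)
    months = ((later.dt.year - earlier.dt.year) * 12
              + (later.dt.month - earlier.dt.month))
    # not yet reached the day-of-month anniversary -> one month fewer
    months -= (later.dt.day < earlier.dt.day).astype(int)
    return months


def apply_eligibility(pool: pd.DataFrame,
                      items: pd.DataFrame | None = None,
                      *,
                      literal_ambulation: bool = False,
                      lvef_inclusive: bool = True,
                      age_range: tuple[float, float] = (4.0, 12.0),
                      rise_time_max: float = 7.0,
                      lvef_min: float = 55.0,
                      steroid_months_min: int = 6,
                      ) -> tuple[pd.DataFrame, SelectionReport]:
    """Select the external control cohort from the placebo pool.

    Parameters
    ----------
    pool : DataFrame
        Participant records (steroid imputation already applied when
        start dates can be missing).
    items : DataFrame, optional
        NSAA item table (columns ``id``, ``visit``, ``item_1..item_17``);
        when absent the ambulation rule falls back to a nonmissing,
        positive 10-m run/walk velocity.
    lvef_inclusive : bool
        Whether the LVEF boundary is ``>= 55`` (default) or strictly
        ``> 55``.  Missing LVEF never excludes ("data permitting").

    Returns the selected cohort and a :class:`SelectionReport` with
    per-rule flags and exclusion tallies.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    pool = pool.reset_index(drop=True)
    flags = pd.DataFrame(index=pool["id"])

    age = pool["age_screening"].to_numpy(dtype=float)
    flags["age_4_12"] = (age >= age_range[0]) & (age <= age_range[1])

    if items is not None and len(items) > 0:
        cols = [f"item_{k}" for k in range(1, 18)]
        base_items = items[items["visit"] == "baseline"] \
            .drop_duplicates("id").set_index("id")[cols] \
            .reindex(pool["id"]).to_numpy(dtype=float)
        item17 = base_items[:, 16]
        item2 = base_items[:, 1]
        obs17 = np.isfinite(item17)
        amb = (obs17 & np.isin(item17, (1.0, 2.0))
               | (~obs17 & np.isin(item2, (1.0, 2.0))))
        if literal_ambulation:
            amb |= obs17  # any observed item-17 score qualifies
        flags["ambulatory"] = amb
    else:
        v = pool.get("run10_velocity")
        flags["ambulatory"] = (v.notna() & (v > 0)).to_numpy() \
            if v is not None else True

    rise_t = pool.get("rise_time")
    rise_v = pool.get("rise_velocity")
    if rise_t is not None:
        ok_time = rise_t.notna() & (rise_t <= rise_time_max)
    else:
        ok_time = pd.Series(False, index=pool.index)
    if rise_v is not None:
        ok_vel = rise_t.isna() if rise_t is not None else True
        ok_vel = ok_vel & rise_v.notna() & (rise_v >= 1.0 / rise_time_max)
    else:
        ok_vel = pd.Series(False, index=pool.index)
    flags["rise_7s"] = (ok_time | ok_vel).to_numpy()

    lvef = pool.get("lvef")
    if lvef is None:
        flags["lvef_55"] = True
    else:
        ok = lvef >= lvef_min if lvef_inclusive else lvef > lvef_min
        flags["lvef_55"] = (lvef.isna() | ok).to_numpy()  # data permitting

    steroid = pd.to_datetime(pool["steroid_start"])
    screening = pd.to_datetime(pool["screening_date"])
    months = _months_between(screening, steroid)
    flags["steroid_6mo"] = (steroid.notna()
                            & (months >= steroid_months_min)).to_numpy()

    flags["nsaa_baseline"] = pool["nsaa_total_baseline"].notna().to_numpy()
    flags["nsaa_year1"] = pool["nsaa_total_year1"].notna().to_numpy()

    flags["selected"] = flags[list(RULES)].all(axis=1)
    selected_ids = flags.index[flags["selected"]]
    cohort = pool[pool["id"].isin(selected_ids)].reset_index(drop=True)
    report = SelectionReport(
        flags=flags,
        n_in=len(pool),
        n_selected=int(flags["selected"].sum()),
        exclusions={r: int((~flags[r]).sum()) for r in RULES},
    )
    return cohort, report
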