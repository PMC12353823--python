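"""Item-level North Star Ambulatory Assessment (NSAA) analytics.

The NSAA scores 17 ambulatory actions 0/1/2 (total 0-34, higher = better
function).  Beyond the total, each item is treated as a skill that can be
*gained* (baseline 0, 1-year 1 or 2) or *improved-or-maintained* (same or
higher nonzero score at 1 year).  Under the default reading a 0 -> 1
transition counts as improved as well as gained, because the nonzero
requirement attaches to the 1-year score; ``strict=True`` additionally
requires a nonzero baseline.  Items missing at either visit are excluded
from the skill counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "TotalResult",
    "SkillSummary",
    "nsaa_total",
    "skills_gained",
    "skills_improved_or_maintained",
    "skill_summary",
]

ITEM_COLUMNS = tuple(f"item_{k}" for k in range(1, 18))


class TotalResult(NamedTuple):
    total: int
    n_missing: int


@dataclass
class SkillSummary:
    arm: str
    n: int
    n_with_baseline_zero: int
    n_gained_ge1: int
    pct_gained: float              # percent, over the baseline-zero subset
    median_improved_or_maintained: float
    per_participant: pd.DataFrame  # id, n_zero_baseline, gained, improved

    def __post_init__(self):
        assert self.n_gained_ge1 <= self.n_with_baseline_zero


def _validate(items: np.ndarray) -> np.ndarray:
    v = np.asarray(items, dtype=float)
    if v.ndim != 1 or len(v) > 17:
        raise ValueError("expected a vector of at most 17 item scores")
    observed = v[np.isfinite(v)]
    if not np.isin(observed, (0.0, 1.0, 2.0)).all():
        raise ValueError("item scores must be 0, 1 or 2")
    return v


def nsaa_total(items) -> TotalResult:
    """Sum of nonmissing item scores with the missing count alongside."""
    v = _validate(items)
    observed = np.isfinite(v)
    return TotalResult(int(np.nansum(v)), int((~observed).sum()))


def skills_gained(baseline, year1) -> int:
    """Items scoring 0 at baseline and 1 or 2 at 1 year (both observed)."""
    b, y = _validate(baseline), _validate(year1)
    both = np.isfinite(b) & np.isfinite(y)
    return int(np.sum(both & (b == 0) & (y >= 1)))


def skills_improved_or_maintained(baseline, year1, strict: bool = False
                                  ) -> int:
    """Items with the same or higher nonzero score at 1 year.

    Default: 1-year score nonzero and not below baseline (so 0 -> 1
    counts).  ``strict=True`` also requires a nonzero baseline score.
    """
    b, y = _validate(baseline), _validate(year1)
    both = np.isfinite(b) & np.isfinite(y)
    ok = both & (y >= 1) & (y >= b)
    if strict:
        ok &= b >= 1
    return int(np.sum(ok))


def skill_summary(items: pd.DataFrame, arms: pd.Series,
                  strict: bool = False) -> dict[str, SkillSummary]:
    """Per-arm skill statistics from an NSAA item table.

    ``items`` has columns ``id``, ``visit`` (baseline / year1) and
    ``item_1 .. item_17``; ``arms`` maps id to arm label.  Participants
    need both visits to contribute.  The gained percentage is computed
    over participants with at least one observed baseline-zero item; the
    median improved-or-maintained count is over all participants.
    """
    cols = list(ITEM_COLUMNS)
    base = items[items["visit"] == "baseline"].set_index("id")[cols]
    year1 = items[items["visit"] == "year1"].set_index("id")[cols]
    ids = base.index.intersection(year1.index)
    if len(ids) == 0:
        raise ValueError("no participants with both visits")
    records = []
    for pid in ids:
        b = base.loc[pid].to_numpy(dtype=float)
        y = year1.loc[pid].to_numpy(dtype=float)
        if not np.isfinite(y).any():
            continue  # no usable 1-year items
        n_zero = int(np.sum(np.isfinite(b) & (b == 0)))
        records.append({
            "id": pid,
            "arm": arms.loc[pid],
            "n_zero_baseline": n_zero,
            "gained": skills_gained(b, y),
            "improved_or_maintained":
                skills_improved_or_maintained(b, y, strict=strict),
            "n_missing_items": int(
                np.sum(~(np.isfinite(b) & np.isfinite(y)))),
        })
    per = pd.DataFrame(records)
    out: dict[str, SkillSummary] = {}
    for arm, grp in per.groupby("arm"):
        with_zero = grp[grp["n_zero_baseline"] >= 1]
        gained = int((with_zero["gained"] >= 1).sum())
        denom = len(with_zero)
        out[str(arm)] = SkillSummary(
            arm=str(arm),
            n=len(grp),
            n_with_baseline_zero=denom,
            n_gained_ge1=gained,
            pct_gained=100.0 * gained / denom if denom else float("nan"),
            median_improved_or_maintained=float(
                grp["improved_or_maintained"].median()),
            per_participant=grp.reset_index(drop=True),
        )
    return out
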