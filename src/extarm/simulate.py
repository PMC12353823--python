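"""Synthetic trial generator.

Produces participant-level data emulating a small single-arm gene-therapy
trial in ambulatory boys with Duchenne muscular dystrophy (DMD) together
with a pool of placebo participants from prior trials that serves as the
raw material for an external control cohort.  Every quantity is generated
from explicit, recoverable parameters so that the downstream estimators
(eligibility selection, propensity-score IPTW-ATT weighting, doubly robust
adjustment, bootstrap inference, item-level NSAA analytics and fiber-level
dystrophin quantification) can be validated against known ground truth.

The generator draws:

* four baseline covariates per participant (screening age, NSAA total
  score, rise-from-floor velocity, 10-m run/walk velocity) with a
  configurable mean shift between arms (`confounding_strength`),
* a 1-year change for each functional endpoint following a linear model
  ``change = drift + att * treated + beta @ (x - mu_ref) + noise`` (the
  covariate term applies to the NSAA total only),
* 17-item NSAA vectors whose item sums equal the generated totals,
* eligibility fields (LVEF, rise time, steroid dates, missing outcomes)
  such that a configured fraction of the pool passes selection,
* per-fiber mean stain density (MSD) tables as two-component log-normal
  mixtures, and per-biopsy LC-MS dystrophin concentrations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "FiberParams",
    "LcmsParams",
    "EligibilityParams",
    "generate_study",
    "generate_fibers",
    "worked_example_fixture",
    "PS_COVARIATES",
    "ENDPOINTS",
]

#: The four prespecified propensity-score covariates, in fixed order.
PS_COVARIATES = ("age_screening", "nsaa_total_baseline", "rise_velocity",
                 "run10_velocity")

#: Functional endpoints of the 1-year battery.
ENDPOINTS = ("nsaa_total", "rise_velocity", "run10_velocity",
             "stair4_velocity", "walk6_distance", "pul", "pfvc")

VISITS = ("baseline", "month2", "year1")

# Per-endpoint generating parameters for the 1-year change:
# (treated baseline mean, external baseline mean, baseline s.d.,
#  true ATT, control drift, treated noise s.d., external noise s.d.)
_ENDPOINT_PARAMS = {
    "rise_velocity":   (0.28, 0.22, 0.10, 0.07, -0.06, 0.08, 0.06),
    "run10_velocity":  (2.29, 1.96, 0.45, 0.17, -0.19, 0.32, 0.51),
    "stair4_velocity": (0.37, 0.31, 0.12, 0.02, -0.01, 0.11, 0.12),
    "walk6_distance":  (386.0, 380.0, 60.0, 17.8, -10.6, 59.9, 58.4),
    "pul":             (39.4, 37.4, 3.0, 1.2, -0.3, 2.5, 1.62),
    "pfvc":            (95.6, 107.4, 15.0, 11.0, -7.8, 11.5, 23.1),
}

# Outcome-model coefficients linking the four PS covariates to the NSAA
# 1-year change (points per covariate unit): older boys decline faster,
# better baseline velocity predicts a milder decline.
_NSAA_BETA = np.array([-0.8, 0.1, 8.0, 2.0])
# Reference covariate means (treated generating means) at which the
# covariate term is centred; centring only shifts the intercept.
_NSAA_MU_REF = np.array([8.0, 25.8, 0.28, 2.29])

# Mean shift of the pool covariates relative to the treated arm at
# confounding_strength = 1 (age, NSAA total, rise velocity, 10-m velocity).
_POOL_SHIFT = np.array([0.3, 0.2, -0.06, -0.33])

# A fixed item-difficulty ordering for the 17 NSAA items: rank 1 = easiest.
# Walking (item 2) and standing (item 1) are the easiest skills; rising
# from the floor and hopping are the hardest.  Purely ordinal.
_ITEM_DIFFICULTY_RANK = np.array(
    [2, 1, 6, 10, 13, 14, 9, 15, 16, 17, 11, 12, 7, 8, 5, 4, 3])

# Independent sub-streams of the master seed.
_STREAM_COVARIATES = 11
_STREAM_OUTCOMES = 22
_STREAM_ITEMS = 33
_STREAM_ELIGIBILITY = 44
_STREAM_FIBERS = 55
_STREAM_LCMS = 66


@dataclass
class FiberParams:
    """Two-component log-normal mixture for per-fiber MSD intensities.

    Background fibers are log-normal(background_mu, background_sigma);
    transduced (positive) fibers are log-normal(positive_mu,
    positive_sigma), located well above the background's upper tail.
    ``positive_fraction`` maps visit label to the mixing fraction.
    """

    background_mu: float = 0.0
    background_sigma: float = 0.5
    positive_mu: float = 2.5
    positive_sigma: float = 0.4
    positive_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 0.0, "month2": 0.20,
                                 "year1": 0.35})
    n_fibers_per_section: int = 800
    n_sections: int = 2

    def validate(self) -> None:
        if self.background_sigma <= 0 or self.positive_sigma <= 0:
            raise ValueError("fiber scale parameters must be positive")
        for visit, frac in self.positive_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"mixing fraction for {visit!r} outside [0, 1]: {frac}")


@dataclass
class LcmsParams:
    """LC-MS dystrophin concentration model (fmol per mg total protein)."""

    control_mean: float = 2964.0   # mean of non-dystrophic control tissue
    lloq: float = 10.0             # lower limit of quantification
    visit_mean: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 41.5, "month2": 656.7,
                                 "year1": 1192.3})
    log_sd: float = 0.45

    def validate(self) -> None:
        if self.control_mean <= 0:
            raise ValueError("control_mean must be positive")
        if self.lloq < 0:
            raise ValueError("lloq must be nonnegative")


@dataclass
class EligibilityParams:
    """Selection thresholds mirrored by the generator.

    ``pass_fraction`` is the probability that a pool participant satisfies
    every selection rule; failing participants are assigned at least one
    violated rule at random.
    """

    pass_fraction: float = 0.4
    age_range: tuple[float, float] = (4.0, 12.0)
    rise_time_max: float = 7.0
    lvef_min: float = 55.0
    steroid_months_min: int = 6

    def validate(self) -> None:
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise ValueError("pass_fraction outside [0, 1]")


@dataclass
class SimConfig:
    """Full parameterization of a synthetic study.

    Defaults describe the study conditions: 16 high-dose treated
    participants, a pool of 156 placebo participants, a true average
    treatment effect among the treated of 3.4 NSAA points over a control
    drift of -2.7 points, and arm-specific outcome noise of 4.0 / 5.3
    points (treated / external).
    """

    seed: int
    n_treated: int = 16
    n_pool: int = 156
    true_att: float = 3.4
    control_drift: float = -2.7
    noise_sd: tuple[float, float] = (4.0, 5.3)  # (treated, external)
    confounding_strength: float = 1.0
    eligibility: EligibilityParams = field(default_factory=EligibilityParams)
    fibers: FiberParams = field(default_factory=FiberParams)
    lcms: LcmsParams = field(default_factory=LcmsParams)
    missing_steroid_frac: float = 0.0
    missing_lvef_frac: float = 0.0
    screening_date: str = "2020-01-15"
    # capability switches for large simulation studies that do not touch
    # item- or fiber-level data; distributions are unaffected
    include_items: bool = True
    include_biopsies: bool = True

    def validate(self) -> None:
        if self.n_treated < 2:
            raise ValueError("n_treated must be >= 2")
        if self.n_pool < self.n_treated:
            raise ValueError("n_pool must be >= n_treated")
        if min(self.noise_sd) <= 0:
            raise ValueError("noise_sd components must be positive")
        if not 0.0 <= self.missing_steroid_frac <= 1.0:
            raise ValueError("missing_steroid_frac outside [0, 1]")
        if not 0.0 <= self.missing_lvef_frac <= 1.0:
            raise ValueError("missing_lvef_frac outside [0, 1]")
        self.eligibility.validate()
        self.fibers.validate()
        self.lcms.validate()


@dataclass
class SimulatedStudy:
    """A generated study: five tables plus the generating truth."""

    participants: pd.DataFrame
    visits: pd.DataFrame
    items: pd.DataFrame
    fibers: pd.DataFrame
    lcms: pd.DataFrame
    truth: dict

    def write_csvs(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in [("participants", self.participants),
                            ("visits", self.visits),
                            ("nsaa_items", self.items),
                            ("fibers", self.fibers),
                            ("lcms", self.lcms)]:
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        return written


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, *extra])


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _visit_code(visit: str) -> int:
    return zlib.crc32(visit.encode()) & 0x7FFFFFFF


def _allocate_items(total: int, weights: np.ndarray,
                    rng: np.random.Generator,
                    blocked: np.ndarray | None = None) -> np.ndarray:
    """Distribute an NSAA total over 17 items, scores in {0, 1, 2}.

    Each item contributes two unit "slots" carrying the item's weight
    (higher weight = easier item); ``total`` slots are drawn by weighted
    sampling without replacement (Gumbel top-k), so the returned vector
    sums exactly to ``total`` with every score in {0, 1, 2} and easy
    items filled preferentially.  ``blocked`` items stay at 0.
    """
    if not 0 <= total <= 34:
        raise ValueError(f"NSAA total outside [0, 34]: {total}")
    cap = np.full(17, 2)
    if blocked is not None:
        cap[blocked] = 0
    if total > cap.sum():
        raise ValueError("total exceeds achievable maximum given blocks")
    if total == 0:
        return np.zeros(17, dtype=int)
    slot_item = np.repeat(np.arange(17), 2)
    with np.errstate(divide="ignore"):
        keys = np.log(np.repeat(weights, 2)) + rng.gumbel(size=34)
    keys[np.repeat(cap, 2) == 0] = -np.inf
    chosen = np.argpartition(keys, -total)[-total:]
    return np.bincount(slot_item[chosen], minlength=17)


def _item_weights() -> np.ndarray:
    return np.exp(-0.15 * _ITEM_DIFFICULTY_RANK)


def _ensure_ambulatory(scores: np.ndarray) -> np.ndarray:
    """Move one point onto item 17 (10-m run/walk) if it scored 0."""
    if scores[16] >= 1 or scores.sum() == 0:
        return scores
    donor = int(np.argmax(scores))
    scores = scores.copy()
    scores[donor] -= 1
    scores[16] += 1
    return scores


def _items_frame(ids, visit, matrix) -> pd.DataFrame:
    frame = pd.DataFrame(matrix, columns=[f"item_{k}" for k in range(1, 18)])
    frame.insert(0, "visit", visit)
    frame.insert(0, "id", list(ids))
    return frame


def generate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a full synthetic study from ``config``.

    Deterministic given ``config.seed``: the same configuration always
    yields an identical :class:`SimulatedStudy`.
    """
    config.validate()
    seed = config.seed
    n_t, n_p = config.n_treated, config.n_pool
    n = n_t + n_p
    treated = np.zeros(n, dtype=bool)
    treated[:n_t] = True
    ids = [f"T{i+1:03d}" for i in range(n_t)] + \
          [f"E{i+1:03d}" for i in range(n_p)]

    # --- baseline covariates -------------------------------------------
    rng_cov = _rng(seed, _STREAM_COVARIATES)
    shift = config.confounding_strength * _POOL_SHIFT
    mu_t = _NSAA_MU_REF
    age = np.empty(n)
    age[treated] = rng_cov.uniform(4.0, 12.0, n_t)
    age[~treated] = np.clip(
        rng_cov.uniform(4.0, 12.0, n_p) + shift[0], 4.0, 12.0)
    nsaa0 = np.empty(n)
    nsaa0[treated] = _truncnorm(rng_cov, mu_t[1], 4.5, 5, 34, n_t)
    nsaa0[~treated] = _truncnorm(rng_cov, mu_t[1] + shift[1], 4.5, 5, 34, n_p)
    nsaa0 = np.round(nsaa0).astype(int)
    rise_v = np.empty(n)
    rise_v[treated] = _truncnorm(rng_cov, mu_t[2], 0.10, 0.145, 1.0, n_t)
    rise_v[~treated] = _truncnorm(rng_cov, mu_t[2] + shift[2], 0.10,
                                  0.145, 1.0, n_p)
    run10_v = np.empty(n)
    run10_v[treated] = _truncnorm(rng_cov, mu_t[3], 0.45, 0.5, 4.5, n_t)
    run10_v[~treated] = _truncnorm(rng_cov, mu_t[3] + shift[3], 0.45,
                                   0.5, 4.5, n_p)

    # --- eligibility fields --------------------------------------------
    rng_eli = _rng(seed, _STREAM_ELIGIBILITY)
    passes = np.ones(n, dtype=bool)
    passes[~treated] = rng_eli.random(n_p) < config.eligibility.pass_fraction
    fail_rules = ("rise", "lvef", "steroid", "year1_missing", "ambulation")
    fail_rule = np.array([""] * n, dtype=object)
    pool_fail = (~treated) & (~passes)
    fail_rule[pool_fail] = rng_eli.choice(fail_rules, size=pool_fail.sum())

    screening = pd.Timestamp(config.screening_date) + pd.to_timedelta(
        rng_eli.integers(0, 120, n), unit="D")
    lvef = _truncnorm(rng_eli, 62.0, 3.0, 56.0, 75.0, n)
    rise_time = 1.0 / rise_v
    steroid_months = rng_eli.uniform(7.0, 48.0, n)
    year1_missing = np.zeros(n, dtype=bool)

    bad = fail_rule == "rise"
    rise_time[bad] = rng_eli.uniform(7.5, 12.0, bad.sum())
    rise_v[bad] = 1.0 / rise_time[bad]
    bad = fail_rule == "lvef"
    lvef[bad] = _truncnorm(rng_eli, 50.0, 2.5, 40.0, 54.9, bad.sum())
    bad = fail_rule == "steroid"
    steroid_months[bad] = rng_eli.uniform(1.0, 5.5, bad.sum())
    year1_missing[fail_rule == "year1_missing"] = True

    steroid_start = screening - pd.to_timedelta(
        np.round(steroid_months * 30.4375), unit="D")
    steroid_start = pd.Series(steroid_start)
    if config.missing_steroid_frac > 0:
        drop = rng_eli.random(n) < config.missing_steroid_frac
        steroid_start[drop] = pd.NaT
    lvef = pd.Series(lvef)
    if config.missing_lvef_frac > 0:
        drop = rng_eli.random(n) < config.missing_lvef_frac
        lvef[drop] = np.nan

    # --- outcomes -------------------------------------------------------
    rng_out = _rng(seed, _STREAM_OUTCOMES)
    x = np.column_stack([age, nsaa0, rise_v, run10_v])
    sd = np.where(treated, config.noise_sd[0], config.noise_sd[1])
    change_cont = (config.control_drift
                   + config.true_att * treated
                   + (x - _NSAA_MU_REF) @ _NSAA_BETA
                   + rng_out.normal(0.0, 1.0, n) * sd)
    nsaa1 = np.clip(np.round(nsaa0 + change_cont), 0, 34).astype(int)
    nsaa1 = nsaa1.astype(float)
    nsaa1[year1_missing] = np.nan

    visit_rows = []
    for i in range(n):
        y1 = nsaa1[i]
        visit_rows.append((ids[i], "nsaa_total", float(nsaa0[i]), y1,
                           y1 - nsaa0[i] if np.isfinite(y1) else np.nan))
    baseline_map = {"rise_velocity": rise_v, "run10_velocity": run10_v}
    for ep, (b_t, b_e, b_sd, att, drift, sd_t, sd_e) in _ENDPOINT_PARAMS.items():
        if ep in baseline_map:
            base = baseline_map[ep]
        else:
            base = np.where(
                treated,
                rng_out.normal(b_t, b_sd, n),
                rng_out.normal(b_e, b_sd, n))
            base = np.maximum(base, 0.0)
        ch = (drift + att * treated
              + rng_out.normal(0.0, 1.0, n) * np.where(treated, sd_t, sd_e))
        y1v = base + ch
        y1v = np.where(year1_missing, np.nan, y1v)
        for i in range(n):
            visit_rows.append((ids[i], ep, float(base[i]), float(y1v[i]),
                               float(y1v[i] - base[i])))
    visits = pd.DataFrame(
        visit_rows, columns=["id", "endpoint", "baseline", "year1", "change"])

    # --- NSAA item vectors ---------------------------------------------
    rng_items = _rng(seed, _STREAM_ITEMS)
    base_weights = _item_weights()
    non_amb = fail_rule == "ambulation"
    blocked_non_amb = np.zeros(17, dtype=bool)
    blocked_non_amb[[1, 16]] = True  # walk (item 2) and 10-m run (item 17)
    if config.include_items:
        base_items = np.zeros((n, 17), dtype=int)
        year1_items = np.full((n, 17), np.nan)
        for i in range(n):
            w = base_weights * rng_items.lognormal(0.0, 0.3, 17)
            if non_amb[i]:
                total0 = min(int(nsaa0[i]), 30)
                b = _allocate_items(total0, w, rng_items,
                                    blocked=blocked_non_amb)
                nsaa0[i] = total0
            else:
                b = _ensure_ambulatory(
                    _allocate_items(int(nsaa0[i]), w, rng_items))
            base_items[i] = b
            if np.isfinite(nsaa1[i]):
                year1_items[i] = _allocate_items(int(nsaa1[i]), w, rng_items)
        items = pd.concat([
            _items_frame(ids, "baseline", base_items),
            _items_frame(ids, "year1", year1_items),
        ], ignore_index=True)
    else:
        items = _items_frame([], "baseline",
                             np.empty((0, 17), dtype=int))
        # without item vectors the ambulation failers cannot be detected
        # downstream; exclude them via the velocity fallback instead
        run10_v[non_amb] = np.nan
    # keep participant table consistent with possibly capped totals
    visits.loc[visits.endpoint == "nsaa_total", "baseline"] = \
        nsaa0.astype(float)
    visits.loc[visits.endpoint == "nsaa_total", "change"] = (
        visits.loc[visits.endpoint == "nsaa_total", "year1"].to_numpy()
        - nsaa0)

    participants = pd.DataFrame({
        "id": ids,
        "arm": np.where(treated, "treated_high", "external"),
        "age_screening": age,
        "nsaa_total_baseline": nsaa0,
        "nsaa_total_year1": nsaa1,
        "rise_velocity": rise_v,
        "rise_time": rise_time,
        "run10_velocity": run10_v,
        "lvef": lvef.to_numpy(),
        "steroid_start": steroid_start.dt.strftime("%Y-%m-%d"),
        "screening_date": pd.Series(screening).dt.strftime("%Y-%m-%d"),
    })

    # --- fibers and LC-MS ----------------------------------------------
    if config.include_biopsies:
        fibers = pd.concat(
            [generate_fibers(config, v) for v in VISITS], ignore_index=True)
        rng_lcms = _rng(seed, _STREAM_LCMS)
        lcms_rows = []
        for visit in VISITS:
            mean = config.lcms.visit_mean[visit]
            sigma = config.lcms.log_sd
            mu = np.log(mean) - 0.5 * sigma ** 2
            conc = rng_lcms.lognormal(mu, sigma, n_t)
            for i in range(n_t):
                lcms_rows.append((ids[i], visit, float(conc[i])))
        lcms = pd.DataFrame(lcms_rows,
                            columns=["participant_id", "visit", "conc"])
    else:
        fibers = pd.DataFrame(
            columns=["participant_id", "visit", "section", "fiber_id",
                     "msd"])
        lcms = pd.DataFrame(columns=["participant_id", "visit", "conc"])

    truth = {
        "config": _config_dict(config),
        "true_att": config.true_att,
        "control_drift": config.control_drift,
        "nsaa_beta": _NSAA_BETA.tolist(),
        "nsaa_mu_ref": _NSAA_MU_REF.tolist(),
        "pool_shift": (config.confounding_strength * _POOL_SHIFT).tolist(),
        "pool_pass_indicator": passes[~treated].astype(int).tolist(),
        "endpoint_params": {k: list(v) for k, v in _ENDPOINT_PARAMS.items()},
    }
    return SimulatedStudy(participants, visits, items, fibers, lcms, truth)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["noise_sd"] = list(config.noise_sd)
    d["eligibility"]["age_range"] = list(config.eligibility.age_range)
    d["fibers"]["positive_fraction"] = dict(
        config.fibers.positive_fraction)
    d["lcms"]["visit_mean"] = dict(config.lcms.visit_mean)
    return d


def generate_fibers(config: SimConfig, visit: str) -> pd.DataFrame:
    """Per-fiber MSD table for all treated participants at one visit.

    Fibers are drawn from a two-component log-normal mixture whose
    positive fraction is configured per visit (0 at baseline by default).
    Deterministic given ``(config.seed, visit)``.
    """
    if visit not in VISITS:
        raise ValueError(f"unknown visit {visit!r}")
    fp = config.fibers
    fp.validate()
    frac = fp.positive_fraction.get(visit, 0.0)
    rng = _rng(config.seed, _STREAM_FIBERS, _visit_code(visit))
    n_fib = fp.n_fibers_per_section
    sections = list("AB"[:fp.n_sections])
    n_total = config.n_treated * len(sections) * n_fib
    positive = rng.random(n_total) < frac
    msd = np.where(
        positive,
        rng.lognormal(fp.positive_mu, fp.positive_sigma, n_total),
        rng.lognormal(fp.background_mu, fp.background_sigma, n_total))
    pids = np.repeat([f"T{i+1:03d}" for i in range(config.n_treated)],
                     len(sections) * n_fib)
    section_col = np.tile(np.repeat(sections, n_fib), config.n_treated)
    fiber_id = np.tile(np.arange(1, n_fib + 1),
                       config.n_treated * len(sections))
    return pd.DataFrame({"participant_id": pids, "visit": visit,
                         "section": section_col, "fiber_id": fiber_id,
                         "msd": msd})


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

def _fixture_participant(n_zero: int, n_gain: int, n_imp: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Item vectors realizing given baseline-zero / gained / improved counts.

    The hardest ``n_zero`` items score 0 at baseline; the first ``n_gain``
    of them score 1 at 1 year (gained).  Of the remaining items (baseline
    2), ``n_imp - n_gain`` keep their score (maintained) and the rest drop
    to 0, so the improved-or-maintained count is exactly ``n_imp``.
    """
    n_nonzero = 17 - n_zero
    n_maint = n_imp - n_gain
    if not 0 <= n_maint <= n_nonzero:
        raise ValueError("infeasible (n_zero, n_gain, n_imp) combination")
    order = np.argsort(_ITEM_DIFFICULTY_RANK)  # easiest first
    base = np.zeros(17, dtype=int)
    year1 = np.zeros(17, dtype=int)
    nonzero_items = order[:n_nonzero]
    zero_items = order[n_nonzero:]
    base[nonzero_items] = 2
    year1[nonzero_items[:n_maint]] = 2
    year1[zero_items[:n_gain]] = 1
    return base, year1


# (n_zero, n_gain, n_improved_or_maintained) per participant.
_FIXTURE_TREATED = [
    (1, 1, 17), (1, 1, 16), (2, 1, 16), (2, 1, 15), (3, 1, 13),
    (1, 0, 14), (1, 0, 12),
    (0, 0, 17), (0, 0, 17), (0, 0, 17), (0, 0, 16), (0, 0, 16),
    (0, 0, 16), (0, 0, 16), (0, 0, 15), (0, 0, 14),
]

_FIXTURE_EXTERNAL = (
    [(1, 1, 15)] * 5            # gainers
    + [(1, 0, 14)] * 6          # baseline zeros, no gain
    + [(1, 0, 12)] * 6
    + [(0, 0, 8)] * 10
    + [(0, 0, 10)] * 10
    + [(0, 0, 12)] * 9
    + [(0, 0, 14)] * 8
    + [(0, 0, 15)] * 5
)


def worked_example_fixture() -> SimulatedStudy:
    """Deterministic item-level fixture for the skill analytics.

    Sixteen treated and 59 external participants with baseline and 1-year
    NSAA item vectors constructed so that 7 treated and 17 external
    participants have at least one baseline-zero item, of whom 5 and 5
    respectively gain at least one skill (71.4% vs 29.4%), and the
    medians of skills improved-or-maintained are 16.0 and 12.0.
    """
    assert len(_FIXTURE_TREATED) == 16 and len(_FIXTURE_EXTERNAL) == 59
    rows_b, rows_y, ids, arms = [], [], [], []
    for arm, spec_list, prefix in [("treated_high", _FIXTURE_TREATED, "T"),
                                   ("external", _FIXTURE_EXTERNAL, "E")]:
        for k, (nz, ng, ni) in enumerate(spec_list):
            base, year1 = _fixture_participant(nz, ng, ni)
            pid = f"{prefix}{k+1:03d}"
            ids.append(pid)
            arms.append(arm)
            rows_b.append(base)
            rows_y.append(year1)
    items = pd.concat([
        _items_frame(ids, "baseline", np.array(rows_b)),
        _items_frame(ids, "year1", np.array(rows_y)),
    ], ignore_index=True)
    participants = pd.DataFrame({
        "id": ids,
        "arm": arms,
        "nsaa_total_baseline": np.array(rows_b).sum(axis=1),
        "nsaa_total_year1": np.array(rows_y).sum(axis=1),
    })
    visits = pd.DataFrame({
        "id": ids,
        "endpoint": "nsaa_total",
        "baseline": participants.nsaa_total_baseline.astype(float),
        "year1": participants.nsaa_total_year1.astype(float),
        "change": (participants.nsaa_total_year1
                   - participants.nsaa_total_baseline).astype(float),
    })
    empty_fibers = pd.DataFrame(
        columns=["participant_id", "visit", "section", "fiber_id", "msd"])
    empty_lcms = pd.DataFrame(columns=["participant_id", "visit", "conc"])
    truth = {"fixture": "worked_example",
             "treated_spec": _FIXTURE_TREATED,
             "external_spec": _FIXTURE_EXTERNAL}
    return SimulatedStudy(participants, visits, items, empty_fibers,
                          empty_lcms, truth)
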