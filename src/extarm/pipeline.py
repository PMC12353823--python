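"""End-to-end orchestration: configuration, stage execution, reporting.

The pipeline runs selection -> weighting -> balance -> endpoint battery
-> skill analytics -> dystrophin quantification over the five CSV inputs
(``participants.csv``, ``visits.csv``, ``nsaa_items.csv``, ``fibers.csv``,
``lcms.csv``) and writes a CSV report set plus a human-readable summary
and a run log.  All interchange is UTF-8 CSV with one header row and
empty fields for missing values.  Every run is identified by a hash of
its configuration, recorded in the manifest alongside each output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import apply_eligibility, impute_steroid_start
from .dystrophin import (average_sections, expression_summary,
                         fit_threshold, lcms_percent_normal, pct_positive)
from .effects import age_stratified_changes, endpoint_battery
from .nsaa import skill_summary
from .simulate import (PS_COVARIATES, SimConfig, generate_study)
from .weighting import att_weights, balance_table, fit_propensity, \
    trim_and_renormalize

__all__ = ["RunConfig", "RunLog", "cmd_simulate", "cmd_run_all",
           "load_config", "derive_analysis"]

log = logging.getLogger("extarm")


@dataclass
class RunConfig:
    """Run-level configuration (paths, seed, estimator switches)."""

    input_dir: str = "."
    output_dir: str = "out"
    seed: int = 1
    B: int = 2000
    trim_quantile: float = 0.95
    estimator: str = "iptw"
    literal_ambulation: bool = False
    lvef_inclusive: bool = True
    strict_improved: bool = False
    strata: tuple = ((6.0, 7.0), (8.0, 12.0))
    simulate: dict = field(default_factory=dict)  # SimConfig overrides

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulate)
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def derive_analysis(study, endpoint: str = "nsaa_total",
                    literal_ambulation: bool = False,
                    lvef_inclusive: bool = True) -> pd.DataFrame:
    """Selection applied to a study's pool, merged with one endpoint.

    Convenience for simulation studies: imputes steroid dates, applies
    the eligibility rules to the external pool, joins the treated arm
    back in and attaches the endpoint's 1-year change.  Returns one row
    per analysis participant with ``id``, ``arm``, ``change`` and the
    four propensity covariates (complete cases only).
    """
    parts = study.participants
    pool = impute_steroid_start(parts[parts["arm"].astype(str) == "external"])
    items = study.items if study.items is not None and len(study.items) \
        else None
    cohort_ext, _ = apply_eligibility(
        pool, items, literal_ambulation=literal_ambulation,
        lvef_inclusive=lvef_inclusive)
    cohort = pd.concat(
        [parts[parts["arm"].astype(str) != "external"], cohort_ext],
        ignore_index=True)
    changes = study.visits[study.visits["endpoint"] == endpoint]
    merged = cohort[["id", "arm", *PS_COVARIATES]].merge(
        changes[["id", "change"]], on="id", how="inner")
    return merged.dropna(subset=["change", *PS_COVARIATES]) \
        .reset_index(drop=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    if "strata" in raw:
        raw["strata"] = tuple(tuple(s) for s in raw["strata"])
    return RunConfig(**raw)


@dataclass
class RunLog:
    config_hash: str
    version: str = __version__
    stages: list = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        entry = {"stage": stage,
                 "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        self.stages.append(entry)
        log.info("stage %s: %s", stage, info)

    def write(self, path: Path, config: RunConfig) -> None:
        payload = {"config_hash": self.config_hash,
                   "version": self.version,
                   "config": dataclasses.asdict(config),
                   "stages": self.stages}
        path.write_text(json.dumps(payload, indent=2, default=str),
                        encoding="utf-8")


def _write(frame: pd.DataFrame, path: Path, manifest: dict,
           config_hash: str) -> None:
    frame.to_csv(path, index=False)
    manifest[path.name] = config_hash


def cmd_simulate(config: RunConfig) -> list[Path]:
    """Generate a synthetic study and write the five CSVs plus truth."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate_study(config.sim_config())
    written = study.write_csvs(outdir)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(study.truth, indent=2, default=str),
                          encoding="utf-8")
    written.append(truth_path)
    return written


def _read_inputs(indir: Path) -> dict[str, pd.DataFrame | None]:
    tables: dict[str, pd.DataFrame | None] = {}
    for name in ("participants", "visits", "nsaa_items", "fibers", "lcms"):
        path = indir / f"{name}.csv"
        tables[name] = pd.read_csv(path) if path.exists() else None
    return tables


def cmd_run_all(config: RunConfig) -> dict:
    """Run every analysis stage and assemble the report.

    Returns a dict of in-memory results; files land in
    ``config.output_dir``.  Missing fiber / LC-MS inputs skip the
    dystrophin stages with a logged warning; any stage error aborts with
    the stage name while retaining partial outputs.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    runlog = RunLog(config_hash=chash)
    manifest: dict[str, str] = {}
    results: dict = {"config_hash": chash}
    stage = "read_inputs"
    try:
        tables = _read_inputs(indir)
        participants = tables["participants"]
        visits = tables["visits"]
        items = tables["nsaa_items"]
        if participants is None or visits is None:
            raise FileNotFoundError(
                "participants.csv and visits.csv are required")
        runlog.record(stage, rows={k: (len(v) if v is not None else 0)
                                   for k, v in tables.items()})

        stage = "selection"
        treated = participants[
            participants["arm"].astype(str) != "external"]
        pool = participants[participants["arm"].astype(str) == "external"]
        pool = impute_steroid_start(pool)
        cohort_ext, report = apply_eligibility(
            pool, items,
            literal_ambulation=config.literal_ambulation,
            lvef_inclusive=config.lvef_inclusive)
        cohort = pd.concat([treated, cohort_ext], ignore_index=True)
        sel_frame = report.flags.reset_index()
        _write(cohort, outdir / "cohort.csv", manifest, chash)
        _write(sel_frame, outdir / "selection_report.csv", manifest, chash)
        results["selection"] = report
        runlog.record(stage, n_in=report.n_in,
                      n_selected=report.n_selected)

        stage = "weighting"
        psfit = fit_propensity(cohort)
        wv = trim_and_renormalize(
            att_weights(psfit, cohort.set_index("id")["arm"]),
            config.trim_quantile)
        weights_frame = pd.DataFrame({
            "id": wv.w.index, "arm": wv.arm.to_numpy(),
            "Pi": psfit.fitted_p.to_numpy(),
            "w_raw": att_weights(psfit,
                                 cohort.set_index("id")["arm"]).w.to_numpy(),
            "w_final": wv.w.to_numpy(),
        })
        _write(weights_frame, outdir / "weights.csv", manifest, chash)
        results["weights"] = wv
        runlog.record(stage, trim_cap=wv.trim_cap)

        stage = "balance"
        bal = balance_table(cohort, wv)
        _write(bal.reset_index(names="covariate"),
               outdir / "balance.csv", manifest, chash)
        results["balance"] = bal
        runlog.record(stage, **bal.attrs["max_abs_smd"])

        stage = "battery"
        battery = endpoint_battery(
            cohort, visits, B=config.B, seed=config.seed,
            estimator=config.estimator,
            trim_quantile=config.trim_quantile)
        _write(battery, outdir / "effects.csv", manifest, chash)
        results["battery"] = battery
        runlog.record(stage, n_endpoints=len(battery))

        stage = "age_strata"
        strata = age_stratified_changes(cohort, visits, wv,
                                        strata=config.strata)
        _write(strata, outdir / "age_strata.csv", manifest, chash)
        results["age_strata"] = strata
        runlog.record(stage, n_strata=len(strata))

        stage = "skills"
        if items is not None:
            in_cohort = items[items["id"].isin(cohort["id"])]
            summaries = skill_summary(
                in_cohort, cohort.set_index("id")["arm"],
                strict=config.strict_improved)
            skill_rows = []
            per_parts = []
            for arm, s in summaries.items():
                skill_rows.append({
                    "arm": arm, "n": s.n,
                    "n_with_baseline_zero": s.n_with_baseline_zero,
                    "n_gained_ge1": s.n_gained_ge1,
                    "pct_gained": s.pct_gained,
                    "median_improved_or_maintained":
                        s.median_improved_or_maintained})
                per_parts.append(s.per_participant)
            _write(pd.concat(per_parts, ignore_index=True),
                   outdir / "skills.csv", manifest, chash)
            _write(pd.DataFrame(skill_rows),
                   outdir / "skill_summary.csv", manifest, chash)
            results["skills"] = summaries
            runlog.record(stage, arms=list(summaries))
        else:
            log.warning("nsaa_items.csv missing; skill stage skipped")
            runlog.record(stage, skipped=True)

        stage = "dystrophin"
        fibers, lcms = tables["fibers"], tables["lcms"]
        if fibers is not None and len(fibers) > 0:
            model = fit_threshold(fibers[fibers["visit"] == "baseline"])
            quant = average_sections(pct_positive(fibers, model))
            if lcms is not None and len(lcms) > 0:
                lcms_cfg = config.simulate.get("lcms", {})
                norm = lcms_percent_normal(
                    lcms["conc"],
                    control_mean=lcms_cfg.get("control_mean", 2964.0),
                    lloq=lcms_cfg.get("lloq", 10.0))
                lcms_out = pd.concat(
                    [lcms.reset_index(drop=True), norm.drop(columns="conc")],
                    axis=1)
                _write(lcms_out, outdir / "lcms_quant.csv", manifest, chash)
            expr_rows = []
            for visit, grp in quant.groupby("visit"):
                s = expression_summary(grp["pct_positive_mean"])
                expr_rows.append({"visit": visit, **s})
            _write(quant, outdir / "biopsy_quant.csv", manifest, chash)
            _write(pd.DataFrame(expr_rows),
                   outdir / "expression_summary.csv", manifest, chash)
            (outdir / "threshold.json").write_text(
                json.dumps(dataclasses.asdict(model), indent=2),
                encoding="utf-8")
            manifest["threshold.json"] = chash
            results["threshold"] = model
            results["biopsy_quant"] = quant
            runlog.record(stage, threshold=model.threshold)
        else:
            log.warning("fibers.csv missing; dystrophin stages skipped")
            runlog.record(stage, skipped=True)
    except Exception as exc:
        runlog.record("error", failed_stage=stage, error=str(exc))
        runlog.write(outdir / "run_log.json", config)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "report"
    summary = _human_summary(results, config)
    (outdir / "summary.txt").write_text(summary, encoding="utf-8")
    manifest["summary.txt"] = chash
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8")
    runlog.record(stage, files=sorted(manifest))
    runlog.write(outdir / "run_log.json", config)
    results["summary"] = summary
    return results


def _human_summary(results: dict, config: RunConfig) -> str:
    lines = [f"extarm {__version__} run {results['config_hash']}",
             f"seed={config.seed} B={config.B} estimator={config.estimator}",
             ""]
    sel = results.get("selection")
    if sel is not None:
        lines.append(f"external pool {sel.n_in} -> cohort {sel.n_selected}")
    bal = results.get("balance")
    if bal is not None:
        mx = bal.attrs["max_abs_smd"]
        lines.append(
            f"max |SMD| unweighted {mx['smd_unweighted']:.3f}, "
            f"weighted {mx['smd_weighted']:.3f}")
    battery = results.get("battery")
    if battery is not None and len(battery):
        lines.append("")
        lines.append("endpoint battery (change at 1 year, "
                     "LS mean treated vs external, difference [95% CI], p):")
        for _, r in battery.iterrows():
            lines.append(
                f"  {r.endpoint:16s} {r.ls_mean_treated:8.2f} "
                f"{r.ls_mean_external:8.2f}  {r.difference:7.2f} "
                f"[{r.ci_low:.2f}, {r.ci_high:.2f}]  p={r.p_one_sided:.4f}")
    skills = results.get("skills")
    if skills:
        lines.append("")
        for arm, s in skills.items():
            lines.append(
                f"  {arm}: {s.n_gained_ge1}/{s.n_with_baseline_zero} "
                f"gained >=1 skill ({s.pct_gained:.1f}%), median "
                f"improved-or-maintained {s.median_improved_or_maintained}")
    model = results.get("threshold")
    if model is not None:
        lines.append("")
        lines.append(f"fiber positivity threshold {model.threshold:.3f} "
                     f"(99th pct of {model.source_n_fibers} baseline fibers)")
    return "\n".join(lines) + "\n"
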