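"""End-to-end reproducible runs: generate, build outcomes, estimate, report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import did, sequential
from .calibration import CalibrationTable, CovariateMarginals
from .cohort import CohortConfig, apply_missingness, generate_cohort
from .outcomes import add_analysis_columns, filter_sample

log = logging.getLogger("carebundle")

ALL_STAGES = ("main", "periods", "pretrend", "criteria", "robustness", "sequential")


def _package_version() -> str:
    try:
        return version("carebundle")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunConfig:
    """One reproducible run: cohort settings, stage selection, seed, outputs."""

    outdir: str = "carebundle_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    calibration_csv: str | None = None  # packaged transcription if None
    marginals_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        if "hospitals" in cohort_raw:
            cohort_raw["hospitals"] = {
                k: tuple(v) for k, v in cohort_raw["hospitals"].items()
            }
        if "effect_overrides" in cohort_raw:
            cohort_raw["effect_overrides"] = {
                (d["country"], int(d["financial_year"]), d.get("measure", "bundle")): float(
                    d["delta"]
                )
                for d in cohort_raw["effect_overrides"]
            }
        cfg = cls(**{k: v for k, v in raw.items() if k != "cohort"})
        cfg.cohort = CohortConfig(**cohort_raw)
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["effect_overrides"] = [
            {"country": c, "financial_year": fy, "measure": m, "delta": v}
            for (c, fy, m), v in self.cohort.effect_overrides.items()
        ]
        d["package_version"] = _package_version()
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_inputs(cfg: RunConfig) -> tuple[CalibrationTable, CovariateMarginals]:
    cal = (
        CalibrationTable.from_csv(cfg.calibration_csv)
        if cfg.calibration_csv
        else CalibrationTable.packaged()
    )
    marg = (
        CovariateMarginals.from_csv(cfg.marginals_csv)
        if cfg.marginals_csv
        else CovariateMarginals.packaged()
    )
    return cal, marg


def build_cohort(cfg: RunConfig) -> pd.DataFrame:
    """Generate -> mask covariates -> append analysis columns."""
    cal, marg = load_inputs(cfg)
    raw = generate_cohort(cal, marg, cfg.cohort, seed=cfg.seed)
    log.info("generated cohort: %d rows", len(raw))
    masked = apply_missingness(raw, cfg.cohort, seed=cfg.seed + 1)
    rows = add_analysis_columns(masked)
    return rows


def run_all(cfg: RunConfig) -> dict:
    """Run the configured stages and write every output with checksums.

    Returns the manifest (also written to ``manifest.json``). Any stage
    failure aborts with the stage name and the row count it received.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "package_version": _package_version(), "outputs": {}}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = {"sha256": _sha256(path)}

    emit("config.json", lambda p: p.write_text(json.dumps(cfg.to_jsonable(), indent=2, default=str)))

    rows = build_cohort(cfg)
    emit("cohort.csv", lambda p: rows.to_csv(p, index=False))
    main_rows = filter_sample(rows, "main")
    log.info("main estimation sample: %d of %d rows", len(main_rows), len(rows))

    stage = "series"
    try:
        emit("series_monthly.csv", lambda p: did.monthly_series(rows).to_csv(p, index=False))
        results_json: dict = {}
        if "main" in cfg.stages:
            stage = "main"
            fit = did.run_average_did(main_rows)
            results_json["main"] = fit.to_dict()
            emit("table_main.txt", lambda p: p.write_text(fit.summary("Average policy effect")))
        if "periods" in cfg.stages:
            stage = "periods"
            fit = did.run_period_did(main_rows)
            results_json["periods"] = fit.to_dict()
            emit("table_periods.txt", lambda p: p.write_text(fit.summary("Period-specific policy effects")))
        if "pretrend" in cfg.stages:
            stage = "pretrend"
            fit = did.run_pretrend_test(main_rows)
            d = fit.to_dict()
            for key in ("joint_wald", "joint_wald_no_anticipation"):
                w = fit.extras[key]
                d[key] = {"statistic": w.statistic, "df": w.df, "pvalue": w.pvalue,
                          "f_pvalue": w.f_pvalue}
            for key in ("joint_lincomb", "joint_lincomb_no_anticipation"):
                est, se, p = fit.extras[key]
                d[key] = {"estimate": est, "se": se, "pvalue": p}
            results_json["pretrend"] = d
        if "criteria" in cfg.stages:
            stage = "criteria"
            res = did.run_criterion_effects(main_rows)
            emit("table_criteria.csv", lambda p: did.criterion_table(res).to_csv(p, index=False))
            results_json["criteria"] = {k: v["average"].to_dict() for k, v in res.items()}
        if "robustness" in cfg.stages:
            stage = "robustness"
            res = did.run_robustness_suite(rows)
            emit("table_robustness.csv", lambda p: did.robustness_table(res).to_csv(p, index=False))
            results_json["robustness"] = {k: v["average"].to_dict() for k, v in res.items()}
        if "sequential" in cfg.stages:
            stage = "sequential"
            seq_rows = sequential.build_sequential_rows(main_rows)
            results_json["sequential"] = {
                variant: sequential.run_sequential(seq_rows, variant).to_dict()
                for variant in sequential.SEQUENTIAL_VARIANTS
            }
        emit("results.json", lambda p: p.write_text(json.dumps(results_json, indent=2)))
    except Exception:
        log.error("stage %r failed (cohort rows: %d, main sample: %d)",
                  stage, len(rows), len(main_rows))
        raise

    emit_manifest = outdir / "manifest.json"
    emit_manifest.write_text(json.dumps(manifest, indent=2))
    return manifest
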