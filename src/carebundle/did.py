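"""Difference-in-differences specifications over an analysis-row table.

All estimating equations share one core: a linear probability model with
hospital fixed effects (absorbed), financial-year and calendar-month dummies,
case-mix dummies, and hospital-clustered standard errors. The treatment
contrast is England (treated, paid the bundle bonus from April 2010) against
Wales (control, capitation-funded throughout).

Only interactions are entered: the post-period main effect is collinear with
the year dummies and the England main effect with the hospital fixed
effects, so neither is identified and the builder omits them by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CRITERIA
from .felpm import FEResults, FixedEffectsLPM, PanelSpec
from .outcomes import filter_sample

#: covariate dummies with their reference categories (first level = reference)
FULL_COVARIATES = ("age_band", "sex", "admission_source", "asa", "mobility", "fracture")
LIMITED_COVARIATES = ("age_band", "sex", "fracture")
REFERENCE_LEVELS = {
    "age_band": "60-64",
    "sex": "female",
    "admission_source": "hospital",
    "asa": "1",
    "mobility": "full",
    "fracture": "extracapsular",
    "financial_year": 2008,
    "adm_month": 4,  # April
}


@dataclass(frozen=True)
class PeriodMap:
    """The three post-policy bonus eras and their per-patient bonus sizes (GBP)."""

    periods: tuple[str, ...] = ("P1", "P2", "P3")
    years: dict = field(
        default_factory=lambda: {"P1": (2010,), "P2": (2011,), "P3": (2012, 2013, 2014)}
    )
    bonus: dict = field(default_factory=lambda: {"P1": 445.0, "P2": 890.0, "P3": 1335.0})


@dataclass(frozen=True)
class PretrendSpec:
    """Country-specific quarter trends over the pre-policy window."""

    quarters: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    reference: int = 1
    anticipation_quarter: int = 8  # January - March 2010


def _dummies(df: pd.DataFrame, col: str, prefix: str | None = None) -> pd.DataFrame:
    """0/1 dummies for every level except the reference category."""
    prefix = prefix or col
    d = pd.get_dummies(df[col], prefix=prefix, dtype=np.float64)
    ref = REFERENCE_LEVELS.get(col)
    ref_col = f"{prefix}_{ref}"
    if ref_col in d.columns:
        d = d.drop(columns=ref_col)
    elif len(d.columns):
        # reference level absent from this sample (e.g. post-policy-only
        # windows): treat the first observed level as the reference instead
        d = d.drop(columns=d.columns[0])
    return d


def build_design(
    df: pd.DataFrame,
    covariates=FULL_COVARIATES,
    year_dummies: bool = True,
    month_dummies: bool = True,
) -> pd.DataFrame:
    """Assemble the shared dummy block (covariates, year and month effects)."""
    parts = []
    if year_dummies:
        parts.append(_dummies(df, "financial_year", "fy"))
    if month_dummies:
        parts.append(_dummies(df, "adm_month", "month"))
    for var in covariates or ():
        parts.append(_dummies(df, var))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def _resolve_covariates(covariates):
    if covariates == "full":
        return FULL_COVARIATES
    if covariates == "limited":
        return LIMITED_COVARIATES
    if covariates is None:
        return ()
    return tuple(covariates)


def _check_support(rows: pd.DataFrame, need_pre_post: bool = True) -> None:
    if rows["england"].nunique() < 2:
        raise ValueError("both countries must be present")
    if need_pre_post and rows["post"].nunique() < 2:
        raise ValueError("rows must span the pre- and post-policy periods")


def _fit(rows: pd.DataFrame, outcome: str, treatment_cols, covariates) -> FEResults:
    design = build_design(rows, covariates=_resolve_covariates(covariates))
    data = pd.concat([rows[[outcome, "hospital"]], treatment_cols, design], axis=1)
    spec = PanelSpec(
        outcome=outcome,
        regressors=tuple(treatment_cols.columns) + tuple(design.columns),
        absorb="hospital",
        cluster="hospital",
    )
    return FixedEffectsLPM(data, spec).fit()


def run_average_did(rows: pd.DataFrame, outcome: str = "bundle_met", covariates="full") -> FEResults:
    """Average post-policy treatment effect: the England x post coefficient."""
    _check_support(rows)
    treat = pd.DataFrame({"england_post": rows["england_post"].astype(np.float64)})
    res = _fit(rows, outcome, treat, covariates)
    res.effects["att"] = "england_post"
    return res


def run_period_did(
    rows: pd.DataFrame,
    outcome: str = "bundle_met",
    pm: PeriodMap | None = None,
    covariates="full",
) -> FEResults:
    """Period-specific treatment effects, one per bonus era."""
    pm = pm or PeriodMap()
    _check_support(rows)
    treat = {}
    for p in pm.periods:
        in_period = rows["financial_year"].isin(pm.years[p]).astype(np.float64)
        treat[f"england_{p}"] = rows["england"].to_numpy(np.float64) * in_period.to_numpy()
    treat = pd.DataFrame(treat, index=rows.index)
    res = _fit(rows, outcome, treat, covariates)
    for p in pm.periods:
        res.effects[f"att_{p.lower()}"] = f"england_{p}"
    res.extras["bonus"] = dict(pm.bonus)
    return res


def run_pretrend_test(
    rows: pd.DataFrame,
    outcome: str = "bundle_met",
    spec: PretrendSpec | None = None,
    covariates="full",
) -> FEResults:
    """Country-specific quarter trends over the pre-policy window.

    Fits quarter dummies plus England x quarter interactions on pre-policy
    rows only. Attaches, in ``extras``: the joint Wald test over all
    interactions, the same test excluding the final (anticipation) quarter,
    and the corresponding summed-coefficient linear combinations.
    """
    spec = spec or PretrendSpec()
    pre = rows[rows["post"] == 0]
    present = set(pre["quarter"].dropna().astype(int))
    if present != set(spec.quarters):
        raise ValueError(
            f"pre-trend test needs all quarters {sorted(spec.quarters)}, found {sorted(present)}"
        )
    _check_support(pre, need_pre_post=False)
    q = pre["quarter"].astype(int)
    cols = {}
    taus = []
    for k in spec.quarters:
        if k == spec.reference:
            continue
        qk = (q == k).astype(np.float64)
        cols[f"q{k}"] = qk
        cols[f"england_q{k}"] = pre["england"].to_numpy(np.float64) * qk.to_numpy()
        taus.append(f"england_q{k}")
    treat = pd.DataFrame(cols, index=pre.index)
    # no year or calendar-month dummies here: year-specific quarters already
    # saturate the two-year window, and month dummies would be collinear with
    # them (each calendar quarter's months sum to a pair of quarter dummies)
    design = build_design(
        pre, covariates=_resolve_covariates(covariates), year_dummies=False, month_dummies=False
    )
    data = pd.concat([pre[[outcome, "hospital"]], treat, design], axis=1)
    pspec = PanelSpec(
        outcome=outcome,
        regressors=tuple(treat.columns) + tuple(design.columns),
        absorb="hospital",
        cluster="hospital",
    )
    res = FixedEffectsLPM(data, pspec).fit()
    for name in taus:
        res.effects[f"tau_{name.split('_')[1]}"] = name
    no_anticip = [t for t in taus if t != f"england_q{spec.anticipation_quarter}"]
    res.extras["joint_wald"] = res.wald_joint(taus)
    res.extras["joint_wald_no_anticipation"] = res.wald_joint(no_anticip)
    res.extras["joint_lincomb"] = res.lincomb(taus)
    res.extras["joint_lincomb_no_anticipation"] = res.lincomb(no_anticip)
    return res


CRITERION_OUTCOMES = CRITERIA + ("criteria_count",)


def run_criterion_effects(rows: pd.DataFrame, pm: PeriodMap | None = None) -> dict:
    """Average and period-specific effects for each criterion and the count."""
    out = {}
    for outcome in CRITERION_OUTCOMES:
        out[outcome] = {
            "average": run_average_did(rows, outcome=outcome),
            "periods": run_period_did(rows, outcome=outcome, pm=pm),
        }
    return out


def criterion_table(results: dict) -> pd.DataFrame:
    rows = []
    for outcome, fits in results.items():
        avg = fits["average"]
        per = fits["periods"]
        est, se, p = avg.effect("att")
        row = {"outcome": outcome, "att": est, "att_se": se, "att_p": p}
        for name in per.effects:
            e, s, _ = per.effect(name)
            row[name] = e
            row[f"{name}_se"] = s
        rows.append(row)
    return pd.DataFrame(rows)


ROBUSTNESS_VARIANTS = ("balanced_panel", "limited_casemix", "seven_criteria", "no_anticipation")


def run_robustness_suite(rows: pd.DataFrame, pm: PeriodMap | None = None) -> dict:
    """Sensitivity analyses on unfiltered analysis rows.

    Each variant applies its own sample filter, covariate set and outcome
    definition, then re-estimates the average and period-specific effects.
    """
    out = {}
    for variant in ROBUSTNESS_VARIANTS:
        sub = filter_sample(rows, variant)
        if len(sub) == 0:
            raise ValueError(f"variant {variant!r} produced an empty sample")
        covariates = "limited" if variant == "limited_casemix" else "full"
        outcome = "bundle_met7" if variant == "seven_criteria" else "bundle_met"
        out[variant] = {
            "average": run_average_did(sub, outcome=outcome, covariates=covariates),
            "periods": run_period_did(sub, outcome=outcome, pm=pm, covariates=covariates),
        }
    return out


def robustness_table(results: dict) -> pd.DataFrame:
    rows = []
    for variant, fits in results.items():
        est, se, p = fits["average"].effect("att")
        row = {"variant": variant, "att": est, "att_se": se, "att_p": p,
               "nobs": fits["average"].nobs}
        for name in fits["periods"].effects:
            e, s, _ = fits["periods"].effect(name)
            row[name] = e
            row[f"{name}_se"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def monthly_series(rows: pd.DataFrame, outcome: str = "bundle_met") -> pd.DataFrame:
    """Achievement-by-month time series per country (figure-style output)."""
    g = (
        rows.groupby(["country", "adm_year", "adm_month"], observed=True)[outcome]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": outcome, "size": "n"})
    )
    g["date"] = pd.to_datetime(dict(year=g["adm_year"], month=g["adm_month"], day=1))
    return g.sort_values(["country", "date"]).reset_index(drop=True)
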