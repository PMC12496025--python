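"""Sequential decision-making: does missing an early criterion reduce later effort?

Bonus payment is all-or-nothing per patient, so once any criterion is missed
the marginal financial incentive for the remaining ones drops to zero. The
care pathway orders some criteria before surgery (timely surgery bpt1, the
multidisciplinary protocol bpt3, pre-operative cognitive assessment bpt4 and
the peri-operative geriatric assessment bpt6) and some after (rehabilitation
bpt7, falls prevention bpt8, bone health bpt9). Shared care bpt2 is excluded:
its achievement is persistently low in the control country, leaving almost no
patients with every pre-surgery criterion met.

The regression of interest is, on post-policy admissions,

    Post = a + gamma * Pre + theta * England x Pre + X d + time + FE + e

where Pre = 1 if at least one pre-surgery criterion was missed and Post = 1
if all post-surgery criteria were met. A negative theta would indicate
strategic effort withdrawal in the incentivized country once the bonus is
lost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .did import build_design, _resolve_covariates
from .felpm import FEResults, FixedEffectsLPM, PanelSpec
from .outcomes import ERA_BOUNDARY_FY, POLICY_START_FY

PRE_SURGERY = ("bpt1", "bpt3", "bpt4", "bpt6")
POST_SURGERY = ("bpt7", "bpt8", "bpt9")

SEQUENTIAL_VARIANTS = ("observed", "covariates_no_FE", "covariates_FE")


def build_sequential_rows(rows: pd.DataFrame, bpt4_from: int | None = None) -> pd.DataFrame:
    """Derive the Pre (any pre-surgery criterion missed) and Post (all
    post-surgery criteria met) indicators on post-policy rows.

    ``bpt4_from``: if set (e.g. 2012), bpt4 only counts toward Pre from that
    financial year; by default it is included in all post-policy years.
    """
    df = rows[rows["financial_year"] >= POLICY_START_FY].copy()
    pre_cols = df[list(PRE_SURGERY)].to_numpy()
    missed_any = (pre_cols == 0).any(axis=1)
    if bpt4_from is not None:
        no_bpt4 = (df[[c for c in PRE_SURGERY if c != "bpt4"]].to_numpy() == 0).any(axis=1)
        missed_any = np.where(df["financial_year"] >= bpt4_from, missed_any, no_bpt4)
    df["pre_failed"] = missed_any.astype(np.int8)
    df["post_met"] = (df[list(POST_SURGERY)].to_numpy() == 1).all(axis=1).astype(np.int8)
    return df


def run_sequential(rows: pd.DataFrame, variant: str = "covariates_FE") -> FEResults:
    """Estimate the effort-withdrawal regression in one of three variants.

    observed: raw contrasts only (Pre, England, Pre x England; no controls).
    covariates_no_FE: adds year/month dummies and case-mix dummies.
    covariates_FE: additionally absorbs hospital fixed effects; the England
        main effect is then collinear with them and omitted.
    """
    if variant not in SEQUENTIAL_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {SEQUENTIAL_VARIANTS}")
    if "pre_failed" not in rows.columns:
        rows = build_sequential_rows(rows)
    treat = pd.DataFrame(
        {
            "pre_failed": rows["pre_failed"].astype(np.float64),
            "pre_failed_x_england": (rows["pre_failed"] * rows["england"]).astype(np.float64),
        },
        index=rows.index,
    )
    absorb = "hospital" if variant == "covariates_FE" else None
    if absorb is None:
        treat.insert(1, "england", rows["england"].astype(np.float64))
    if variant == "observed":
        design = pd.DataFrame(index=rows.index)
    else:
        design = build_design(rows, covariates=_resolve_covariates("full"))
    data = pd.concat([rows[["post_met", "hospital"]], treat, design], axis=1)
    spec = PanelSpec(
        outcome="post_met",
        regressors=tuple(treat.columns) + tuple(design.columns),
        absorb=absorb,
        cluster="hospital",
    )
    res = FixedEffectsLPM(data, spec).fit()
    res.effects["gamma"] = "pre_failed"
    res.effects["interaction"] = "pre_failed_x_england"
    if absorb is None:
        res.effects["england"] = "england"
    res.extras["variant"] = variant
    return res
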