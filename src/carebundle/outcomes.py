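"""Analysis variables: financial years, policy periods, bundle indicators, filters.

The bundle indicator is era-specific: before April 2012 a patient counts as
fully treated when all seven then-incentivized criteria are met; from April
2012 the pre-operative cognitive assessment (bpt4) joins the set. bpt5 never
enters any analysis. Unachieved criteria are coded 0 at source (the audit
records a criterion as missing when it was not achieved), so no indicator is
ever treated as missing data.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

from .calibration import EIGHT_CRITERIA, SEVEN_CRITERIA

STUDY_START = (2008, 4)  # April 2008
STUDY_END = (2015, 3)  # March 2015
POLICY_START_FY = 2010  # bonus first paid from April 2010
ERA_BOUNDARY_FY = 2012  # bpt4 incentivized from April 2012

#: anticipation window: the six months before the policy (Oct 2009 - Mar 2010)
ANTICIPATION_MONTHS = ((2009, 10), (2010, 3))

SAMPLE_VARIANTS = ("main", "balanced_panel", "limited_casemix", "seven_criteria", "no_anticipation")


def financial_year(date) -> int:
    """UK financial year of a date: April-December map to the calendar year,
    January-March to the previous one. Raises outside April 2008 - March 2015."""
    if isinstance(date, str):
        date = pd.Timestamp(date)
    y, m = date.year, date.month
    fy = y if m >= 4 else y - 1
    if not (STUDY_START <= (y, m) <= (STUDY_END[0], 12)) or (y, m) > STUDY_END:
        raise ValueError(f"date {y}-{m:02d} outside study window April 2008 - March 2015")
    return fy


def fy_label(fy: int) -> str:
    return f"FY{fy}"


def bundle_met(record) -> int:
    """All-criteria indicator for one patient record (mapping or Series).

    Uses the admission era to choose the seven- or eight-criterion set; the
    record must expose ``financial_year`` (or ``adm_year``/``adm_month``) and
    the criterion indicators.
    """
    if "financial_year" in record:
        fy = int(record["financial_year"])
    else:
        fy = financial_year(_dt.date(int(record["adm_year"]), int(record["adm_month"]), 1))
    crits = EIGHT_CRITERIA if fy >= ERA_BOUNDARY_FY else SEVEN_CRITERIA
    return int(all(int(record[c]) == 1 for c in crits))


def _all_met(df: pd.DataFrame, criteria) -> np.ndarray:
    return df[list(criteria)].to_numpy().min(axis=1)


def add_analysis_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append outcome, treatment and time labels to a cohort frame.

    Adds: ``financial_year`` (if absent), ``post``, ``period`` (P1/P2/P3 for
    the three post-policy bonus eras), ``quarter`` (1..8 within the pre-policy
    window), ``england``, ``england_post``, ``bundle_met``, ``bundle_met7``
    (seven-criterion definition in *all* years) and ``criteria_count``
    (era-specific set).
    """
    df = df.copy()
    if "financial_year" not in df:
        df["financial_year"] = [
            financial_year(_dt.date(y, m, 1)) for y, m in zip(df["adm_year"], df["adm_month"])
        ]
    fy = df["financial_year"].to_numpy()
    df["post"] = (fy >= POLICY_START_FY).astype(np.int8)
    df["period"] = pd.Series(
        np.select(
            [fy == 2010, fy == 2011, fy >= ERA_BOUNDARY_FY],
            ["P1", "P2", "P3"],
            default=None,
        ),
        index=df.index,
        dtype="object",
    ).where(df["post"] == 1)

    # pre-policy quarter index (Apr-Jun 2008 = 1, ..., Jan-Mar 2010 = 8)
    months_since = (df["adm_year"] - 2008) * 12 + df["adm_month"] - 4
    quarter = months_since // 3 + 1
    df["quarter"] = quarter.where(df["post"] == 0).astype("Int64")

    df["england"] = (df["country"] == "England").astype(np.int8)
    df["england_post"] = df["england"] * df["post"]

    eight = _all_met(df, EIGHT_CRITERIA)
    seven = _all_met(df, SEVEN_CRITERIA)
    era8 = fy >= ERA_BOUNDARY_FY
    df["bundle_met"] = np.where(era8, eight, seven).astype(np.int8)
    df["bundle_met7"] = seven.astype(np.int8)

    count7 = df[list(SEVEN_CRITERIA)].sum(axis=1)
    count8 = df[list(EIGHT_CRITERIA)].sum(axis=1)
    df["criteria_count"] = np.where(era8, count8, count7).astype(np.int8)
    return df


def _rows_without_masked(df: pd.DataFrame) -> pd.DataFrame:
    flags = [c for c in df.columns if c.endswith("_missing")]
    if not flags:
        return df
    return df.loc[~df[flags].any(axis=1)]


def filter_sample(rows: pd.DataFrame, variant: str = "main", min_patients: int = 30) -> pd.DataFrame:
    """Apply one of the named estimation-sample filters.

    main: drop rows with any masked covariate.
    balanced_panel: additionally keep only hospitals observed in every
        financial year with at least ``min_patients`` patients per year
        (hospital-year counts evaluated before the covariate filter).
    limited_casemix: keep every row (the matching estimation uses only the
        fully recorded covariates: age, sex, fracture type).
    seven_criteria: same rows as main (the outcome switches to the
        seven-criterion bundle definition at estimation time).
    no_anticipation: main, minus admissions in the six months before the
        policy start (October 2009 - March 2010 inclusive).
    """
    if variant not in SAMPLE_VARIANTS:
        raise ValueError(f"unknown sample variant {variant!r}; choose from {SAMPLE_VARIANTS}")
    if variant == "limited_casemix":
        return rows
    if variant == "balanced_panel":
        n_years = rows["financial_year"].nunique()
        counts = rows.groupby(["hospital", "financial_year"]).size()
        ok_years = (counts >= min_patients).groupby("hospital").sum()
        present = counts.groupby("hospital").size()
        keep = ok_years.index[(ok_years == n_years) & (present == n_years)]
        rows = rows[rows["hospital"].isin(keep)]
        return _rows_without_masked(rows)
    if variant == "no_anticipation":
        ym = list(zip(rows["adm_year"], rows["adm_month"]))
        in_window = [ANTICIPATION_MONTHS[0] <= x <= ANTICIPATION_MONTHS[1] for x in ym]
        rows = rows.loc[~np.asarray(in_window)]
        return _rows_without_masked(rows)
    return _rows_without_masked(rows)
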