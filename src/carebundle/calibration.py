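"""Published calibration inputs: achievement proportions and case-mix marginals.

Ships two transcribed tables as package data:

- ``achievement_calibration.csv``: per country (England / Wales) and financial
  year (2008..2014, each running 1 April to 31 March) the proportion of
  patients achieving each best-practice criterion (bpt1..bpt4, bpt6..bpt9;
  bpt5 was not collected before April 2011 and is excluded from all analyses)
  plus the all-criteria "bundle" proportion.
- ``covariate_marginals.csv``: categorical case-mix distributions (age band,
  sex, admission source, ASA grade, pre-fracture mobility, fracture type) per
  country. The age-band distribution is synthetic: the audit descriptives
  publish only mean age, so bands were chosen to match the published means.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COUNTRIES = ("England", "Wales")
FINANCIAL_YEARS = tuple(range(2008, 2015))
CRITERIA = ("bpt1", "bpt2", "bpt3", "bpt4", "bpt6", "bpt7", "bpt8", "bpt9")
MEASURES = ("bundle",) + CRITERIA

#: pre-operative cognitive assessment joins the incentivized bundle here
ERA_BOUNDARY_FY = 2012

#: bundle membership by era: seven criteria before April 2012, eight after
SEVEN_CRITERIA = ("bpt1", "bpt2", "bpt3", "bpt6", "bpt7", "bpt8", "bpt9")
EIGHT_CRITERIA = ("bpt1", "bpt2", "bpt3", "bpt4", "bpt6", "bpt7", "bpt8", "bpt9")

_ALIASES = {"care bundle": "bundle", "care_bundle": "bundle", "all": "bundle"}


def bundle_criteria(financial_year: int) -> tuple[str, ...]:
    """Criteria counted toward the bundle in the given financial year."""
    return EIGHT_CRITERIA if financial_year >= ERA_BOUNDARY_FY else SEVEN_CRITERIA


def _canonical(measure: str) -> str:
    m = measure.strip().lower()
    return _ALIASES.get(m, m)


@dataclass(frozen=True)
class CalibrationTable:
    """Achievement probabilities keyed by (country, financial year, measure)."""

    probs: dict = field(repr=False)

    def __post_init__(self) -> None:
        missing = [
            (c, fy, m)
            for c in COUNTRIES
            for fy in FINANCIAL_YEARS
            for m in MEASURES
            if (c, fy, m) not in self.probs
        ]
        if missing:
            raise ValueError(f"calibration grid incomplete, first missing cell: {missing[0]}")
        bad = {k: v for k, v in self.probs.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ValueError(f"calibration probabilities outside [0, 1]: {bad}")

    def prob(self, country: str, financial_year: int, measure: str) -> float:
        return self.probs[(country, int(financial_year), _canonical(measure))]

    def criterion_probs(self, country: str, financial_year: int) -> dict[str, float]:
        return {c: self.prob(country, financial_year, c) for c in CRITERIA}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationTable":
        probs = {
            (row.country, int(row.financial_year), _canonical(row.measure)): float(row.proportion)
            for row in df.itertuples()
        }
        return cls(probs=probs)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def packaged(cls) -> "CalibrationTable":
        """The transcription shipped with the package."""
        ref = importlib.resources.files("carebundle.data") / "achievement_calibration.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"country": c, "financial_year": fy, "measure": m, "proportion": p}
            for (c, fy, m), p in sorted(self.probs.items())
        ]
        return pd.DataFrame(rows)

    # -- counterfactual constructors -------------------------------------

    def placebo(self, source_country: str = "England") -> "CalibrationTable":
        """Both countries given ``source_country``'s probabilities (no-effect design)."""
        probs = {
            (c, fy, m): self.probs[(source_country, fy, m)]
            for c in COUNTRIES
            for fy in FINANCIAL_YEARS
            for m in MEASURES
        }
        return replace(self, probs=probs)

    def with_effect(
        self,
        country: str,
        financial_years,
        delta: float,
        measure: str = "bundle",
    ) -> "CalibrationTable":
        """Shift a measure's probability by ``delta`` in the given cells (clipped to [0, 1])."""
        probs = dict(self.probs)
        m = _canonical(measure)
        for fy in financial_years:
            key = (country, int(fy), m)
            probs[key] = float(np.clip(probs[key] + delta, 0.0, 1.0))
        return replace(self, probs=probs)


def recovery_calibration(delta: float = 0.0) -> CalibrationTable:
    """A symmetric design for parameter-recovery simulations.

    Both countries share identical, time-constant probabilities (criteria 0.85,
    bundle 0.35, all inside the feasible copula range), and ``delta`` is added
    to England's post-policy (financial year >= 2010) bundle probability. The
    injected ``delta`` is therefore the true average treatment effect.
    """
    probs = {}
    for c in COUNTRIES:
        for fy in FINANCIAL_YEARS:
            probs[(c, fy, "bundle")] = 0.35
            for crit in CRITERIA:
                probs[(c, fy, crit)] = 0.85
    cal = CalibrationTable(probs=probs)
    if delta:
        cal = cal.with_effect("England", [fy for fy in FINANCIAL_YEARS if fy >= 2010], delta)
    return cal


# ---------------------------------------------------------------------------


COVARIATES = ("age_band", "sex", "admission_source", "asa", "mobility", "fracture")


@dataclass(frozen=True)
class CovariateMarginals:
    """Categorical case-mix distributions per country."""

    tables: dict = field(repr=False)  # country -> variable -> (levels, probs)

    def __post_init__(self) -> None:
        for country, vars_ in self.tables.items():
            for var, (levels, probs) in vars_.items():
                if abs(sum(probs) - 1.0) > 0.02:
                    raise ValueError(f"{country}/{var} probabilities sum to {sum(probs):.3f}")

    def levels(self, country: str, variable: str) -> tuple:
        return self.tables[country][variable][0]

    def probabilities(self, country: str, variable: str) -> np.ndarray:
        levels, probs = self.tables[country][variable]
        p = np.asarray(probs, dtype=float)
        return p / p.sum()  # renormalise rounded transcriptions

    @classmethod
    def from_csv(cls, path) -> "CovariateMarginals":
        df = pd.read_csv(path, dtype={"level": str})
        tables: dict = {}
        for (country, var), g in df.groupby(["country", "variable"], sort=False):
            tables.setdefault(country, {})[var] = (
                tuple(g["level"]),
                tuple(g["probability"].astype(float)),
            )
        return cls(tables=tables)

    @classmethod
    def packaged(cls) -> "CovariateMarginals":
        ref = importlib.resources.files("carebundle.data") / "covariate_marginals.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)
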