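"""Synthetic hip-fracture audit cohorts calibrated to published achievement rates.

Each patient carries categorical case-mix covariates, a hospital, a country,
a monthly admission date (April 2008 - March 2015) and eight binary
care-process indicators. Indicators are correlated within patient through a
one-factor Gaussian copula: the latent score for patient ``i`` in hospital
``h`` on criterion ``j`` is

    L_ijh = sqrt(a) * U_h + sqrt(r - a) * Z_i + sqrt(1 - r) * E_ij

with ``U_h`` a persistent hospital intercept (variance share ``a``), ``Z_i``
a patient-level common factor and ``E_ij`` idiosyncratic noise; criterion
``j`` is achieved iff ``L_ijh < Phi^{-1}(p_j)`` so every marginal matches its
calibration cell exactly in expectation.

The cell-level equicorrelation ``r`` is, by default, *calibrated*: it is
solved (Brent's method on a Gauss-Hermite quadrature of the joint orthant
probability) so that the probability of achieving *all* criteria in the
era-specific bundle equals the published all-criteria proportion for that
country and financial year. Cells whose published bundle proportion falls
below the independence product are clamped at ``r = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special

from .calibration import (
    COUNTRIES,
    COVARIATES,
    CRITERIA,
    FINANCIAL_YEARS,
    CalibrationTable,
    CovariateMarginals,
    bundle_criteria,
)

#: financial-year months in order: April..December of fy, then January..March of fy+1
_FY_MONTHS = tuple(range(4, 13)) + tuple(range(1, 4))


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration.

    hospitals: per-country (start, end) counts; participation grows linearly
        across the seven financial years, early joiners staying for good.
    patients_per_country_year: cell totals (int for both countries, or a
        mapping country -> int).
    dispersion: gamma shape for allocating a cell's patients across its
        active hospitals (smaller = more unequal cluster sizes).
    hospital_icc: variance share of the persistent hospital intercept on the
        unit-variance latent scale (shared across criteria and years).
    correlation: None to calibrate the within-patient equicorrelation to the
        published bundle proportions; a float or {(country, fy): float}
        mapping to fix it instead.
    missing_rates: target row-level share of patients with at least one
        masked covariate, per country.
    maskable: covariates eligible for masking. Age, sex and fracture type are
        recorded for all patients in the audit and excluded by default.
    effect_overrides: {(country, financial_year, measure): delta} shifts
        applied to the calibration before generation (parameter-recovery
        hooks); measure "bundle" shifts the joint target, criterion names
        shift marginals.
    """

    hospitals: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"England": (105, 165), "Wales": (5, 13)}
    )
    patients_per_country_year: int | Mapping[str, int] = field(
        default_factory=lambda: {"England": 12000, "Wales": 3000}
    )
    dispersion: float = 5.0
    hospital_icc: float = 0.03
    correlation: float | Mapping[tuple[str, int], float] | None = None
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {"England": 0.175, "Wales": 0.188}
    )
    maskable: tuple[str, ...] = ("admission_source", "asa", "mobility")
    effect_overrides: Mapping[tuple[str, int, str], float] = field(default_factory=dict)
    seed: int = 0

    def cell_size(self, country: str) -> int:
        if isinstance(self.patients_per_country_year, Mapping):
            return int(self.patients_per_country_year[country])
        return int(self.patients_per_country_year)


class CorrelationError(ValueError):
    """Requested correlation is infeasible for the given marginals."""


# ---------------------------------------------------------------------------
# joint achievement probability under the one-factor copula

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def joint_achievement_prob(marginals, rho: float) -> float:
    """P(all criteria met) given marginal probabilities and latent equicorrelation."""
    ps = np.asarray([p for p in marginals if p < 1.0], dtype=float)
    if ps.size == 0:
        return 1.0
    if (ps <= 0.0).any():
        return 0.0
    if not 0.0 <= rho < 1.0:
        raise CorrelationError(f"equicorrelation must lie in [0, 1), got {rho}")
    t = special.ndtri(ps)
    if rho <= 1e-12:
        return float(np.prod(ps))
    z = (t[None, :] - np.sqrt(rho) * _GH_NODES[:, None]) / np.sqrt(1.0 - rho)
    return float(_GH_WEIGHTS @ np.prod(special.ndtr(z), axis=1))


_RHO_MAX = 0.995


def calibrate_equicorrelation(marginals, bundle_target: float) -> float:
    """Solve for the equicorrelation reproducing the published bundle proportion.

    The joint probability is increasing in the correlation, from the
    independence product up to (nearly) the smallest marginal; targets outside
    that range are clamped to the nearest endpoint.
    """
    lo = joint_achievement_prob(marginals, 0.0)
    hi = joint_achievement_prob(marginals, _RHO_MAX)
    if bundle_target <= lo:
        return 0.0
    if bundle_target >= hi:
        return _RHO_MAX
    return float(
        optimize.brentq(
            lambda r: joint_achievement_prob(marginals, r) - bundle_target,
            0.0,
            _RHO_MAX,
            xtol=1e-10,
        )
    )


# ---------------------------------------------------------------------------
# hospital panel


def hospital_panel(cfg: CohortConfig) -> pd.DataFrame:
    """One row per (country, hospital, financial_year) for active hospitals.

    Participation counts interpolate linearly between the start and end counts;
    hospitals are indexed so that early joiners remain in every later year,
    which makes the first ``start`` hospitals a balanced panel.
    """
    rows = []
    n_years = len(FINANCIAL_YEARS)
    for country, (start, end) in cfg.hospitals.items():
        prefix = country[0]
        width = len(str(end))
        for i, fy in enumerate(FINANCIAL_YEARS):
            count = int(round(start + (end - start) * i / (n_years - 1)))
            for h in range(count):
                rows.append(
                    {
                        "country": country,
                        "hospital": f"{prefix}{h + 1:0{width}d}",
                        "financial_year": fy,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generation


def _apply_overrides(cal: CalibrationTable, overrides) -> CalibrationTable:
    for (country, fy, measure), delta in overrides.items():
        cal = cal.with_effect(country, [fy], delta, measure=measure)
    return cal


def _cell_rho(cfg: CohortConfig, cal: CalibrationTable, country: str, fy: int) -> float:
    if cfg.correlation is None:
        crits = bundle_criteria(fy)
        ps = [cal.prob(country, fy, c) for c in crits]
        return calibrate_equicorrelation(ps, cal.prob(country, fy, "bundle"))
    if isinstance(cfg.correlation, Mapping):
        return float(cfg.correlation[(country, fy)])
    return float(cfg.correlation)


def generate_cohort(
    cal: CalibrationTable,
    marg: CovariateMarginals,
    cfg: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate one synthetic cohort (one row per patient admission).

    Deterministic for a given (calibration, marginals, config, seed): cells
    are generated in a fixed (country, financial year) order from a single
    seeded generator stream.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cal = _apply_overrides(cal, cfg.effect_overrides)
    panel = hospital_panel(cfg)

    # persistent hospital intercepts, shared across years and criteria
    hospitals = panel["hospital"].unique()
    u_h = dict(zip(hospitals, rng.standard_normal(len(hospitals))))

    frames = []
    pid = 0
    for country in COUNTRIES:
        n_cell = cfg.cell_size(country)
        for fy in FINANCIAL_YEARS:
            active = panel.query("country == @country and financial_year == @fy")["hospital"].to_numpy()
            weights = rng.gamma(cfg.dispersion, size=len(active))
            counts = rng.multinomial(n_cell, weights / weights.sum())
            hosp_col = np.repeat(active, counts)

            rho_tot = _cell_rho(cfg, cal, country, fy)
            a = min(cfg.hospital_icc, rho_tot)  # hospital share cannot exceed the total
            b = rho_tot - a

            probs = np.array([cal.prob(country, fy, c) for c in CRITERIA])
            # clip away exact 0/1 only for threshold arithmetic; inf is fine in ndtri
            with np.errstate(divide="ignore"):
                thresholds = special.ndtri(probs)

            u = np.array([u_h[h] for h in hosp_col])
            z = rng.standard_normal(n_cell)
            eps = rng.standard_normal((n_cell, len(CRITERIA)))
            latent = (
                np.sqrt(a) * u[:, None]
                + np.sqrt(b) * z[:, None]
                + np.sqrt(1.0 - rho_tot) * eps
            )
            met = (latent < thresholds[None, :]).astype(np.int8)

            month_idx = rng.integers(0, 12, n_cell)
            month = np.array(_FY_MONTHS)[month_idx]
            year = np.where(month >= 4, fy, fy + 1)

            cell = {
                "patient_id": np.arange(pid, pid + n_cell),
                "hospital": hosp_col,
                "country": country,
                "financial_year": fy,
                "adm_year": year,
                "adm_month": month,
            }
            pid += n_cell
            for var in COVARIATES:
                levels = np.array(marg.levels(country, var), dtype=object)
                cell[var] = levels[
                    rng.choice(len(levels), size=n_cell, p=marg.probabilities(country, var))
                ]
            for j, crit in enumerate(CRITERIA):
                cell[crit] = met[:, j]
            frames.append(pd.DataFrame(cell))

    df = pd.concat(frames, ignore_index=True)
    df["date"] = pd.to_datetime(
        {"year": df["adm_year"], "month": df["adm_month"], "day": 1}
    )
    return df


def apply_missingness(
    records: pd.DataFrame, cfg: CohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Mask covariates completely at random; criterion indicators are never masked.

    The configured country rate is the *row-level* share of patients with at
    least one masked covariate; each maskable field is masked independently at
    the per-field rate ``1 - (1 - rate)**(1/n_fields)`` so the row-level share
    matches. Masked values become NA and a ``<var>_missing`` flag is added.
    """
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    df = records.copy()
    k = len(cfg.maskable)
    for var in cfg.maskable:
        df[f"{var}_missing"] = False
    for country, rate in cfg.missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate must lie in [0, 1], got {rate}")
        idx = df.index[df["country"] == country]
        r_field = 1.0 - (1.0 - rate) ** (1.0 / k) if k else 0.0
        for var in cfg.maskable:
            mask = rng.random(len(idx)) < r_field
            masked = idx[mask]
            df.loc[masked, var] = pd.NA
            df.loc[masked, f"{var}_missing"] = True
    return df
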