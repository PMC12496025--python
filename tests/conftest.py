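import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import carebundle as cb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calibration() -> cb.CalibrationTable:
    return cb.CalibrationTable.packaged()


@pytest.fixture(scope="session")
def marginals() -> cb.CovariateMarginals:
    return cb.CovariateMarginals.packaged()


@pytest.fixture(scope="session")
def small_cohort(calibration, marginals) -> pd.DataFrame:
    """A modest calibrated cohort with analysis columns, shared across tests."""
    cfg = cb.CohortConfig(patients_per_country_year=2000, seed=11)
    raw = cb.generate_cohort(calibration, marginals, cfg)
    rows = cb.add_analysis_columns(cb.apply_missingness(raw, cfg))
    return rows


@pytest.fixture(scope="session")
def small_cohort_main(small_cohort) -> pd.DataFrame:
    return cb.filter_sample(small_cohort, "main")
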