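import pytest

from strokecoi.models import BaseYearAmount, ClaimRecord, EconomicParameters
from strokecoi.simulate import generate_cohort, reference_config


def make_claim(**overrides) -> ClaimRecord:
    """A valid outpatient claim with explicit overrides."""
    base = dict(
        patient_id="P1",
        subtype="ischemic",
        gender="male",
        age_band="60-69",
        disposition="outpatient",
        facility="general",
        inpatient_days=0,
        covered_cost=50_000.0,
        medication_cost=10_000.0,
        year=2015,
    )
    base.update(overrides)
    return ClaimRecord(**base)


@pytest.fixture
def simple_params() -> EconomicParameters:
    """Flat, easily hand-checkable parameter set."""
    bands = ["0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"]
    return EconomicParameters(
        cpi_index={2010: 100.0, 2015: 110.0},
        round_trip_fare=21_000.0,
        caregiver_daily_rate_base=BaseYearAmount(amount=60_000.0, base_year=2010),
        noncovered_ratio_inpatient=0.2,
        noncovered_ratio_outpatient=0.1,
        annual_income={b: 30_000_000.0 for b in bands},
        employment_rate={b: 0.6 for b in bands},
    )


@pytest.fixture(scope="session")
def reference_cohort_10k():
    """One seeded 10 000-patient cohort under the 2015 study conditions."""
    config = reference_config(n_patients=10_000, seed=0)
    claims, mortality = generate_cohort(config)
    return config, claims, mortality
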