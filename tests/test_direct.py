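"""Direct cost components: arithmetic, CPI adjustment, linearity, additivity."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from strokecoi.direct import (
    assistive_device_cost,
    caregiver_cost,
    covered_treatment_costs,
    cpi_adjust,
    inpatient_days_by_subtype,
    medication_costs,
    noncovered_costs,
    outpatient_visits_by_subtype,
    transportation_cost,
)
from strokecoi.models import ParameterError, claims_to_frame
from strokecoi.simulate import generate_cohort, reference_config

from .conftest import make_claim


class TestCoveredAndMedication:
    def test_split_by_disposition(self):
        claims = [
            make_claim(disposition="inpatient", inpatient_days=3, covered_cost=1_000_000),
            make_claim(disposition="inpatient", inpatient_days=5, covered_cost=1_000_000),
            make_claim(covered_cost=50_000),
        ]
        inpatient, outpatient = covered_treatment_costs(claims)
        assert inpatient.amount("ischemic") == 2_000_000
        assert outpatient.amount("ischemic") == 50_000
        assert inpatient.amount("hemorrhagic") == 0

    def test_empty_claims_give_zeros(self):
        inpatient, outpatient = covered_treatment_costs([])
        assert inpatient.total == outpatient.total == 0
        assert medication_costs([]).total == 0

    def test_sums_equal_brute_force_row_oracle(self):
        claims, _ = generate_cohort(reference_config(n_patients=25, seed=11))
        records = list(claims.itertuples(index=False))
        inpatient, outpatient = covered_treatment_costs(claims)
        medication = medication_costs(claims)
        for subtype in ("ischemic", "hemorrhagic"):
            rows = [r for r in records if r.subtype == subtype]
            assert inpatient.amount(subtype) == pytest.approx(
                sum(r.covered_cost for r in rows if r.disposition == "inpatient")
            )
            assert outpatient.amount(subtype) == pytest.approx(
                sum(r.covered_cost for r in rows if r.disposition == "outpatient")
            )
            assert medication.amount(subtype) == pytest.approx(
                sum(r.medication_cost for r in rows)
            )

    def test_medication_sums_per_subtype(self):
        claims = [
            make_claim(medication_cost=10),
            make_claim(medication_cost=20),
            make_claim(medication_cost=30, subtype="hemorrhagic"),
        ]
        comp = medication_costs(claims)
        assert comp.amount("ischemic") == 30
        assert comp.amount("hemorrhagic") == 30


class TestNoncovered:
    def test_zero_ratios_give_zero(self, simple_params):
        params = simple_params.model_copy(
            update={"noncovered_ratio_inpatient": 0.0, "noncovered_ratio_outpatient": 0.0}
        )
        comp = noncovered_costs({"ischemic": 100.0}, {"ischemic": 100.0}, params)
        assert comp.total == 0

    def test_ratio_arithmetic(self, simple_params):
        # ratios (0.2, 0.1) on covered (100, 100) -> 30
        comp = noncovered_costs({"ischemic": 100.0}, {"ischemic": 100.0}, simple_params)
        assert comp.amount("ischemic") == pytest.approx(30.0)

    def test_published_ledger_ratio_inverts_exactly(self, simple_params):
        # the all-stroke ratio implied by the published ledger recovers the
        # printed non-covered total when applied forward
        ratio = 354_489 / (1_898_241 + 114_285)
        params = simple_params.model_copy(
            update={
                "noncovered_ratio_inpatient": ratio,
                "noncovered_ratio_outpatient": ratio,
            }
        )
        comp = noncovered_costs(
            {"ischemic": 1_898_241.0}, {"ischemic": 114_285.0}, params
        )
        assert comp.amount("ischemic") == pytest.approx(354_489.0, abs=1e-6)


class TestUnitCostComponents:
    def test_assistive_zero_patients(self, simple_params):
        assert assistive_device_cost({}, simple_params).total == 0

    def test_assistive_flat_cpi_identity(self, simple_params):
        params = simple_params.model_copy(
            update={"cpi_index": {2010: 100.0, 2015: 100.0}}
        )
        comp = assistive_device_cost({"ischemic": 1000}, params)
        assert comp.amount("ischemic") == pytest.approx(241_512_000.0)

    def test_assistive_missing_cpi_year_names_it(self, simple_params):
        params = simple_params.model_copy(update={"cpi_index": {2015: 110.0}})
        with pytest.raises(ParameterError, match="2010"):
            assistive_device_cost({"ischemic": 1}, params)

    def test_transportation_examples(self, simple_params):
        assert transportation_cost({}, simple_params).total == 0
        comp = transportation_cost({"ischemic": 1_000_000}, simple_params)
        assert comp.amount("ischemic") == 21_000_000_000  # 21 000 million KRW

    def test_transportation_reproduces_published_row(self, simple_params):
        # 57 387 million / 21 000 = ischemic outpatient visit-claims; forward
        # multiplication returns the printed row
        visits = 57_387e6 / 21_000
        comp = transportation_cost({"ischemic": visits}, simple_params)
        assert comp.amount("ischemic") == pytest.approx(57_387e6)

    def test_caregiver_flat_cpi_arithmetic(self, simple_params):
        params = simple_params.model_copy(
            update={"cpi_index": {2010: 100.0, 2015: 100.0}}
        )
        comp = caregiver_cost({"ischemic": 10}, params)
        assert comp.amount("ischemic") == pytest.approx(600_000.0)

    @settings(
        max_examples=50, deadline=None, derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(days=st.floats(0, 1e6, allow_nan=False))
    def test_caregiver_output_over_rate_is_exactly_days(self, simple_params, days):
        comp = caregiver_cost({"ischemic": days}, simple_params)
        rate = 60_000.0 * 110.0 / 100.0
        assert comp.amount("ischemic") / rate == pytest.approx(days, rel=1e-12, abs=1e-9)


class TestCpiAdjust:
    def test_identity_same_year(self):
        assert cpi_adjust(123.0, 2015, 2015, {2015: 104.2}) == 123.0

    def test_index_ratio_arithmetic(self):
        assert cpi_adjust(200.0, 2010, 2015, {2010: 100.0, 2015: 123.5}) == pytest.approx(247.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        amount=st.floats(0, 1e12, allow_nan=False),
        ia=st.floats(1, 1e4, allow_nan=False),
        ib=st.floats(1, 1e4, allow_nan=False),
    )
    def test_round_trip_is_identity(self, amount, ia, ib):
        index = {2010: ia, 2015: ib}
        back = cpi_adjust(cpi_adjust(amount, 2010, 2015, index), 2015, 2010, index)
        assert back == pytest.approx(amount, rel=1e-12, abs=1e-9)

    def test_missing_year_is_named(self):
        with pytest.raises(ParameterError, match="2011"):
            cpi_adjust(1.0, 2011, 2015, {2015: 110.0})


class TestLinearityAndAdditivity:
    def test_components_are_homogeneous_in_their_unit_cost(self, simple_params):
        doubled = simple_params.model_copy(
            update={
                "round_trip_fare": simple_params.round_trip_fare * 2,
                "noncovered_ratio_inpatient": simple_params.noncovered_ratio_inpatient * 2,
                "noncovered_ratio_outpatient": simple_params.noncovered_ratio_outpatient * 2,
            }
        )
        visits = {"ischemic": 123.0, "hemorrhagic": 45.0}
        assert (
            transportation_cost(visits, doubled).total
            == 2 * transportation_cost(visits, simple_params).total
        )
        covered_in, covered_out = {"ischemic": 1e6}, {"ischemic": 2e5}
        assert noncovered_costs(covered_in, covered_out, doubled).total == pytest.approx(
            2 * noncovered_costs(covered_in, covered_out, simple_params).total
        )

    def test_additive_over_disjoint_claim_subsets(self):
        claims, _ = generate_cohort(reference_config(n_patients=40, seed=13))
        frame = claims_to_frame(claims)
        first, second = frame.iloc[:100], frame.iloc[100:]
        for aggregate in (outpatient_visits_by_subtype, inpatient_days_by_subtype):
            whole = aggregate(frame)
            split = aggregate(first)
            for subtype, value in aggregate(second).items():
                split[subtype] += value
            assert split == whole
        inpatient_whole, _ = covered_treatment_costs(frame)
        inpatient_a, _ = covered_treatment_costs(first)
        inpatient_b, _ = covered_treatment_costs(second)
        for s in ("ischemic", "hemorrhagic"):
            assert inpatient_whole.amount(s) == pytest.approx(
                inpatient_a.amount(s) + inpatient_b.amount(s)
            )
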