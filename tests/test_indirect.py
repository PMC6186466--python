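"""Indirect productivity losses: the 1/3-day rule, income boundaries,
loop oracles, and the product vs present-value conventions."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from strokecoi.indirect import morbidity_loss, mortality_loss, total_indirect
from strokecoi.models import (
    BaseYearAmount,
    EconomicParameters,
    MortalityTable,
    ParameterError,
)

BANDS = ("20-29", "30-39", "40-49", "50-59", "60-69")


def params_with(income, employment, **overrides):
    all_bands = ["0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"]
    defaults = dict(
        cpi_index={2010: 100.0, 2015: 110.0},
        caregiver_daily_rate_base=BaseYearAmount(amount=60_000.0, base_year=2010),
        noncovered_ratio_inpatient=0.1,
        noncovered_ratio_outpatient=0.1,
        annual_income={b: income.get(b, 0.0) for b in all_bands},
        employment_rate={b: employment.get(b, 0.0) for b in all_bands},
    )
    defaults.update(overrides)
    return EconomicParameters(**defaults)


class TestMorbidityLoss:
    def test_three_visits_equal_one_inpatient_day(self):
        params = params_with({"60-69": 90_000.0 * 365}, {"60-69": 1.0})
        visits = morbidity_loss({}, {("ischemic", "60-69"): 3.0}, params)
        days = morbidity_loss({("ischemic", "60-69"): 1.0}, {}, params)
        assert visits.amount("ischemic") == pytest.approx(90_000.0)
        assert visits.amount("ischemic") == pytest.approx(days.amount("ischemic"))

    def test_person_time_beyond_retirement_earns_nothing(self):
        params = params_with({"80+": 30e6}, {"80+": 0.9})
        comp = morbidity_loss(
            {("ischemic", "80+"): 100.0}, {("ischemic", "80+"): 300.0}, params
        )
        assert comp.total == 0.0

    @settings(
        max_examples=200, deadline=None, derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        days=st.lists(st.floats(0, 500, allow_nan=False), min_size=5, max_size=5),
        visits=st.lists(st.floats(0, 2000, allow_nan=False), min_size=5, max_size=5),
        incomes=st.lists(st.floats(0, 1e8, allow_nan=False), min_size=5, max_size=5),
        rates=st.lists(st.floats(0, 1, allow_nan=False), min_size=5, max_size=5),
    )
    def test_equals_brute_force_double_loop(self, days, visits, incomes, rates):
        params = params_with(dict(zip(BANDS, incomes)), dict(zip(BANDS, rates)))
        day_map = {("ischemic", b): d for b, d in zip(BANDS, days)}
        visit_map = {("ischemic", b): v for b, v in zip(BANDS, visits)}
        comp = morbidity_loss(day_map, visit_map, params)
        expected = 0.0
        for b, d, v, income, rate in zip(BANDS, days, visits, incomes, rates):
            expected += (d + v / 3.0) * (income / 365.0) * rate
        assert comp.amount("ischemic") == pytest.approx(expected, rel=1e-12, abs=1e-6)

    def test_missing_band_in_income_map_is_an_error(self):
        params = params_with({"60-69": 30e6}, {"60-69": 0.5})
        trimmed = params.model_copy(
            update={"annual_income": {"60-69": 30e6}}  # other bands dropped
        )
        with pytest.raises(ParameterError, match="50-59"):
            morbidity_loss({("ischemic", "50-59"): 1.0}, {}, trimmed)


class TestMortalityLoss:
    def test_product_formula_spot_value(self):
        params = params_with({"60-69": 30e6}, {"60-69": 0.6})
        table = MortalityTable.from_records([("ischemic", "60-69", 10, 5.0)])
        comp = mortality_loss(table, params, mode="product")
        assert comp.amount("ischemic") == pytest.approx(10 * 5.0 * 30e6 * 0.6)  # 9e8

    @pytest.mark.parametrize("mode", ["product", "present_value"])
    def test_deaths_at_70_plus_carry_no_income(self, mode):
        params = params_with({"70-79": 30e6, "80+": 20e6}, {"70-79": 0.5, "80+": 0.2})
        table = MortalityTable.from_records(
            [("ischemic", "70-79", 50, 13.0), ("hemorrhagic", "80+", 20, 7.0)]
        )
        assert mortality_loss(table, params, mode=mode).total == 0.0

    def test_present_value_matches_product_at_zero_discount_within_band(self):
        # lost years stay inside the 60-69 band and below retirement
        params = params_with({"60-69": 30e6}, {"60-69": 0.6})
        table = MortalityTable.from_records([("ischemic", "60-69", 7, 3.5)])
        product = mortality_loss(table, params, mode="product")
        pv = mortality_loss(table, params, mode="present_value")
        assert pv.amount("ischemic") == pytest.approx(product.amount("ischemic"))

    def test_discounting_never_increases_the_loss(self):
        base = params_with({"40-49": 40e6, "50-59": 37e6, "60-69": 25e6},
                           {"40-49": 0.8, "50-59": 0.7, "60-69": 0.4})
        discounted = base.model_copy(update={"discount_rate": 0.05})
        table = MortalityTable.from_records([("ischemic", "40-49", 12, 20.0)])
        pv0 = mortality_loss(table, base, mode="present_value").total
        pv5 = mortality_loss(table, discounted, mode="present_value").total
        assert pv5 <= pv0

    def test_present_value_truncates_at_retirement_and_crosses_bands(self):
        # death at midpoint 65 with 10 lost years: only ages 65..69 earn
        params = params_with({"60-69": 30e6, "70-79": 50e6}, {"60-69": 0.5, "70-79": 0.9})
        table = MortalityTable.from_records([("ischemic", "60-69", 1, 10.0)])
        pv = mortality_loss(table, params, mode="present_value")
        assert pv.amount("ischemic") == pytest.approx(5 * 30e6 * 0.5)

    def test_monotone_in_each_product_factor(self):
        base = params_with({"50-59": 30e6}, {"50-59": 0.5})
        table = MortalityTable.from_records([("ischemic", "50-59", 10, 5.0)])
        reference = mortality_loss(table, base, mode="product").total
        more_deaths = MortalityTable.from_records([("ischemic", "50-59", 11, 5.0)])
        longer = MortalityTable.from_records([("ischemic", "50-59", 10, 6.0)])
        richer = params_with({"50-59": 31e6}, {"50-59": 0.5})
        busier = params_with({"50-59": 30e6}, {"50-59": 0.6})
        assert mortality_loss(more_deaths, base, mode="product").total >= reference
        assert mortality_loss(longer, base, mode="product").total >= reference
        assert mortality_loss(table, richer, mode="product").total >= reference
        assert mortality_loss(table, busier, mode="product").total >= reference

    def test_unknown_mode_rejected(self):
        params = params_with({}, {})
        table = MortalityTable.from_records([("ischemic", "60-69", 1, 1.0)])
        with pytest.raises(ValueError, match="mode"):
            mortality_loss(table, params, mode="median")

    def test_zero_employment_kills_both_losses(self):
        params = params_with({b: 30e6 for b in BANDS}, {b: 0.0 for b in BANDS})
        table = MortalityTable.from_records([("ischemic", b, 5, 10.0) for b in BANDS])
        assert mortality_loss(table, params).total == 0.0
        day_map = {("ischemic", b): 10.0 for b in BANDS}
        assert morbidity_loss(day_map, {}, params).total == 0.0


class TestTotalIndirect:
    def test_published_all_stroke_row_sums_exactly(self):
        from strokecoi.direct import CostComponent

        morbidity = CostComponent("morbidity_loss", {"ischemic": 802_005.0})
        mortality = CostComponent("mortality_loss", {"ischemic": 3_402_329.0})
        total = total_indirect(morbidity, mortality)
        assert total["ischemic"] == 4_204_334.0

    def test_published_ischemic_row_within_printed_rounding(self):
        from strokecoi.direct import CostComponent

        morbidity = CostComponent("morbidity_loss", {"ischemic": 607_442.0})
        mortality = CostComponent("mortality_loss", {"ischemic": 881_203.0})
        total = total_indirect(morbidity, mortality)
        assert abs(total["ischemic"] - 1_488_646.0) <= 1.0
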