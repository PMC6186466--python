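"""Indirect (productivity) costs under the human-capital approach.

Morbidity loss values the work time absorbed by care episodes: one
inpatient day costs one work day, one outpatient visit costs a configurable
fraction of a work day (default 1/3, so three visits equal one day's
hospitalization), priced at the age band's daily earnings times its
employment rate. Premature-mortality loss values each death as its lost
life-years times the annual expected income and employment rate at the age
of death. Ages below ``working_age_min`` (20) and at or above
``retirement_age`` (70) carry no income in either loss.

``mortality_loss`` offers two conventions: ``product`` — the plain
deaths x lost-years x income x employment multiplication; and
``present_value`` — a year-by-year earnings stream from the band midpoint
age, truncated at retirement and discounted at ``discount_rate``. With a
zero discount rate and lost years that stay inside one age band (and below
retirement), the two coincide.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .direct import CostComponent
from .models import (
    AGE_BAND_MIDPOINTS,
    AGE_BANDS,
    ClaimRecord,
    Disposition,
    EconomicParameters,
    MortalityTable,
    ParameterError,
    Subtype,
    age_band_of,
    claims_to_frame,
)

__all__ = [
    "morbidity_loss",
    "mortality_loss",
    "total_indirect",
    "care_time_by_age_and_subtype",
]

_SUBTYPES = (Subtype.ischemic.value, Subtype.hemorrhagic.value)


def _check_band_coverage(params: EconomicParameters, bands: Iterable[str]) -> None:
    for band in bands:
        if band not in params.annual_income:
            raise ParameterError(f"annual_income missing age band {band!r}")
        if band not in params.employment_rate:
            raise ParameterError(f"employment_rate missing age band {band!r}")


def care_time_by_age_and_subtype(
    claims: Iterable[ClaimRecord] | pd.DataFrame,
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Aggregate (inpatient days, outpatient visits) keyed by (subtype, age band)."""
    frame = claims_to_frame(claims)
    days: dict[tuple[str, str], float] = {}
    visits: dict[tuple[str, str], float] = {}
    inp = frame.loc[frame["disposition"] == Disposition.inpatient.value]
    out = frame.loc[frame["disposition"] == Disposition.outpatient.value]
    day_sum = inp.groupby(["subtype", "age_band"], observed=True)["inpatient_days"].sum()
    visit_n = out.groupby(["subtype", "age_band"], observed=True).size()
    for s in _SUBTYPES:
        for b in AGE_BANDS:
            days[(s, b)] = float(day_sum.get((s, b), 0.0))
            visits[(s, b)] = float(visit_n.get((s, b), 0.0))
    return days, visits


def morbidity_loss(
    inpatient_days: Mapping[tuple[str, str], float],
    outpatient_visits: Mapping[tuple[str, str], float],
    params: EconomicParameters,
) -> CostComponent:
    """Earnings lost to care episodes, per subtype.

    Inputs are keyed by (subtype, age band); missing keys count as zero
    person-time, but every band with nonzero person-time must be covered by
    the income and employment maps.
    """
    used_bands = {b for (_, b), v in {**inpatient_days, **outpatient_visits}.items() if v}
    _check_band_coverage(params, used_bands)

    amounts = {}
    for s in _SUBTYPES:
        total = 0.0
        for b in AGE_BANDS:
            days = float(inpatient_days.get((s, b), 0.0))
            visits = float(outpatient_visits.get((s, b), 0.0))
            if days < 0 or visits < 0:
                raise ValueError(f"negative person-time for {s}/{b}")
            workdays = days + params.outpatient_day_fraction * visits
            if workdays == 0.0 or not params.band_has_income(b):
                continue
            total += (
                workdays * params.daily_earnings(b) * params.employment_rate[b]
            )
        amounts[s] = total
    return CostComponent("morbidity_loss", amounts)


def _pv_earnings_per_death(
    band: str, lost_years: float, params: EconomicParameters
) -> float:
    """Discounted earnings stream for one death at the band midpoint age."""
    start = AGE_BAND_MIDPOINTS[band]
    total = 0.0
    t = 0
    while t < lost_years:
        age = start + t
        if age >= params.retirement_age:
            break
        weight = min(1.0, lost_years - t)  # partial final year
        b = age_band_of(age)
        if params.band_has_income(b) and age >= params.working_age_min:
            income = params.annual_income.get(b)
            emp = params.employment_rate.get(b)
            if income is None or emp is None:
                raise ParameterError(f"income/employment missing age band {b!r}")
            total += weight * income * emp / (1.0 + params.discount_rate) ** t
        t += 1
    return total


def mortality_loss(
    mortality: MortalityTable,
    params: EconomicParameters,
    mode: str = "product",
) -> CostComponent:
    """Premature-death earnings loss per subtype.

    mode="product": deaths x lost_years x annual income x employment rate,
    with zero income for bands entirely outside working ages. This is the
    reference analysis's stated formula. mode="present_value": year-by-year
    earnings from the band midpoint age, truncated at retirement and
    discounted; age-specific incomes apply as the lost years cross bands.
    """
    if mode not in ("product", "present_value"):
        raise ValueError(f"unknown mortality_loss mode {mode!r}")
    frame = mortality.frame
    active = frame.loc[frame["deaths"].astype(float) > 0, "age_band"]
    _check_band_coverage(params, set(active))

    amounts = {s: 0.0 for s in _SUBTYPES}
    for row in frame.itertuples(index=False):
        deaths = float(row.deaths)
        if deaths == 0:
            continue
        band = row.age_band
        lost = float(row.lost_years)
        if mode == "product":
            if not params.band_has_income(band):
                continue
            value = lost * params.annual_income[band] * params.employment_rate[band]
        else:
            value = _pv_earnings_per_death(band, lost, params)
        amounts[row.subtype] = amounts.get(row.subtype, 0.0) + deaths * value
    return CostComponent("mortality_loss", {s: amounts.get(s, 0.0) for s in _SUBTYPES})


def total_indirect(morbidity: CostComponent, mortality: CostComponent) -> dict[str, float]:
    """Indirect subtotal: elementwise sum of the two losses, per subtype."""
    return {
        s: morbidity.amount_by_subtype[s] + mortality.amount_by_subtype[s]
        for s in _SUBTYPES
    }
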