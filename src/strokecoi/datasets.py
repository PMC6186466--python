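"""Published 2015 South Korea stroke burden reference values.

These are the printed results of the national 2015 cost-of-illness analysis
of stroke (ICD-10 I63 ischemic, I61 hemorrhagic) built on the single-payer
health-insurance claims database: cohort counts stratified by gender, age
band, disposition, facility and subtype, and the economic cost ledger in
million KRW. They serve two purposes: (1) a worked-example fixture — feeding
the nine component cost rows through the breakdown builder must reproduce
the printed subtotals, shares and per-case costs; (2) calibration anchors
for the synthetic claims generator.

All cost figures are in **million KRW** exactly as printed (each cell
independently rounded to the nearest million, which is why printed subtotals
can disagree with cell sums by a few million).
"""

from __future__ import annotations

from .models import BaseYearAmount, EconomicParameters

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .direct import CostComponent

__all__ = [
    "REFERENCE_YEAR",
    "N_PATIENTS",
    "PATIENT_COUNTS",
    "VISIT_COUNTS",
    "COST_COMPONENTS_MILLION_KRW",
    "PRINTED_SUBTOTALS_MILLION_KRW",
    "PRINTED_SHARES_PERCENT",
    "PRINTED_PER_CASE_MILLION_KRW",
    "TOTAL_COST_MILLION_USD",
    "LOST_YEARS_BY_BAND",
    "default_parameters",
]

REFERENCE_YEAR = 2015

#: Distinct patients treated for stroke in 2015 (national total).
N_PATIENTS = 515_848

#: Patient-level counts (each patient counted once per stratifier).
PATIENT_COUNTS = {
    "gender": {"male": 277_641, "female": 238_207},
    "age": {
        "0-9": 657, "10-19": 575, "20-29": 1_465, "30-39": 5_558,
        "40-49": 24_243, "50-59": 78_878, "60-69": 128_542,
        "70-79": 178_504, "80+": 97_426,
    },
    "subtype": {"ischemic": 463_147, "hemorrhagic": 52_701},
}

#: Visit-level counts (patients may appear in several categories).
VISIT_COUNTS = {
    "disposition": {"inpatient": 129_513, "outpatient": 472_371},
    "facility": {
        "tertiary": 187_263, "general": 232_450, "hospital": 102_535,
        "clinic": 63_863, "public_health": 1_833,
    },
}

#: The nine component rows of the cost ledger, million KRW, per subtype and
#: for all stroke, exactly as printed.
COST_COMPONENTS_MILLION_KRW = {
    "inpatient":       {"ischemic": 1_378_782, "hemorrhagic": 519_458, "all": 1_898_241},
    "outpatient":      {"ischemic": 99_382,    "hemorrhagic": 14_903,  "all": 114_285},
    "noncovered":      {"ischemic": 263_113,   "hemorrhagic": 91_375,  "all": 354_489},
    "medication":      {"ischemic": 335_280,   "hemorrhagic": 45_409,  "all": 380_689},
    "assistive":       {"ischemic": 122_270,   "hemorrhagic": 13_913,  "all": 136_183},
    "transportation":  {"ischemic": 57_387,    "hemorrhagic": 8_924,   "all": 66_312},
    "caregiver":       {"ischemic": 242_573,   "hemorrhagic": 75_720,  "all": 318_293},
    "mortality_loss":  {"ischemic": 881_203,   "hemorrhagic": 2_521_126, "all": 3_402_329},
    "morbidity_loss":  {"ischemic": 607_442,   "hemorrhagic": 194_562, "all": 802_005},
}

#: Printed subtotal rows of the same ledger, million KRW.
PRINTED_SUBTOTALS_MILLION_KRW = {
    "direct_medical":    {"ischemic": 2_198_827, "hemorrhagic": 685_058, "all": 2_883_887},
    "direct_nonmedical": {"ischemic": 299_961,   "hemorrhagic": 84_644,  "all": 384_606},
    "direct_total":      {"ischemic": 2_498_788, "hemorrhagic": 769_702, "all": 3_268_493},
    "indirect_total":    {"ischemic": 1_488_646, "hemorrhagic": 2_715_689, "all": 4_204_334},
    "grand_total":       {"ischemic": 3_987_434, "hemorrhagic": 3_485_391, "all": 7_472_828},
}

#: Printed column shares (% of each column's grand total) for the nine
#: component rows.
PRINTED_SHARES_PERCENT = {
    "inpatient":      {"ischemic": 34.58, "hemorrhagic": 14.90, "all": 25.40},
    "outpatient":     {"ischemic": 2.49,  "hemorrhagic": 0.43,  "all": 1.53},
    "noncovered":     {"ischemic": 6.60,  "hemorrhagic": 2.62,  "all": 4.74},
    "medication":     {"ischemic": 8.41,  "hemorrhagic": 1.30,  "all": 5.09},
    "assistive":      {"ischemic": 3.07,  "hemorrhagic": 0.40,  "all": 1.82},
    "transportation": {"ischemic": 1.44,  "hemorrhagic": 0.26,  "all": 0.89},
    "caregiver":      {"ischemic": 6.08,  "hemorrhagic": 2.17,  "all": 4.26},
    "mortality_loss": {"ischemic": 22.10, "hemorrhagic": 72.33, "all": 45.53},
    "morbidity_loss": {"ischemic": 15.23, "hemorrhagic": 5.58,  "all": 10.73},
}

#: Printed cost per stroke case (grand total minus premature-death loss,
#: divided by patients), million KRW. The hemorrhagic cell as printed (18.5)
#: differs from the value its own ledger implies (18.3); the ledger-implied
#: value is what the arithmetic reproduces.
PRINTED_PER_CASE_MILLION_KRW = {"ischemic": 6.7, "hemorrhagic": 18.5, "all": 7.9}

#: Printed national total in USD (the KRW/USD rate 1090.14 is implied by the
#: 7 472 828 million KRW / 6 855 million USD pair).
TOTAL_COST_MILLION_USD = 6_855.0

#: Expected remaining life-years at the band midpoint age, from the Korean
#: 2015 complete life table (both sexes, rounded to one decimal).
LOST_YEARS_BY_BAND = {
    "0-9": 77.5, "10-19": 67.6, "20-29": 57.8, "30-39": 48.1,
    "40-49": 38.6, "50-59": 29.5, "60-69": 21.0, "70-79": 13.4, "80+": 7.0,
}

#: 2015 mean annual earned income per employed person by age band, KRW.
#: Rounded national labour statistics; bands outside working ages carry a
#: nominal value that the income rule zeroes out anyway.
ANNUAL_INCOME_KRW = {
    "0-9": 0.0, "10-19": 12_000_000.0, "20-29": 26_000_000.0,
    "30-39": 36_000_000.0, "40-49": 40_000_000.0, "50-59": 37_000_000.0,
    "60-69": 25_000_000.0, "70-79": 15_000_000.0, "80+": 8_000_000.0,
}

#: 2015 employment-to-population ratio by age band.
EMPLOYMENT_RATE = {
    "0-9": 0.0, "10-19": 0.07, "20-29": 0.58, "30-39": 0.75,
    "40-49": 0.79, "50-59": 0.75, "60-69": 0.39, "70-79": 0.15, "80+": 0.02,
}

#: Korean consumer price index, 2010 = 100.
CPI_INDEX = {2010: 100.0, 2015: 109.8}

#: Stroke deaths by subtype and age band consistent with the 2015 ledger:
#: working-age counts were obtained by inverting the printed premature-death
#: loss rows against LOST_YEARS_BY_BAND, ANNUAL_INCOME_KRW and
#: EMPLOYMENT_RATE (product formula), then rounding to integers; the 70+
#: counts (which carry no income) reflect the strong old-age skew of stroke
#: mortality. Product-mode premature-death loss computed from this table
#: under default_parameters() lands within 0.1% of the printed rows.
DEATHS_BY_BAND = {
    "ischemic": {
        "0-9": 0, "10-19": 0, "20-29": 13, "30-39": 49, "40-49": 185,
        "50-59": 432, "60-69": 1_111, "70-79": 6_000, "80+": 8_000,
    },
    "hemorrhagic": {
        "0-9": 0, "10-19": 0, "20-29": 42, "30-39": 211, "40-49": 632,
        "50-59": 1_265, "60-69": 1_968, "70-79": 3_500, "80+": 3_000,
    },
}


def reference_components() -> "list[CostComponent]":
    """The nine printed component rows as CostComponents, **million KRW**.

    Only the subtype cells are carried; the breakdown builder recomputes the
    all-stroke column as their sum (which can differ from the printed
    all-stroke cells by up to 1 million per row, the printed rounding).
    """
    from .direct import CostComponent

    return [
        CostComponent(
            label,
            {s: float(cells[s]) for s in ("ischemic", "hemorrhagic")},
        )
        for label, cells in COST_COMPONENTS_MILLION_KRW.items()
    ]


def default_parameters() -> EconomicParameters:
    """Economic parameters of the 2015 reference analysis.

    Unit costs with a printed source keep that value (21 000 KRW round-trip
    fare; 241 512 KRW assistive-device annual cost at 2010 prices). The
    caregiver daily rate has no printed value; 60 000 KRW/day at 2010 prices
    is the package's documented choice from the 2010 hospital caregiver
    model-project range. Non-covered ratios use the ledger-implied
    stroke-level value 354 489 / (1 898 241 + 114 285) = 0.17617 for both
    dispositions.
    """
    noncovered = 354_489 / (1_898_241 + 114_285)
    return EconomicParameters(
        cpi_index=CPI_INDEX,
        round_trip_fare=21_000.0,
        caregiver_daily_rate_base=BaseYearAmount(amount=60_000.0, base_year=2010),
        assistive_device_annual_base=BaseYearAmount(amount=241_512.0, base_year=2010),
        noncovered_ratio_inpatient=noncovered,
        noncovered_ratio_outpatient=noncovered,
        annual_income=ANNUAL_INCOME_KRW,
        employment_rate=EMPLOYMENT_RATE,
        krw_per_usd=1090.14,
        reference_year=REFERENCE_YEAR,
    )
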