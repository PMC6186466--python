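"""Direct cost components of the stroke cost-of-illness model.

Direct medical costs: covered inpatient and outpatient treatment (insurer
payment plus legal copay, summed straight off the claim lines), the
non-covered allotment (a ratio applied to covered totals per disposition,
because it comes from an external out-of-pocket survey rather than claims),
medication incl. pharmacy use, and assistive devices (an annual per-patient
cost CPI-adjusted from its 2010 base). Direct non-medical costs:
transportation (a flat round-trip fare per outpatient visit-claim) and paid
caregivers (a CPI-adjusted daily rate per inpatient day).

Every component is linear in its unit cost and additive over disjoint claim
subsets; all outputs are keyed by stroke subtype in unrounded KRW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .models import (
    ClaimRecord,
    Disposition,
    EconomicParameters,
    ParameterError,
    Subtype,
    claims_to_frame,
)

__all__ = [
    "COMPONENT_LABELS",
    "CostComponent",
    "cpi_adjust",
    "covered_treatment_costs",
    "noncovered_costs",
    "medication_costs",
    "assistive_device_cost",
    "transportation_cost",
    "caregiver_cost",
    "patient_counts_by_subtype",
    "outpatient_visits_by_subtype",
    "inpatient_days_by_subtype",
]

#: The nine cost rows of the full breakdown, in ledger order.
COMPONENT_LABELS = (
    "inpatient",
    "outpatient",
    "noncovered",
    "medication",
    "assistive",
    "transportation",
    "caregiver",
    "mortality_loss",
    "morbidity_loss",
)

_SUBTYPES = (Subtype.ischemic.value, Subtype.hemorrhagic.value)


@dataclass(frozen=True)
class CostComponent:
    """A labeled monetary amount per stroke subtype (KRW, unrounded)."""

    label: str
    amount_by_subtype: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.label not in COMPONENT_LABELS:
            raise ValueError(f"unknown component label {self.label!r}")
        object.__setattr__(
            self,
            "amount_by_subtype",
            {s: float(self.amount_by_subtype.get(s, 0.0)) for s in _SUBTYPES},
        )
        for s, v in self.amount_by_subtype.items():
            if v < 0:
                raise ValueError(f"negative amount for {self.label}/{s}")

    def amount(self, subtype: Subtype | str) -> float:
        s = subtype.value if isinstance(subtype, Subtype) else subtype
        return self.amount_by_subtype[s]

    @property
    def total(self) -> float:
        """All-stroke amount: the sum over subtypes."""
        return sum(self.amount_by_subtype.values())


def cpi_adjust(
    amount: float, from_year: int, to_year: int, cpi_index: Mapping[int, float]
) -> float:
    """Re-express a KRW amount in another year's prices via the CPI index ratio."""
    for year in (from_year, to_year):
        if year not in cpi_index:
            raise ParameterError(f"cpi_index missing year {year}")
        if cpi_index[year] <= 0:
            raise ParameterError(f"cpi_index[{year}] must be positive")
    return amount * cpi_index[to_year] / cpi_index[from_year]


def _sum_by_subtype(frame: pd.DataFrame, column: str) -> dict[str, float]:
    grouped = frame.groupby("subtype", observed=True)[column].sum()
    return {s: float(grouped.get(s, 0.0)) for s in _SUBTYPES}


def covered_treatment_costs(
    claims: Iterable[ClaimRecord] | pd.DataFrame,
) -> tuple[CostComponent, CostComponent]:
    """Sum covered treatment cost over claims, split by disposition.

    Returns the (inpatient, outpatient) components.
    """
    frame = claims_to_frame(claims)
    parts = {}
    for disposition in (Disposition.inpatient, Disposition.outpatient):
        sub = frame.loc[frame["disposition"] == disposition.value]
        parts[disposition.value] = CostComponent(
            disposition.value, _sum_by_subtype(sub, "covered_cost")
        )
    return parts["inpatient"], parts["outpatient"]


def noncovered_costs(
    covered_inpatient: Mapping[str, float],
    covered_outpatient: Mapping[str, float],
    params: EconomicParameters,
) -> CostComponent:
    """Out-of-pocket non-covered care as ratios on covered totals."""
    for name, ratio in (
        ("noncovered_ratio_inpatient", params.noncovered_ratio_inpatient),
        ("noncovered_ratio_outpatient", params.noncovered_ratio_outpatient),
    ):
        if ratio < 0:
            raise ParameterError(f"{name} must be nonnegative")
    amounts = {
        s: params.noncovered_ratio_inpatient * float(covered_inpatient.get(s, 0.0))
        + params.noncovered_ratio_outpatient * float(covered_outpatient.get(s, 0.0))
        for s in _SUBTYPES
    }
    return CostComponent("noncovered", amounts)


def medication_costs(claims: Iterable[ClaimRecord] | pd.DataFrame) -> CostComponent:
    """Medication plus pharmacy-use cost summed off the claim lines."""
    frame = claims_to_frame(claims)
    return CostComponent("medication", _sum_by_subtype(frame, "medication_cost"))


def assistive_device_cost(
    n_patients_by_subtype: Mapping[str, float], params: EconomicParameters
) -> CostComponent:
    """Annual assistive-device upkeep per patient, CPI-adjusted to the reference year."""
    base = params.assistive_device_annual_base
    per_patient = cpi_adjust(
        base.amount, base.base_year, params.reference_year, params.cpi_index
    )
    amounts = {
        s: per_patient * float(n_patients_by_subtype.get(s, 0.0)) for s in _SUBTYPES
    }
    return CostComponent("assistive", amounts)


def transportation_cost(
    n_outpatient_visits_by_subtype: Mapping[str, float], params: EconomicParameters
) -> CostComponent:
    """Round-trip fare times the number of outpatient visit-claims."""
    if params.round_trip_fare <= 0:
        raise ParameterError("round_trip_fare must be positive")
    amounts = {
        s: params.round_trip_fare * float(n_outpatient_visits_by_subtype.get(s, 0.0))
        for s in _SUBTYPES
    }
    return CostComponent("transportation", amounts)


def caregiver_cost(
    inpatient_days_by_subtype: Mapping[str, float], params: EconomicParameters
) -> CostComponent:
    """CPI-adjusted daily caregiver rate times total inpatient days."""
    base = params.caregiver_daily_rate_base
    daily = cpi_adjust(
        base.amount, base.base_year, params.reference_year, params.cpi_index
    )
    amounts = {
        s: daily * float(inpatient_days_by_subtype.get(s, 0.0)) for s in _SUBTYPES
    }
    return CostComponent("caregiver", amounts)


# --- aggregation helpers feeding the unit-cost components


def patient_counts_by_subtype(
    claims: Iterable[ClaimRecord] | pd.DataFrame,
) -> dict[str, int]:
    """Distinct patients per subtype (a mixed-subtype patient counts in both)."""
    frame = claims_to_frame(claims)
    dedup = frame.loc[:, ["patient_id", "subtype"]].drop_duplicates()
    counts = dedup["subtype"].value_counts()
    return {s: int(counts.get(s, 0)) for s in _SUBTYPES}


def outpatient_visits_by_subtype(
    claims: Iterable[ClaimRecord] | pd.DataFrame,
) -> dict[str, int]:
    """Outpatient visit-claim lines per subtype."""
    frame = claims_to_frame(claims)
    sub = frame.loc[frame["disposition"] == Disposition.outpatient.value]
    counts = sub["subtype"].value_counts()
    return {s: int(counts.get(s, 0)) for s in _SUBTYPES}


def inpatient_days_by_subtype(
    claims: Iterable[ClaimRecord] | pd.DataFrame,
) -> dict[str, float]:
    """Total inpatient days per subtype."""
    frame = claims_to_frame(claims)
    sub = frame.loc[frame["disposition"] == Disposition.inpatient.value]
    return _sum_by_subtype(sub, "inpatient_days")
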