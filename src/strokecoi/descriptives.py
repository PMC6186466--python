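"""Stratified cohort summaries: patient counts, visit counts, shares, ratios.

Gender, age and subtype are tallied over distinct patients; disposition and
facility are tallied over claim lines (a patient with three outpatient
visits contributes three to the outpatient row), matching how national
claims statistics report "visits" versus "cases". A patient carrying claims
of both stroke subtypes is counted once in each subtype's patient count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .models import (
    AGE_BANDS,
    ClaimRecord,
    Disposition,
    Facility,
    Gender,
    Subtype,
    claims_to_frame,
)
from .rounding import round_half_up

__all__ = ["CohortSummary", "summarize_cohort", "category_ratio"]

PATIENT_STRATIFIERS = {
    "gender": [g.value for g in Gender],
    "age": list(AGE_BANDS),
    "subtype": [s.value for s in Subtype],
}
VISIT_STRATIFIERS = {
    "disposition": [d.value for d in Disposition],
    "facility": [f.value for f in Facility],
}
_COLUMN_OF = {"gender": "gender", "age": "age_band", "subtype": "subtype",
              "disposition": "disposition", "facility": "facility"}


@dataclass(frozen=True)
class CohortSummary:
    """Counts and percentage shares per stratifier and category.

    ``patient_counts`` / ``visit_counts`` map (stratifier, category) to a
    (count, percent) pair; percent is None when the stratifier total is
    zero. Percents are rounded half-up to 2 decimals and sum to 100 within
    0.05 inside each stratifier.
    """

    patient_counts: dict[tuple[str, str], tuple[int, float | None]]
    visit_counts: dict[tuple[str, str], tuple[int, float | None]]
    n_patients: int
    n_visits_by_stratifier: dict[str, int]

    def count(self, stratifier: str, category: str) -> int:
        table = self.patient_counts if stratifier in PATIENT_STRATIFIERS else self.visit_counts
        return table[(stratifier, category)][0]

    def percent(self, stratifier: str, category: str) -> float | None:
        table = self.patient_counts if stratifier in PATIENT_STRATIFIERS else self.visit_counts
        return table[(stratifier, category)][1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: stratifier, category, count, percent."""
        rows = [
            {"stratifier": s, "category": c, "count": n, "percent": p}
            for table in (self.patient_counts, self.visit_counts)
            for (s, c), (n, p) in table.items()
        ]
        return pd.DataFrame(rows, columns=["stratifier", "category", "count", "percent"])


def _tally(series: pd.Series, categories: list[str]) -> dict[str, int]:
    counts = series.value_counts()
    return {c: int(counts.get(c, 0)) for c in categories}


def summarize_cohort(claims: Iterable[ClaimRecord] | pd.DataFrame) -> CohortSummary:
    """Stratified counts and shares for a validated claims collection.

    Invariant to claim row order. An empty collection yields zero counts
    with percents omitted (None).
    """
    frame = claims_to_frame(claims)

    patient_counts: dict[tuple[str, str], tuple[int, float | None]] = {}
    visit_counts: dict[tuple[str, str], tuple[int, float | None]] = {}

    # patient-level: one row per distinct (patient, category) pair
    for strat, categories in PATIENT_STRATIFIERS.items():
        col = _COLUMN_OF[strat]
        dedup = frame.loc[:, ["patient_id", col]].drop_duplicates()
        counts = _tally(dedup[col], categories)
        total = sum(counts.values())
        for cat in categories:
            pct = round_half_up(100.0 * counts[cat] / total, 2) if total else None
            patient_counts[(strat, cat)] = (counts[cat], pct)

    n_visits: dict[str, int] = {}
    for strat, categories in VISIT_STRATIFIERS.items():
        col = _COLUMN_OF[strat]
        counts = _tally(frame[col], categories)
        total = sum(counts.values())
        n_visits[strat] = total
        for cat in categories:
            pct = round_half_up(100.0 * counts[cat] / total, 2) if total else None
            visit_counts[(strat, cat)] = (counts[cat], pct)

    return CohortSummary(
        patient_counts=patient_counts,
        visit_counts=visit_counts,
        n_patients=int(frame["patient_id"].nunique()),
        n_visits_by_stratifier=n_visits,
    )


def category_ratio(count_a: float, count_b: float, decimals: int = 1) -> float:
    """How many times larger category A is than B, rounded half-up.

    E.g. 463147 ischemic vs 52701 hemorrhagic patients -> 8.8.
    """
    if count_b == 0:
        raise ZeroDivisionError("category_ratio undefined for a zero denominator")
    return round_half_up(count_a / count_b, decimals)
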