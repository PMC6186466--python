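"""Cost breakdown assembly, per-case costs, currency conversion, rendering.

The breakdown is the full cost ledger: nine component rows (five direct
medical, two direct non-medical, two indirect) with subtotals and
percentage shares per column — one column per stroke subtype plus an
all-stroke column that is always the elementwise subtype sum. All internal
arithmetic stays in unrounded input units; rounding to million KRW happens
only when a table is rendered. (The published tables were rounded cell by
cell before summing, which is why their printed subtotals can disagree
with their own cells by a few million — computing unrounded avoids ever
creating such inconsistencies.)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .descriptives import CohortSummary
from .direct import COMPONENT_LABELS, CostComponent
from .models import EconomicParameters, ParameterError, Subtype
from .rounding import round_half_up

__all__ = [
    "COLUMNS",
    "SUBTOTAL_ROWS",
    "CostBreakdown",
    "build_cost_breakdown",
    "per_case_cost",
    "krw_to_usd",
    "usd_to_krw",
    "render_tables",
]

_SUBTYPES = (Subtype.ischemic.value, Subtype.hemorrhagic.value)
#: Ledger columns: the two subtypes and their sum.
COLUMNS = (*_SUBTYPES, "all")

#: Subtotal rows, in ledger order, with the component rows they sum.
SUBTOTAL_ROWS: dict[str, tuple[str, ...]] = {
    "direct_medical": ("inpatient", "outpatient", "noncovered", "medication", "assistive"),
    "direct_nonmedical": ("transportation", "caregiver"),
    "direct_total": (
        "inpatient", "outpatient", "noncovered", "medication", "assistive",
        "transportation", "caregiver",
    ),
    "indirect_total": ("mortality_loss", "morbidity_loss"),
    "grand_total": COMPONENT_LABELS,
}


@dataclass(frozen=True)
class CostBreakdown:
    """The assembled ledger: component amounts, subtotals, and column shares.

    ``amounts`` maps (row, column) to the unrounded amount for every
    component and subtotal row; ``shares`` maps the same keys to the row's
    percent of that column's grand total, rounded half-up to 2 decimals
    (None for an all-zero column).
    """

    components: tuple[CostComponent, ...]
    amounts: dict[tuple[str, str], float]
    shares: dict[tuple[str, str], float | None]

    def amount(self, row: str, column: str = "all") -> float:
        return self.amounts[(row, column)]

    def share(self, row: str, column: str = "all") -> float | None:
        return self.shares[(row, column)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format ledger: row, column, amount, share_percent."""
        rows = [
            {
                "row": r,
                "column": c,
                "amount": self.amounts[(r, c)],
                "share_percent": self.shares[(r, c)],
            }
            for r in (*COMPONENT_LABELS, *SUBTOTAL_ROWS)
            for c in COLUMNS
        ]
        return pd.DataFrame(rows)


def build_cost_breakdown(components: Iterable[CostComponent]) -> CostBreakdown:
    """Assemble the ledger from exactly the nine component rows.

    Unit-agnostic: amounts come out in whatever unit the components carry
    (the pipeline feeds KRW; the packaged reference ledger is million KRW).
    """
    comps = tuple(components)
    labels = [c.label for c in comps]
    for label in COMPONENT_LABELS:
        n = labels.count(label)
        if n == 0:
            raise ValueError(f"missing component {label!r}")
        if n > 1:
            raise ValueError(f"duplicate component {label!r}")
    extra = set(labels) - set(COMPONENT_LABELS)
    if extra:
        raise ValueError(f"unknown component(s): {sorted(extra)}")
    by_label = {c.label: c for c in comps}
    ordered = tuple(by_label[label] for label in COMPONENT_LABELS)

    amounts: dict[tuple[str, str], float] = {}
    for label, comp in by_label.items():
        for s in _SUBTYPES:
            amounts[(label, s)] = comp.amount_by_subtype[s]
        amounts[(label, "all")] = comp.total
    for row, parts in SUBTOTAL_ROWS.items():
        for c in COLUMNS:
            amounts[(row, c)] = sum(amounts[(p, c)] for p in parts)

    shares: dict[tuple[str, str], float | None] = {}
    for c in COLUMNS:
        grand = amounts[("grand_total", c)]
        for row in (*COMPONENT_LABELS, *SUBTOTAL_ROWS):
            shares[(row, c)] = (
                round_half_up(100.0 * amounts[(row, c)] / grand, 2) if grand else None
            )
    return CostBreakdown(components=ordered, amounts=amounts, shares=shares)


def per_case_cost(
    grand_total: float,
    mortality_loss: float,
    n_patients: int,
    decimals: int = 1,
) -> float:
    """Average cost per stroke case, million KRW.

    The premature-death loss is excluded before dividing by the patient
    count (deaths are not treatment cases). Inputs are KRW; the result is
    million KRW rounded half-up to ``decimals``.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if mortality_loss > grand_total:
        raise ValueError("mortality_loss cannot exceed grand_total")
    return round_half_up((grand_total - mortality_loss) / n_patients / 1e6, decimals)


def krw_to_usd(amount: float, params: EconomicParameters) -> float:
    """Convert KRW to USD at the parameter exchange rate."""
    if params.krw_per_usd <= 0:
        raise ParameterError("krw_per_usd must be positive")
    return amount / params.krw_per_usd


def usd_to_krw(amount: float, params: EconomicParameters) -> float:
    """Convert USD back to KRW at the parameter exchange rate."""
    if params.krw_per_usd <= 0:
        raise ParameterError("krw_per_usd must be positive")
    return amount * params.krw_per_usd


# --- rendering


def _md_table(headers: Sequence[str], rows: Sequence[Sequence[object]]) -> str:
    def fmt(v: object) -> str:
        return "" if v is None else str(v)

    lines = [
        "| " + " | ".join(headers) + " |",
        "| " + " | ".join("---" for _ in headers) + " |",
    ]
    lines += ["| " + " | ".join(fmt(v) for v in row) + " |" for row in rows]
    return "\n".join(lines) + "\n"


def _million(amount_krw: float) -> int:
    return int(round_half_up(amount_krw / 1e6, 0))


_ROW_TITLES = {
    "inpatient": "Inpatient costs",
    "outpatient": "Outpatient costs",
    "noncovered": "Non-covered care costs",
    "medication": "Medication costs",
    "assistive": "Assistive devices costs",
    "transportation": "Transportation costs",
    "caregiver": "Caregiver's costs",
    "mortality_loss": "Lost productivity, premature death",
    "morbidity_loss": "Lost productivity, care episodes",
    "direct_medical": "Total direct medical costs",
    "direct_nonmedical": "Total direct non-medical costs",
    "direct_total": "Total direct costs",
    "indirect_total": "Total indirect costs",
    "grand_total": "Total costs",
}


def render_tables(
    summary: CohortSummary,
    breakdown: CostBreakdown,
    per_case: Mapping[str, float],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the cohort, cost and per-case tables as CSV plus a Markdown report.

    ``breakdown`` amounts must be KRW; monetary cells are printed in
    million KRW (integers), percents to 2 decimals, per-case costs (a
    mapping column -> million KRW) to 1 decimal. Pure function of its
    inputs: identical inputs yield identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "table1_cohort.csv",
        "costs": out / "table2_costs.csv",
        "per_case": out / "table3_per_case.csv",
        "report": out / "report.md",
    }

    cohort = summary.to_frame()
    cohort.to_csv(paths["cohort"], index=False)

    ledger_rows = []
    for row in (*COMPONENT_LABELS, *SUBTOTAL_ROWS):
        entry: dict[str, object] = {"row": row}
        for c in COLUMNS:
            entry[f"{c}_million_krw"] = _million(breakdown.amount(row, c))
            entry[f"{c}_percent"] = breakdown.share(row, c)
        ledger_rows.append(entry)
    pd.DataFrame(ledger_rows).to_csv(paths["costs"], index=False)

    pc_rows = [{"column": c, "per_case_million_krw": per_case[c]} for c in per_case]
    pd.DataFrame(pc_rows).to_csv(paths["per_case"], index=False)

    md = ["# Stroke cost-of-illness report", ""]
    md += ["## Cohort characteristics", ""]
    md.append(
        _md_table(
            ["Stratifier", "Category", "Count", "%"],
            [
                (s, c, n, p)
                for table in (summary.patient_counts, summary.visit_counts)
                for (s, c), (n, p) in table.items()
            ],
        )
    )
    md += ["## Economic costs (million KRW, % of column total)", ""]
    md.append(
        _md_table(
            ["Cost item", *(f"{c} (M KRW)" for c in COLUMNS), *(f"{c} %" for c in COLUMNS)],
            [
                (
                    _ROW_TITLES[row],
                    *(_million(breakdown.amount(row, c)) for c in COLUMNS),
                    *(breakdown.share(row, c) for c in COLUMNS),
                )
                for row in (*COMPONENT_LABELS, *SUBTOTAL_ROWS)
            ],
        )
    )
    md += ["## Costs per stroke case (million KRW)", ""]
    md.append(_md_table(["Column", "Per case"], [(c, per_case[c]) for c in per_case]))
    paths["report"].write_text("\n".join(md), encoding="utf-8")
    return paths
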