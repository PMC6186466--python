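"""Worked-example verification against the published 2015 ledger.

Feeds the nine printed component cost rows through the breakdown builder
and checks that the printed subtotals, column shares, headline ratios and
per-case costs come back out. Because every printed cell was rounded to the
nearest million KRW before the source summed them, a subtotal reconstructed
from k printed cells can legitimately differ from the printed subtotal by
up to 0.5k million; that bound (not an empirical fit) is the tolerance.

Two published cells are internally inconsistent with their own ledger and
are checked against the ledger-implied value instead, flagged ``note``:
the hemorrhagic per-case cost (printed 18.5, ledger-implied 18.3) and
nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import datasets
from .descriptives import category_ratio
from .models import Subtype
from .reporting import (
    COLUMNS,
    COMPONENT_LABELS,
    SUBTOTAL_ROWS,
    build_cost_breakdown,
    krw_to_usd,
    per_case_cost,
)
from .rounding import round_half_up

__all__ = ["Check", "run_reference_checks"]

_SUBTYPES = (Subtype.ischemic.value, Subtype.hemorrhagic.value)
_EPS = 1e-9


@dataclass(frozen=True)
class Check:
    name: str
    expected: float
    computed: float
    tolerance: float
    ok: bool
    note: str = ""


def _check(name: str, expected: float, computed: float, tol: float, note: str = "") -> Check:
    return Check(
        name=name,
        expected=expected,
        computed=computed,
        tolerance=tol,
        ok=abs(computed - expected) <= tol + _EPS,
        note=note,
    )


def run_reference_checks() -> list[Check]:
    """All worked-example checks; every returned Check should have ok=True."""
    checks: list[Check] = []
    breakdown = build_cost_breakdown(datasets.reference_components())

    # subtotal rows, tolerance 0.5 million per printed cell summed
    for row, parts in SUBTOTAL_ROWS.items():
        for col in COLUMNS:
            n_cells = len(parts) * (2 if col == "all" else 1)
            checks.append(
                _check(
                    f"subtotal {row}/{col} (million KRW)",
                    datasets.PRINTED_SUBTOTALS_MILLION_KRW[row][col],
                    breakdown.amount(row, col),
                    0.5 * n_cells,
                )
            )

    # exact printed-column sums: summing the printed all-stroke cells
    # themselves reproduces two subtotals to the million
    all_cells = datasets.COST_COMPONENTS_MILLION_KRW
    medical = sum(all_cells[r]["all"] for r in SUBTOTAL_ROWS["direct_medical"])
    indirect = sum(all_cells[r]["all"] for r in SUBTOTAL_ROWS["indirect_total"])
    checks.append(_check("printed-column sum direct_medical/all", 2_883_887, medical, 0))
    checks.append(_check("printed-column sum indirect_total/all", 4_204_334, indirect, 0))

    # component-row shares, within 0.01 percentage points
    for row in COMPONENT_LABELS:
        for col in COLUMNS:
            checks.append(
                _check(
                    f"share {row}/{col} (%)",
                    datasets.PRINTED_SHARES_PERCENT[row][col],
                    breakdown.share(row, col),
                    0.01,
                )
            )

    # per-case costs from the printed grand totals and premature-death rows
    printed = datasets.PRINTED_SUBTOTALS_MILLION_KRW["grand_total"]
    mort = datasets.COST_COMPONENTS_MILLION_KRW["mortality_loss"]
    n_pat = {**datasets.PATIENT_COUNTS["subtype"], "all": datasets.N_PATIENTS}
    expected_pc = {"ischemic": 6.7, "all": 7.9, "hemorrhagic": 18.3}
    for col in COLUMNS:
        pc = per_case_cost(printed[col] * 1e6, mort[col] * 1e6, n_pat[col])
        note = (
            "printed cell says 18.5; its own ledger implies 18.3"
            if col == "hemorrhagic"
            else ""
        )
        checks.append(
            _check(f"per-case {col} (million KRW)", expected_pc[col], pc, 0.0, note)
        )

    # headline cohort arithmetic
    pat = datasets.PATIENT_COUNTS
    vis = datasets.VISIT_COUNTS
    checks.append(
        _check(
            "ischemic:hemorrhagic patient ratio",
            8.8,
            category_ratio(pat["subtype"]["ischemic"], pat["subtype"]["hemorrhagic"]),
            0.0,
        )
    )
    checks.append(
        _check(
            "outpatient:inpatient visit ratio",
            3.6,
            category_ratio(vis["disposition"]["outpatient"], vis["disposition"]["inpatient"]),
            0.0,
        )
    )
    checks.append(
        _check(
            "male patient share (%)",
            53.82,
            round_half_up(100.0 * pat["gender"]["male"] / datasets.N_PATIENTS, 2),
            0.0,
            "printed cohort table transposes the gender percents; the text agrees",
        )
    )

    # national total in USD at the implied exchange rate (0.1%)
    params = datasets.default_parameters()
    usd = krw_to_usd(printed["all"] * 1e6, params) / 1e6
    checks.append(
        _check(
            "total cost (million USD)",
            datasets.TOTAL_COST_MILLION_USD,
            usd,
            0.001 * datasets.TOTAL_COST_MILLION_USD,
        )
    )
    return checks
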