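"""End-to-end orchestration: claims + mortality + parameters -> cost report.

``estimate`` is the in-memory pipeline used by tests and scripts;
``run_pipeline`` wraps it with file I/O, rendering, and a machine-readable
results JSON whose grand total always equals the component sum at full
precision (the ledger is computed unrounded and subtotalled once).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import direct, indirect
from .descriptives import CohortSummary, summarize_cohort
from .models import (
    EconomicParameters,
    MortalityTable,
    read_claims,
    read_mortality,
    read_parameters,
)
from .reporting import (
    COLUMNS,
    COMPONENT_LABELS,
    SUBTOTAL_ROWS,
    CostBreakdown,
    build_cost_breakdown,
    krw_to_usd,
    per_case_cost,
    render_tables,
)

__all__ = ["estimate", "run_pipeline", "RESULTS_SCHEMA_VERSION"]

RESULTS_SCHEMA_VERSION = 1

logger = logging.getLogger("strokecoi")


def estimate(
    claims: pd.DataFrame,
    mortality: MortalityTable,
    params: EconomicParameters,
    mortality_mode: str = "product",
) -> dict:
    """Run every cost stage on validated inputs.

    Returns a dict with the cohort summary, the nine components, the
    assembled breakdown (KRW), and per-case costs (million KRW) per column.
    """
    summary = summarize_cohort(claims)

    inpatient, outpatient = direct.covered_treatment_costs(claims)
    noncovered = direct.noncovered_costs(
        inpatient.amount_by_subtype, outpatient.amount_by_subtype, params
    )
    medication = direct.medication_costs(claims)
    assistive = direct.assistive_device_cost(
        direct.patient_counts_by_subtype(claims), params
    )
    transportation = direct.transportation_cost(
        direct.outpatient_visits_by_subtype(claims), params
    )
    caregiver = direct.caregiver_cost(direct.inpatient_days_by_subtype(claims), params)

    days, visits = indirect.care_time_by_age_and_subtype(claims)
    morbidity = indirect.morbidity_loss(days, visits, params)
    mort_loss = indirect.mortality_loss(mortality, params, mode=mortality_mode)

    components = [
        inpatient, outpatient, noncovered, medication, assistive,
        transportation, caregiver, mort_loss, morbidity,
    ]
    breakdown = build_cost_breakdown(components)

    # per-case denominators: distinct patients per column
    n_by_subtype = direct.patient_counts_by_subtype(claims)
    n_patients = {**n_by_subtype, "all": summary.n_patients}
    per_case = {
        c: per_case_cost(
            breakdown.amount("grand_total", c),
            breakdown.amount("mortality_loss", c),
            n_patients[c],
        )
        for c in COLUMNS
        if n_patients[c] > 0
    }
    return {
        "summary": summary,
        "components": components,
        "breakdown": breakdown,
        "per_case_million_krw": per_case,
        "n_patients": n_patients,
    }


def _results_json(
    result: Mapping, params: EconomicParameters, claims_rows: int
) -> dict:
    breakdown: CostBreakdown = result["breakdown"]
    subtotals = {
        row: {c: breakdown.amount(row, c) for c in COLUMNS}
        for row in (*COMPONENT_LABELS, *SUBTOTAL_ROWS)
    }
    return {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "n_claims": claims_rows,
        "n_patients": result["n_patients"],
        "subtotals_krw": subtotals,
        "shares_percent": {
            f"{row}/{c}": breakdown.share(row, c)
            for row in (*COMPONENT_LABELS, *SUBTOTAL_ROWS)
            for c in COLUMNS
        },
        "per_case_million_krw": result["per_case_million_krw"],
        "grand_total_usd": krw_to_usd(breakdown.amount("grand_total", "all"), params),
    }


def run_pipeline(
    claims_path: str | Path,
    mortality_path: str | Path,
    params_path: str | Path,
    out_dir: str | Path,
    mortality_mode: str = "product",
) -> dict:
    """File-to-file pipeline; writes tables, report.md and results.json.

    Raises the originating stage error (schema / validation / parameter)
    unchanged; the CLI maps these onto exit codes.
    """
    out = Path(out_dir)
    logger.info("reading claims from %s", claims_path)
    claims = read_claims(claims_path, as_frame=True)
    logger.info("read %d claim rows", len(claims))
    logger.info("reading mortality from %s", mortality_path)
    mortality = read_mortality(mortality_path)
    logger.info("reading parameters from %s", params_path)
    params = read_parameters(params_path)

    result = estimate(claims, mortality, params, mortality_mode=mortality_mode)
    paths = render_tables(
        result["summary"], result["breakdown"], result["per_case_million_krw"], out
    )
    results = _results_json(result, params, claims_rows=len(claims))
    results_path = out / "results.json"
    results_path.write_text(
        json.dumps(results, indent=2, sort_keys=True), encoding="utf-8"
    )
    paths["results"] = results_path
    logger.info("wrote %s", ", ".join(str(p) for p in paths.values()))
    result["paths"] = paths
    result["results_json"] = results
    return result
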