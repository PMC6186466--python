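"""Seeded synthetic claims generator.

The national claims database behind the 2015 stroke cost analysis is not
public, so this module generates cohorts with its published statistical
structure: subtype / gender / age-band mixes from the published cohort
table, and per-patient claim volumes and per-claim costs calibrated so
that, in expectation, every direct cost component reproduces the published
ledger (see :mod:`strokecoi.datasets`). Deaths are drawn independently of
the claim stream, mirroring the study's separate cause-of-death source.

Reproducibility contract: one ``numpy.random.default_rng(seed)`` stream,
consumed in a fixed order — patient attributes, outpatient visit counts,
inpatient days, then per-claim facilities and costs (inpatient block before
outpatient block), then deaths. The same config and seed produce
byte-identical CSV output.

Distributional choices (the source reports only totals, never per-patient
distributions): outpatient visits per patient are zero-truncated Poisson —
every patient has at least one visit; inpatient days per admission are
zero-truncated negative binomial with configurable dispersion; per-claim
costs are gamma, nonnegative by construction and rounded to whole KRW.
"""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from . import datasets
from .models import AGE_BANDS, Disposition, Facility, Gender, MortalityTable, Subtype

__all__ = [
    "ConfigError",
    "CostModel",
    "SimulationConfig",
    "reference_config",
    "generate_cohort",
]

_FACILITIES = tuple(f.value for f in Facility)
_SUBTYPES = (Subtype.ischemic.value, Subtype.hemorrhagic.value)


class ConfigError(ValueError):
    """A simulation configuration value is invalid."""


PerSubtype = Union[float, Mapping[str, float]]


def _per_subtype(value: PerSubtype, name: str) -> dict[str, float]:
    """Broadcast a scalar, or validate a per-subtype mapping."""
    if isinstance(value, Mapping):
        missing = [s for s in _SUBTYPES if s not in value]
        if missing:
            raise ConfigError(f"{name} missing subtype(s): {missing}")
        out = {s: float(value[s]) for s in _SUBTYPES}
    else:
        out = {s: float(value) for s in _SUBTYPES}
    for s, v in out.items():
        if v <= 0:
            raise ConfigError(f"{name}[{s}] must be positive")
    return out


def _check_probs(probs: Mapping[str, float], keys: tuple[str, ...], name: str) -> None:
    missing = [k for k in keys if k not in probs]
    if missing:
        raise ConfigError(f"{name} missing categories: {missing}")
    total = float(sum(probs[k] for k in keys))
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} sums to {total!r}, not 1")
    if any(probs[k] < 0 for k in keys):
        raise ConfigError(f"{name} has negative entries")


# --- calibration helpers: study-condition defaults derived once from the
# --- published 2015 tables (datasets module)

_N_REF = float(datasets.N_PATIENTS)
_P_HOSP = datasets.VISIT_COUNTS["disposition"]["inpatient"] / _N_REF


def _n_by_subtype() -> dict[str, float]:
    return {s: float(datasets.PATIENT_COUNTS["subtype"][s]) for s in _SUBTYPES}


def _visits_by_subtype() -> dict[str, float]:
    # outpatient visit-claims implied by the published transportation rows
    comp = datasets.COST_COMPONENTS_MILLION_KRW
    return {s: comp["transportation"][s] * 1e6 / 21_000.0 for s in _SUBTYPES}


def _days_by_subtype() -> dict[str, float]:
    # inpatient days implied by the published caregiver rows at the default
    # CPI-adjusted 2015 caregiver rate
    comp = datasets.COST_COMPONENTS_MILLION_KRW
    cpi = datasets.CPI_INDEX
    rate = 60_000.0 * cpi[2015] / cpi[2010]
    return {s: comp["caregiver"][s] * 1e6 / rate for s in _SUBTYPES}


def _default_age_probs() -> dict[str, float]:
    return {b: datasets.PATIENT_COUNTS["age"][b] / _N_REF for b in AGE_BANDS}


def _default_facility_probs() -> dict[str, float]:
    fac = datasets.VISIT_COUNTS["facility"]
    total = float(sum(fac.values()))
    return {f: fac[f] / total for f in _FACILITIES}


def _default_visit_means() -> dict[str, float]:
    visits, n_sub = _visits_by_subtype(), _n_by_subtype()
    return {s: visits[s] / n_sub[s] for s in _SUBTYPES}


def _default_day_means() -> dict[str, float]:
    days, n_sub = _days_by_subtype(), _n_by_subtype()
    return {s: days[s] / (n_sub[s] * _P_HOSP) for s in _SUBTYPES}


def _default_cost_model() -> "CostModel":
    comp = datasets.COST_COMPONENTS_MILLION_KRW
    visits, n_sub = _visits_by_subtype(), _n_by_subtype()
    admissions = {s: n_sub[s] * _P_HOSP for s in _SUBTYPES}
    return CostModel(
        inpatient_covered_mean={
            s: comp["inpatient"][s] * 1e6 / admissions[s] for s in _SUBTYPES
        },
        outpatient_covered_mean={
            s: comp["outpatient"][s] * 1e6 / visits[s] for s in _SUBTYPES
        },
        medication_mean={
            s: comp["medication"][s] * 1e6 / (visits[s] + admissions[s])
            for s in _SUBTYPES
        },
    )


def _default_death_rates() -> dict[str, dict[str, float]]:
    p_isch = datasets.PATIENT_COUNTS["subtype"]["ischemic"] / _N_REF
    p_subtype = {"ischemic": p_isch, "hemorrhagic": 1.0 - p_isch}
    age_probs = _default_age_probs()
    return {
        s: {
            b: (
                1000.0
                * datasets.DEATHS_BY_BAND[s][b]
                / (_N_REF * p_subtype[s] * age_probs[b])
                if age_probs[b] > 0
                else 0.0
            )
            for b in AGE_BANDS
        }
        for s in _SUBTYPES
    }


class CostModel(BaseModel):
    """Per-claim gamma cost distributions, mean KRW per subtype."""

    model_config = ConfigDict(frozen=True)

    inpatient_covered_mean: Mapping[str, float]  # per admission
    outpatient_covered_mean: Mapping[str, float]  # per visit
    medication_mean: Mapping[str, float]  # per claim line
    gamma_shape: float = Field(default=1.5, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "CostModel":
        for name in ("inpatient_covered_mean", "outpatient_covered_mean", "medication_mean"):
            _per_subtype(getattr(self, name), name)
        return self


class SimulationConfig(BaseModel):
    """Cohort structure and intensity parameters for one simulated year.

    Every default is the 2015 study condition: category probabilities are
    the published cohort counts divided by their column totals (ischemic
    463147/515848 = 0.8978, general hospital 232450/587944 = 0.3954, ...);
    visit/day intensities and per-claim cost means are the values that make
    each direct cost component match the published ledger in expectation;
    death rates are the calibrated national death counts scaled by expected
    patients per (subtype, band).
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(gt=0)
    p_ischemic: float = Field(
        default=datasets.PATIENT_COUNTS["subtype"]["ischemic"] / _N_REF, ge=0, le=1
    )
    p_male: float = Field(
        default=datasets.PATIENT_COUNTS["gender"]["male"] / _N_REF, ge=0, le=1
    )
    age_band_probs: Mapping[str, float] = Field(default_factory=_default_age_probs)
    p_patient_hospitalized: float = Field(default=_P_HOSP, ge=0, le=1)
    mean_outpatient_visits: PerSubtype = Field(default_factory=_default_visit_means)
    mean_inpatient_days: PerSubtype = Field(default_factory=_default_day_means)
    inpatient_days_dispersion: float = Field(default=1.2, gt=0)
    facility_probs: Mapping[str, float] = Field(default_factory=_default_facility_probs)
    cost_model: CostModel = Field(default_factory=_default_cost_model)
    deaths_per_1000_patients: Mapping[str, Mapping[str, float]] = Field(
        default_factory=_default_death_rates
    )
    lost_years: Mapping[str, float] = Field(
        default_factory=lambda: dict(datasets.LOST_YEARS_BY_BAND)
    )
    year: int = datasets.REFERENCE_YEAR
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        _check_probs(self.age_band_probs, AGE_BANDS, "age_band_probs")
        _check_probs(self.facility_probs, _FACILITIES, "facility_probs")
        _per_subtype(self.mean_outpatient_visits, "mean_outpatient_visits")
        _per_subtype(self.mean_inpatient_days, "mean_inpatient_days")
        for s in _SUBTYPES:
            rates = self.deaths_per_1000_patients.get(s)
            if rates is None:
                raise ConfigError(f"deaths_per_1000_patients missing subtype {s!r}")
            for band in AGE_BANDS:
                if rates.get(band, 0.0) < 0:
                    raise ConfigError(f"negative death rate for {s}/{band}")
        for band in AGE_BANDS:
            if self.lost_years.get(band, 0.0) < 0:
                raise ConfigError(f"negative lost_years for {band}")
        return self


def reference_config(n_patients: int = 10_000, seed: int = 0) -> SimulationConfig:
    """The 2015 study-condition configuration at a chosen cohort size."""
    return SimulationConfig(n_patients=n_patients, seed=seed)


def _zt_poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson draws via inverse CDF on (P(0), 1)."""
    lam = np.asarray(lam, dtype=float)
    p0 = np.exp(-lam)
    u = rng.random(lam.shape)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(np.int64)


def _zt_nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Zero-truncated negative binomial draws (size r, mean mu)."""
    mu = np.asarray(mean, dtype=float)
    r = float(dispersion)
    p = r / (r + mu)
    p0 = p**r
    u = rng.random(mu.shape)
    return stats.nbinom.ppf(p0 + u * (1.0 - p0), r, p).astype(np.int64)


def _gamma_costs(rng: np.random.Generator, mean: np.ndarray, shape: float) -> np.ndarray:
    scale = np.asarray(mean, dtype=float) / shape
    return np.round(rng.gamma(shape, scale), 0)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, MortalityTable]:
    """Draw one synthetic cohort: a claims frame plus a mortality table.

    Exactly ``n_patients`` distinct patients; every patient has at least one
    outpatient visit-claim; hospitalized patients (probability
    ``p_patient_hospitalized``) additionally have one admission claim with
    at least one inpatient day. Identical config and seed give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # 1. patient attributes
    subtype = np.where(rng.random(n) < config.p_ischemic, "ischemic", "hemorrhagic")
    gender = np.where(
        rng.random(n) < config.p_male, Gender.male.value, Gender.female.value
    )
    age_p = np.array([config.age_band_probs[b] for b in AGE_BANDS], dtype=float)
    age_band = rng.choice(np.array(AGE_BANDS, dtype=object), size=n, p=age_p / age_p.sum())
    hospitalized = rng.random(n) < config.p_patient_hospitalized

    # 2. outpatient visit counts (every patient has >= 1)
    visits_mean = _per_subtype(config.mean_outpatient_visits, "mean_outpatient_visits")
    lam = np.where(subtype == "ischemic", visits_mean["ischemic"], visits_mean["hemorrhagic"])
    n_visits = _zt_poisson(rng, lam)

    # 3. inpatient days per admission
    days_mean = _per_subtype(config.mean_inpatient_days, "mean_inpatient_days")
    mu = np.where(subtype == "ischemic", days_mean["ischemic"], days_mean["hemorrhagic"])
    hosp_idx = np.flatnonzero(hospitalized)
    inpatient_days = _zt_nbinom(rng, mu[hosp_idx], config.inpatient_days_dispersion)

    patient_ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)

    def subtype_values(mapping: Mapping[str, float], st: np.ndarray) -> np.ndarray:
        return np.where(st == "ischemic", mapping["ischemic"], mapping["hemorrhagic"])

    cm = config.cost_model
    fac_p = np.array([config.facility_probs[f] for f in _FACILITIES], dtype=float)
    fac_p = fac_p / fac_p.sum()
    facilities = np.array(_FACILITIES, dtype=object)

    # 4a. inpatient claim lines (one per hospitalized patient)
    st_in = subtype[hosp_idx]
    inpatient = pd.DataFrame(
        {
            "patient_idx": hosp_idx,
            "patient_id": patient_ids[hosp_idx],
            "subtype": st_in,
            "gender": gender[hosp_idx],
            "age_band": age_band[hosp_idx],
            "disposition": Disposition.inpatient.value,
            "facility": rng.choice(facilities, size=hosp_idx.size, p=fac_p),
            "inpatient_days": inpatient_days,
            "covered_cost": _gamma_costs(
                rng, subtype_values(cm.inpatient_covered_mean, st_in), cm.gamma_shape
            ),
            "medication_cost": _gamma_costs(
                rng, subtype_values(cm.medication_mean, st_in), cm.gamma_shape
            ),
            "year": config.year,
        }
    )

    # 4b. outpatient claim lines (one per visit)
    rep = np.repeat(np.arange(n), n_visits)
    st_out = subtype[rep]
    outpatient = pd.DataFrame(
        {
            "patient_idx": rep,
            "patient_id": patient_ids[rep],
            "subtype": st_out,
            "gender": gender[rep],
            "age_band": age_band[rep],
            "disposition": Disposition.outpatient.value,
            "facility": rng.choice(facilities, size=rep.size, p=fac_p),
            "inpatient_days": 0,
            "covered_cost": _gamma_costs(
                rng, subtype_values(cm.outpatient_covered_mean, st_out), cm.gamma_shape
            ),
            "medication_cost": _gamma_costs(
                rng, subtype_values(cm.medication_mean, st_out), cm.gamma_shape
            ),
            "year": config.year,
        }
    )

    claims = pd.concat([inpatient, outpatient], ignore_index=True)
    claims = claims.sort_values(
        ["patient_idx", "disposition"], kind="stable", ignore_index=True
    ).drop(columns="patient_idx")

    # 5. deaths, independent of the claim stream (separate vital-statistics source)
    p_subtype = {"ischemic": config.p_ischemic, "hemorrhagic": 1.0 - config.p_ischemic}
    rows = []
    for s in _SUBTYPES:
        for b in AGE_BANDS:
            rate = config.deaths_per_1000_patients[s].get(b, 0.0)
            expected = n * p_subtype[s] * config.age_band_probs[b] * rate / 1000.0
            deaths = int(rng.poisson(expected))
            rows.append((s, b, deaths, float(config.lost_years.get(b, 0.0))))
    mortality = MortalityTable.from_records(rows)

    return claims, mortality
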