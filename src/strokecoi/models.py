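"""Domain types for stroke cost-of-illness estimation, plus readers/writers.

The unit of analysis is one claim line: a single outpatient visit or a single
inpatient admission episode for a patient with a stroke main diagnosis
(cerebral infarction, ICD-10 I63, or intracerebral hemorrhage, ICD-10 I61).
Monetary amounts are carried in KRW (not million KRW) so that no rounding
happens at ingest; age is a 10-year band, the finest resolution of the
underlying claims statistics.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "AGE_BANDS",
    "Subtype",
    "Gender",
    "Disposition",
    "Facility",
    "ClaimRecord",
    "MortalityTable",
    "BaseYearAmount",
    "EconomicParameters",
    "SchemaError",
    "ClaimsValidationError",
    "ParameterError",
    "read_claims",
    "write_claims",
    "claims_to_frame",
    "frame_to_claims",
    "validate_claims_frame",
    "read_mortality",
    "read_parameters",
    "write_parameters",
]

#: Ten-year age bands used throughout: claims, mortality, income and employment.
AGE_BANDS: tuple[str, ...] = (
    "0-9", "10-19", "20-29", "30-39", "40-49",
    "50-59", "60-69", "70-79", "80+",
)

#: Integer age representing a band when a single age is needed (present-value
#: earnings): the band midpoint, with 85 standing in for the open band 80+.
AGE_BAND_MIDPOINTS: dict[str, int] = {
    "0-9": 5, "10-19": 15, "20-29": 25, "30-39": 35, "40-49": 45,
    "50-59": 55, "60-69": 65, "70-79": 75, "80+": 85,
}


def age_band_of(age: int) -> str:
    """Map an exact age in years to its 10-year band."""
    if age < 0:
        raise ValueError(f"negative age {age}")
    if age >= 80:
        return "80+"
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


class Subtype(str, enum.Enum):
    ischemic = "ischemic"
    hemorrhagic = "hemorrhagic"


class Gender(str, enum.Enum):
    male = "male"
    female = "female"


class Disposition(str, enum.Enum):
    inpatient = "inpatient"
    outpatient = "outpatient"


class Facility(str, enum.Enum):
    tertiary = "tertiary"
    general = "general"
    hospital = "hospital"
    clinic = "clinic"
    public_health = "public_health"


class SchemaError(ValueError):
    """A claims file does not have the expected columns."""


class ClaimsValidationError(ValueError):
    """One or more claim rows violate the record invariants.

    Carries *all* offending rows, not just the first, in ``errors`` as
    (row_number, message) pairs; row numbers are 1-based data rows
    (the header is row 0).
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:20])
        more = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid claim row(s): {lines}{more}")


class ParameterError(ValueError):
    """An economic parameter is missing or out of range at its point of use."""


class ClaimRecord(BaseModel):
    """One claim line: an outpatient visit or an inpatient admission episode."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    subtype: Subtype
    gender: Gender
    age_band: str
    disposition: Disposition
    facility: Facility
    inpatient_days: int = Field(ge=0)
    covered_cost: float = Field(ge=0)  # insurer-paid plus legal copay, KRW
    medication_cost: float = Field(ge=0)  # medication incl. pharmacy use, KRW
    year: int

    @model_validator(mode="after")
    def _check_invariants(self) -> "ClaimRecord":
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age_band {self.age_band!r}")
        if self.disposition is Disposition.outpatient and self.inpatient_days != 0:
            raise ValueError("outpatient claim must have inpatient_days = 0")
        if self.disposition is Disposition.inpatient and self.inpatient_days < 1:
            raise ValueError("inpatient claim must have inpatient_days >= 1")
        return self


CLAIM_COLUMNS = (
    "patient_id", "subtype", "gender", "age_band", "disposition",
    "facility", "inpatient_days", "covered_cost", "medication_cost", "year",
)


def claims_to_frame(claims: Iterable[ClaimRecord] | pd.DataFrame) -> pd.DataFrame:
    """Claims as a DataFrame with one row per claim line (order preserved)."""
    if isinstance(claims, pd.DataFrame):
        missing = [c for c in CLAIM_COLUMNS if c not in claims.columns]
        if missing:
            raise SchemaError(f"claims frame missing column(s): {', '.join(missing)}")
        return claims
    rows = [
        {k: (v.value if isinstance(v, enum.Enum) else v)
         for k, v in c.model_dump().items()}
        for c in claims
    ]
    if not rows:
        return pd.DataFrame(columns=list(CLAIM_COLUMNS))
    return pd.DataFrame(rows, columns=list(CLAIM_COLUMNS))


def frame_to_claims(frame: pd.DataFrame) -> list[ClaimRecord]:
    """Validate every row of a claims frame into ClaimRecord objects.

    All invalid rows are collected and reported together.
    """
    missing = [c for c in CLAIM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    records: list[ClaimRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        try:
            records.append(ClaimRecord(**{k: data[k] for k in CLAIM_COLUMNS}))
        except (ValidationError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                msg = "; ".join(
                    f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                    for e in exc.errors()
                )
            else:
                msg = str(exc)
            errors.append((i, msg))
    if errors:
        raise ClaimsValidationError(errors)
    return records


def validate_claims_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Frame-level validation of the ClaimRecord invariants (vectorised).

    Cheaper than building one pydantic object per row; used for large
    simulated cohorts. Raises ClaimsValidationError listing every bad row.
    """
    missing = [c for c in CLAIM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    errors: list[tuple[int, str]] = []

    def flag(mask: pd.Series, message: str) -> None:
        for idx in frame.index[mask.to_numpy()]:
            errors.append((int(idx) + 1, message))

    flag(~frame["subtype"].isin([s.value for s in Subtype]), "unknown subtype")
    flag(~frame["gender"].isin([g.value for g in Gender]), "unknown gender")
    flag(~frame["age_band"].isin(AGE_BANDS), "unknown age_band")
    flag(~frame["disposition"].isin([d.value for d in Disposition]), "unknown disposition")
    flag(~frame["facility"].isin([f.value for f in Facility]), "unknown facility")
    flag(frame["covered_cost"].astype(float) < 0, "negative covered_cost")
    flag(frame["medication_cost"].astype(float) < 0, "negative medication_cost")
    days = frame["inpatient_days"].astype(float)
    flag(days < 0, "negative inpatient_days")
    out = frame["disposition"] == Disposition.outpatient.value
    inp = frame["disposition"] == Disposition.inpatient.value
    flag(out & (days != 0), "outpatient claim must have inpatient_days = 0")
    flag(inp & (days < 1), "inpatient claim must have inpatient_days >= 1")
    if errors:
        errors.sort()
        raise ClaimsValidationError(errors)
    return frame


def read_claims(path: str | Path, *, as_frame: bool = False):
    """Read a claims CSV (UTF-8, header required) into validated records.

    Returns a list of ClaimRecord, or the validated DataFrame when
    ``as_frame`` is true. Row order is preserved.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    if as_frame:
        return validate_claims_frame(frame)
    return frame_to_claims(frame)


def write_claims(claims: Iterable[ClaimRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write claims to CSV with the canonical column order."""
    claims_to_frame(claims).to_csv(path, index=False)


@dataclass(frozen=True)
class MortalityTable:
    """Deaths and expected remaining life-years at death, per subtype and age band.

    ``lost_years`` is the life expectancy of a stroke case at the (band
    midpoint) age of death — the multiplier for premature-mortality
    earnings loss under the human-capital approach.
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("subtype", "age_band", "deaths", "lost_years")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"mortality table missing column(s): {', '.join(missing)}")
        f = self.frame
        bad = ~f["subtype"].isin([s.value for s in Subtype])
        if bad.any():
            raise ValueError(f"unknown subtype(s): {sorted(f.loc[bad, 'subtype'].unique())}")
        bad = ~f["age_band"].isin(AGE_BANDS)
        if bad.any():
            raise ValueError(f"unknown age band(s): {sorted(f.loc[bad, 'age_band'].unique())}")
        if (f["deaths"].astype(float) < 0).any():
            raise ValueError("deaths must be nonnegative")
        if (f["lost_years"].astype(float) < 0).any():
            raise ValueError("lost_years must be nonnegative")
        if f.duplicated(["subtype", "age_band"]).any():
            raise ValueError("duplicate (subtype, age_band) rows")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, float]]
    ) -> "MortalityTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    def deaths(self, subtype: Subtype | str, age_band: str) -> int:
        sel = self._row(subtype, age_band)
        return 0 if sel is None else int(sel["deaths"])

    def lost_years(self, subtype: Subtype | str, age_band: str) -> float:
        sel = self._row(subtype, age_band)
        return 0.0 if sel is None else float(sel["lost_years"])

    def _row(self, subtype, age_band):
        s = subtype.value if isinstance(subtype, Subtype) else subtype
        m = (self.frame["subtype"] == s) & (self.frame["age_band"] == age_band)
        if not m.any():
            return None
        return self.frame.loc[m].iloc[0]

    def write_csv(self, path: str | Path) -> None:
        self.frame.loc[:, list(self.COLUMNS)].to_csv(path, index=False)


def read_mortality(path: str | Path) -> MortalityTable:
    """Read a mortality CSV (subtype, age_band, deaths, lost_years)."""
    return MortalityTable(pd.read_csv(path))


class BaseYearAmount(BaseModel):
    """A KRW amount anchored to the year whose prices it is expressed in."""

    model_config = ConfigDict(frozen=True)

    amount: float = Field(ge=0)
    base_year: int


class EconomicParameters(BaseModel):
    """Unit costs, price index, and labour-market inputs for the cost model.

    Defaults reflect the 2015 reference analysis: a 21 000 KRW round trip per
    outpatient visit, a 241 512 KRW (2010 prices) annual assistive-device
    cost per patient, one outpatient visit costing one third of a work day,
    and no income below ``working_age_min`` (20) or at/above
    ``retirement_age`` (70). The caregiver daily base rate has no printed
    source value and must always be supplied.
    """

    model_config = ConfigDict(frozen=True)

    cpi_index: Mapping[int, float]
    round_trip_fare: float = Field(default=21_000.0, gt=0)
    caregiver_daily_rate_base: BaseYearAmount
    assistive_device_annual_base: BaseYearAmount = BaseYearAmount(
        amount=241_512.0, base_year=2010
    )
    noncovered_ratio_inpatient: float = Field(ge=0)
    noncovered_ratio_outpatient: float = Field(ge=0)
    annual_income: Mapping[str, float]  # age band -> KRW / year
    employment_rate: Mapping[str, float]  # age band -> [0, 1]
    working_age_min: int = 20
    retirement_age: int = 70
    outpatient_day_fraction: float = Field(default=1.0 / 3.0, gt=0)
    daily_wage_divisor: float = Field(default=365.0, gt=0)
    discount_rate: float = Field(default=0.0, ge=0)
    krw_per_usd: float = Field(default=1090.14, gt=0)
    reference_year: int = 2015

    @model_validator(mode="after")
    def _check(self) -> "EconomicParameters":
        for year, value in self.cpi_index.items():
            if value <= 0:
                raise ValueError(f"cpi_index[{year}] must be positive")
        for band, rate in self.employment_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"employment_rate[{band}] = {rate} outside [0, 1]")
        for band, income in self.annual_income.items():
            if income < 0:
                raise ValueError(f"annual_income[{band}] must be nonnegative")
        if self.working_age_min >= self.retirement_age:
            raise ValueError("working_age_min must be below retirement_age")
        return self

    def daily_earnings(self, age_band: str) -> float:
        """Daily wage for a band: annual income / divisor; 0 outside working ages."""
        if age_band not in AGE_BANDS:
            raise ParameterError(f"unknown age band {age_band!r}")
        if not self.band_has_income(age_band):
            return 0.0
        try:
            return self.annual_income[age_band] / self.daily_wage_divisor
        except KeyError:
            raise ParameterError(f"annual_income missing age band {age_band!r}") from None

    def band_has_income(self, age_band: str) -> bool:
        """Whether any age in the band falls inside [working_age_min, retirement_age)."""
        lo = AGE_BAND_MIDPOINTS[age_band] - 5 if age_band != "80+" else 80
        hi = lo + 9 if age_band != "80+" else 200
        return hi >= self.working_age_min and lo < self.retirement_age


def _parameters_from_mapping(data: Mapping) -> EconomicParameters:
    data = dict(data)
    for key in ("caregiver_daily_rate_base", "assistive_device_annual_base"):
        if key in data and isinstance(data[key], Mapping):
            data[key] = BaseYearAmount(**data[key])
    if "cpi_index" in data:
        data["cpi_index"] = {int(k): float(v) for k, v in dict(data["cpi_index"]).items()}
    try:
        return EconomicParameters(**data)
    except ValidationError as exc:
        raise ParameterError(str(exc)) from exc


def read_parameters(path: str | Path) -> EconomicParameters:
    """Read an EconomicParameters YAML or JSON file; defaults fill absent fields."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ParameterError(f"{path} does not contain a mapping")
    return _parameters_from_mapping(data)


def write_parameters(params: EconomicParameters, path: str | Path) -> None:
    """Write parameters to YAML or JSON (by extension); round-trips exactly."""
    path = Path(path)
    data = params.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
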