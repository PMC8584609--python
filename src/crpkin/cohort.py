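"""Domain types and CSV I/O for longitudinal CRP cohorts.

A cohort couples a patient covariate table with one C-reactive protein
(CRP) time series per patient.  Days are integers relative to the day of
surgery (day 0); negative days are preoperative draws.  CRP is in mg/L.

The interchange format is two plain CSV files:

* series CSV with columns ``patient_id,day,crp_mg_L``
* patients CSV with columns ``patient_id,age,sex,bmi,approach,
  indication_trauma,days_until_surgery,postop_days_in_hospital,
  infection,organism``

Sex and surgical approach are stored as the integer codes used by the
published prediction formulas (sex: 1 = male, 2 = female; approach:
1 = anterolateral Watson-Jones, 2 = posterior, 3 = lateral Bauer,
4 = anterior intrapelvic STOPPA, 5 = Kocher-Langenbeck, 6 = anterior).
Booleans are serialized as 0/1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "APPROACH_CODES",
    "CrpMeasurement",
    "CrpSeries",
    "PatientRecord",
    "CohortTable",
    "DerivedFeatures",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "postoperative_subseries",
]

#: Approach code -> surgical access route.
APPROACH_CODES = {
    1: "anterolateral (Watson-Jones)",
    2: "posterior",
    3: "lateral (Bauer)",
    4: "anterior intrapelvic (STOPPA)",
    5: "Kocher-Langenbeck",
    6: "anterior",
}

SERIES_COLUMNS = ["patient_id", "day", "crp_mg_L"]
PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "bmi",
    "approach",
    "indication_trauma",
    "days_until_surgery",
    "postop_days_in_hospital",
    "infection",
    "organism",
]


class CohortValidationError(ValueError):
    """Raised when cohort data violates a domain invariant or schema."""


@dataclass(frozen=True)
class CrpMeasurement:
    """A single CRP draw: integer day relative to surgery, value in mg/L."""

    day: int
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.day):
            raise CohortValidationError(f"day must be finite, got {self.day}")
        if not math.isfinite(self.value) or self.value < 0:
            raise CohortValidationError(
                f"CRP value must be finite and >= 0, got {self.value}"
            )


@dataclass
class CrpSeries:
    """One patient's CRP measurements, strictly increasing in day."""

    patient_id: str
    measurements: list[CrpMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [m.day for m in self.measurements]
        if len(set(days)) != len(days):
            dupes = sorted({d for d in days if days.count(d) > 1})
            raise CohortValidationError(
                f"patient {self.patient_id}: duplicate measurement days {dupes}"
            )
        self.measurements = sorted(self.measurements, key=lambda m: m.day)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self) -> Iterator[CrpMeasurement]:
        return iter(self.measurements)

    @property
    def days(self) -> list[int]:
        return [m.day for m in self.measurements]

    @property
    def values(self) -> list[float]:
        return [m.value for m in self.measurements]

    def value_on(self, day: int) -> Optional[float]:
        """Measured CRP on an exact day, or None if no draw that day."""
        for m in self.measurements:
            if m.day == day:
                return m.value
        return None

    @classmethod
    def from_pairs(cls, patient_id: str, pairs) -> "CrpSeries":
        """Build a series from ``(day, value)`` pairs or a ``{day: value}`` dict."""
        if isinstance(pairs, dict):
            pairs = pairs.items()
        return cls(patient_id, [CrpMeasurement(int(d), float(v)) for d, v in pairs])


@dataclass
class PatientRecord:
    """Covariates and outcome label for one patient.

    Encodings follow the published formulas: sex 1 = male / 2 = female,
    approach codes 1-6 (see :data:`APPROACH_CODES`).
    """

    patient_id: str
    age: float
    sex: int
    bmi: float
    approach: int
    indication_trauma: bool
    days_until_surgery: float
    postop_days_in_hospital: float
    infection: bool
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        if self.approach not in APPROACH_CODES:
            raise CohortValidationError(
                f"patient {self.patient_id}: unknown approach code {self.approach}"
            )
        if self.sex not in (1, 2):
            raise CohortValidationError(
                f"patient {self.patient_id}: sex code must be 1 or 2, got {self.sex}"
            )
        if not self.bmi > 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: BMI must be positive, got {self.bmi}"
            )
        if not self.age > 18:
            raise CohortValidationError(
                f"patient {self.patient_id}: age must exceed 18 years, got {self.age}"
            )


@dataclass
class DerivedFeatures:
    """Per-patient kinetic features feeding the prediction scores.

    ``second_peak_day`` may precede ``crp_post_max_day``: a secondary local
    maximum is second in magnitude, not necessarily second in time.
    """

    crp_preop_mean: float
    crp_preop_max: float
    crp_post_max: float
    crp_post_max_day: int
    second_peak: bool
    second_peak_day: Optional[int]
    failure_to_decline_d3: bool
    failure_to_decline_d4: bool


@dataclass
class CohortTable:
    """Patient records plus one CRP series per patient (keys must match)."""

    records: list[PatientRecord]
    series: dict[str, CrpSeries]

    def __post_init__(self) -> None:
        rec_ids = {r.patient_id for r in self.records}
        if len(rec_ids) != len(self.records):
            raise CohortValidationError("duplicate patient ids in records")
        ser_ids = set(self.series)
        if rec_ids != ser_ids:
            missing = sorted(rec_ids ^ ser_ids)
            raise CohortValidationError(
                f"records and series must cover the same patients; mismatch: {missing}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def record(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    def patients_frame(self) -> pd.DataFrame:
        """Covariate table as a DataFrame (booleans as 0/1)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": str(r.patient_id),
                    "age": float(r.age),
                    "sex": int(r.sex),
                    "bmi": float(r.bmi),
                    "approach": int(r.approach),
                    "indication_trauma": int(r.indication_trauma),
                    "days_until_surgery": float(r.days_until_surgery),
                    "postop_days_in_hospital": float(r.postop_days_in_hospital),
                    "infection": int(r.infection),
                    "organism": r.organism if r.organism is not None else "",
                }
            )
        return pd.DataFrame(rows, columns=PATIENT_COLUMNS)

    def series_frame(self) -> pd.DataFrame:
        """Long-format series table sorted by (patient_id, day)."""
        rows = [
            {"patient_id": pid, "day": m.day, "crp_mg_L": m.value}
            for pid in sorted(self.series)
            for m in self.series[pid]
        ]
        return pd.DataFrame(rows, columns=SERIES_COLUMNS)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")


def read_cohort(series_path, patients_path) -> CohortTable:
    """Read a cohort from the two-CSV interchange format.

    Rows are sorted by (patient_id, day); duplicate (patient_id, day)
    pairs and out-of-domain codes raise :class:`CohortValidationError`.
    """
    series_df = pd.read_csv(series_path, float_precision="round_trip")
    patients_df = pd.read_csv(
        patients_path, keep_default_na=False, float_precision="round_trip"
    )
    _require_columns(series_df, SERIES_COLUMNS, series_path)
    _require_columns(patients_df, PATIENT_COLUMNS, patients_path)

    dup = series_df.duplicated(subset=["patient_id", "day"])
    if dup.any():
        bad = series_df.loc[dup, ["patient_id", "day"]].iloc[0]
        raise CohortValidationError(
            f"duplicate (patient_id, day) row: ({bad['patient_id']}, {bad['day']})"
        )

    series: dict[str, CrpSeries] = {}
    for pid, grp in series_df.groupby("patient_id", sort=True):
        series[str(pid)] = CrpSeries.from_pairs(
            str(pid), zip(grp["day"].astype(int), grp["crp_mg_L"].astype(float))
        )

    records = []
    for row in patients_df.itertuples(index=False):
        organism = str(row.organism)
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                age=float(row.age),
                sex=int(row.sex),
                bmi=float(row.bmi),
                approach=int(row.approach),
                indication_trauma=bool(int(row.indication_trauma)),
                days_until_surgery=float(row.days_until_surgery),
                postop_days_in_hospital=float(row.postop_days_in_hospital),
                infection=bool(int(row.infection)),
                organism=organism if organism else None,
            )
        )
    # patients with a covariate row but no CRP rows get an empty series
    for r in records:
        series.setdefault(r.patient_id, CrpSeries(r.patient_id, []))
    return CohortTable(records=records, series=series)


def write_cohort(cohort: CohortTable, series_path, patients_path) -> None:
    """Write a cohort to the two-CSV interchange format (round-trip safe)."""
    # %.17g keeps doubles bit-identical across the round-trip
    cohort.series_frame().to_csv(series_path, index=False, float_format="%.17g")
    cohort.patients_frame().to_csv(patients_path, index=False, float_format="%.17g")


def postoperative_subseries(series: CrpSeries) -> CrpSeries:
    """Restrict a series to the postoperative window (day >= 1).

    Day 0 is the operation day and is excluded, as are preoperative draws;
    the result may be empty.  Idempotent.
    """
    return CrpSeries(
        series.patient_id, [m for m in series.measurements if m.day >= 1]
    )
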