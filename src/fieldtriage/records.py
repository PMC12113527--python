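"""Patient-level data model and the cohort CSV schema.

A cohort is carried in memory as a :class:`pandas.DataFrame` with one row
per transported patient and the column layout of :data:`COHORT_COLUMNS`;
``_1`` columns hold the first fire-department (prehospital) assessment and
``_2`` columns the in-hospital assessment.  :class:`PatientRecord` is the
record-level view used by single-patient operations and by property tests.

AVPU is the ordered consciousness scale Alert > Verbal > Pain >
Unresponsive; :func:`avpu_severity` maps a level to its derangement rank
(A=0 ... U=3), so "V or lower" means severity >= 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fieldtriage.errors import ValidationError

#: Numeric vital-sign variables, in schema order.
VITALS = ("sbp", "dbp", "pr", "rr", "bt", "spo2")

#: AVPU levels from best (Alert) to worst (Unresponsive).
AVPU_LEVELS = ("A", "V", "P", "U")

_AVPU_RANK = {level: i for i, level in enumerate(AVPU_LEVELS)}

#: Injury-type labels used for subgroup analysis.
INJURY_TYPES = ("TBI", "chest", "abdominal_pelvic", "extremity", "other")

#: Column order of the cohort CSV.
COHORT_COLUMNS = (
    ["id", "age", "sex"]
    + [f"{v}_1" for v in VITALS]
    + ["avpu_1"]
    + [f"{v}_2" for v in VITALS]
    + ["avpu_2"]
    + ["ais_codes", "iss", "injury_types", "icu", "death"]
)


def avpu_severity(level: str) -> int:
    """Rank of an AVPU level on the derangement scale (A=0, V=1, P=2, U=3)."""
    try:
        return _AVPU_RANK[level]
    except KeyError:
        raise ValidationError(f"unknown AVPU level {level!r}; expected one of {AVPU_LEVELS}")


def avpu_severity_array(values: pd.Series) -> np.ndarray:
    """Vectorized :func:`avpu_severity`; missing values map to NaN."""
    return values.map(_AVPU_RANK).to_numpy(dtype=float)


@dataclass(frozen=True)
class VitalSet:
    """One assessment of the six vitals plus AVPU; ``None`` marks missing."""

    sbp: float | None = None
    dbp: float | None = None
    pr: float | None = None
    rr: float | None = None
    bt: float | None = None
    spo2: float | None = None
    avpu: str | None = None

    def __post_init__(self) -> None:
        if self.avpu is not None and self.avpu not in _AVPU_RANK:
            raise ValidationError(f"avpu must be one of {AVPU_LEVELS}, got {self.avpu!r}")
        for name in VITALS:
            value = getattr(self, name)
            if value is not None and not np.isfinite(value):
                raise ValidationError(f"{name} must be finite or missing, got {value!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One transported trauma patient with paired assessments and outcomes."""

    id: str
    age: int
    sex: str
    prehospital: VitalSet = field(default_factory=VitalSet)
    inhospital: VitalSet = field(default_factory=VitalSet)
    ais_codes: tuple[int, ...] = ()
    iss: int | None = None
    injury_types: frozenset[str] = frozenset()
    icu_admission: bool = False
    in_hospital_death: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        unknown = set(self.injury_types) - set(INJURY_TYPES)
        if unknown:
            raise ValidationError(f"unknown injury types {sorted(unknown)}")
        if self.ais_codes and not self.injury_types:
            raise ValidationError("records with AIS codes must carry injury types")


def record_to_row(record: PatientRecord) -> dict:
    row: dict = {"id": record.id, "age": record.age, "sex": record.sex}
    for suffix, vitals in (("1", record.prehospital), ("2", record.inhospital)):
        for name in VITALS:
            row[f"{name}_{suffix}"] = getattr(vitals, name)
        row[f"avpu_{suffix}"] = vitals.avpu
    row["ais_codes"] = ";".join(str(c) for c in record.ais_codes)
    row["iss"] = record.iss
    row["injury_types"] = ";".join(sorted(record.injury_types))
    row["icu"] = int(record.icu_admission)
    row["death"] = int(record.in_hospital_death)
    return row


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Assemble the cohort DataFrame from record objects."""
    frame = pd.DataFrame([record_to_row(r) for r in records], columns=COHORT_COLUMNS)
    return frame


def _row_vitals(row: pd.Series, suffix: str) -> VitalSet:
    kwargs = {}
    for name in VITALS:
        value = row[f"{name}_{suffix}"]
        kwargs[name] = None if pd.isna(value) else float(value)
    avpu = row[f"avpu_{suffix}"]
    kwargs["avpu"] = None if pd.isna(avpu) or avpu == "" else str(avpu)
    return VitalSet(**kwargs)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Record-object view of a cohort DataFrame."""
    records = []
    for _, row in frame.iterrows():
        ais = row["ais_codes"]
        ais_codes = tuple(int(c) for c in str(ais).split(";") if c) if not pd.isna(ais) else ()
        types = row["injury_types"]
        injury = (
            frozenset(t for t in str(types).split(";") if t) if not pd.isna(types) else frozenset()
        )
        iss = None if pd.isna(row["iss"]) else int(row["iss"])
        records.append(
            PatientRecord(
                id=str(row["id"]),
                age=int(row["age"]),
                sex=str(row["sex"]),
                prehospital=_row_vitals(row, "1"),
                inhospital=_row_vitals(row, "2"),
                ais_codes=ais_codes,
                iss=iss,
                injury_types=injury,
                icu_admission=bool(row["icu"]),
                in_hospital_death=bool(row["death"]),
            )
        )
    return records


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write the cohort CSV with missing values as empty cells.

    Output is byte-identical for identical frames: floats are rendered with
    ``repr`` precision and the column order is fixed.
    """
    out = frame.reindex(columns=COHORT_COLUMNS)
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema."""
    frame = pd.read_csv(
        path, dtype={"id": str, "avpu_1": str, "avpu_2": str},
        float_precision="round_trip",
    )
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns {missing}")
    return frame.reindex(columns=COHORT_COLUMNS)


__all__ = [
    "VITALS",
    "AVPU_LEVELS",
    "INJURY_TYPES",
    "COHORT_COLUMNS",
    "avpu_severity",
    "avpu_severity_array",
    "VitalSet",
    "PatientRecord",
    "records_to_frame",
    "frame_to_records",
    "record_to_row",
    "write_cohort_csv",
    "read_cohort_csv",
]
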