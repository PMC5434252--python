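"""Patient medical record: visits, entries, and the two access structures.

A record is a patient plus a date-ordered list of visits; each visit holds
symptom observations, medication orders, and lab results, all keyed to MDS
item ids.  Two read paths mirror how patients browse their record:

* **session view** — everything recorded on one visit date, partitioned into
  the three columns "symptoms and diseases" (MDS categories ``symptoms`` and
  ``medical_history`` merged), "medication", and "lab tests";
* **topic timeline** — the chronological (date, value) series of a single
  item across visits.

Records serialize to YAML/JSON documents with ISO-8601 (``YYYY-MM-DD``)
Gregorian dates.
"""

from __future__ import annotations

import datetime as dt
import io
import math
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import RecordValidationError
from .mds_schema import MinimumDataset

EDUCATION_LEVELS = ("below_diploma", "diploma_or_above")
REGIMENS = ("drug_only", "drug_plus_insulin")


class Demographics(BaseModel):
    model_config = ConfigDict(frozen=True)

    age: int
    sex: str
    education_level: str
    years_since_diagnosis: float
    regimen: str

    @field_validator("age")
    @classmethod
    def _age(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("age must be positive")
        return v

    @field_validator("education_level")
    @classmethod
    def _edu(cls, v: str) -> str:
        if v not in EDUCATION_LEVELS:
            raise ValueError(f"education_level must be one of {EDUCATION_LEVELS}")
        return v

    @field_validator("regimen")
    @classmethod
    def _regimen(cls, v: str) -> str:
        if v not in REGIMENS:
            raise ValueError(f"regimen must be one of {REGIMENS}")
        return v

    @model_validator(mode="after")
    def _ysd(self) -> "Demographics":
        if not (0 <= self.years_since_diagnosis <= self.age):
            raise ValueError("years_since_diagnosis must be in [0, age]")
        return self


class SymptomObservation(BaseModel):
    """A symptom or disease noted at a visit (MDS symptoms/medical_history)."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    present: bool = True
    note: Optional[str] = None


class MedicationOrder(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    dose_value: float
    dose_unit: str
    frequency: str
    timing: str = ""

    @field_validator("dose_value")
    @classmethod
    def _dose(cls, v: float) -> float:
        if not (v > 0 and math.isfinite(v)):
            raise ValueError("dose_value must be positive and finite")
        return v


class LabResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    value: float
    unit: str

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("lab value must be finite")
        return v


class Visit(BaseModel):
    model_config = ConfigDict(frozen=True)

    date: dt.date
    symptoms: tuple[SymptomObservation, ...] = ()
    medications: tuple[MedicationOrder, ...] = ()
    labs: tuple[LabResult, ...] = ()

    @model_validator(mode="after")
    def _no_dup_labs(self) -> "Visit":
        seen = set()
        for lab in self.labs:
            if lab.item_id in seen:
                raise ValueError(f"duplicate lab item {lab.item_id!r} within visit {self.date}")
            seen.add(lab.item_id)
        return self

    def recorded_item_ids(self) -> list[str]:
        """Item ids recorded at this visit, in display order (symptoms, meds, labs)."""
        return (
            [s.item_id for s in self.symptoms]
            + [m.item_id for m in self.medications]
            + [l.item_id for l in self.labs]
        )


class MedicalRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    demographics: Demographics
    visits: tuple[Visit, ...] = ()

    @model_validator(mode="after")
    def _dates_increasing(self) -> "MedicalRecord":
        dates = [v.date for v in self.visits]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("visit dates must be strictly increasing")
        return self

    def visit_on(self, date: dt.date) -> Visit:
        for visit in self.visits:
            if visit.date == date:
                return visit
        available = ", ".join(v.date.isoformat() for v in self.visits) or "<none>"
        raise RecordValidationError(
            f"no visit on {date.isoformat()}; available dates: {available}"
        )


class SessionEntries(BaseModel):
    """The three named columns of the session-based view for one visit date."""

    model_config = ConfigDict(frozen=True)

    date: dt.date
    symptoms_and_diseases: tuple[SymptomObservation, ...]
    medication: tuple[MedicationOrder, ...]
    lab_tests: tuple[LabResult, ...]


class TopicTimeline(BaseModel):
    """Chronological (date, value) points for one item across visits."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    points: tuple[tuple[dt.date, float], ...]


def validate_visit(visit: Visit, mds: MinimumDataset) -> None:
    """Check every entry of a visit against the MDS; raise on the first problem."""
    when = visit.date.isoformat()
    for obs in visit.symptoms:
        if obs.item_id not in mds:
            raise RecordValidationError(f"unknown item {obs.item_id!r} in visit {when}")
        cat = mds.get(obs.item_id).category
        if cat not in ("symptoms", "medical_history"):
            raise RecordValidationError(
                f"item {obs.item_id!r} in visit {when} is {cat}, not a symptom/disease"
            )
    for order in visit.medications:
        if order.item_id not in mds:
            raise RecordValidationError(f"unknown item {order.item_id!r} in visit {when}")
        if mds.get(order.item_id).category != "medication":
            raise RecordValidationError(f"item {order.item_id!r} in visit {when} is not a medication")
    for lab in visit.labs:
        if lab.item_id not in mds:
            raise RecordValidationError(f"unknown item {lab.item_id!r} in visit {when}")
        item = mds.get(lab.item_id)
        if item.category != "lab_tests":
            raise RecordValidationError(f"item {lab.item_id!r} in visit {when} is not a lab test")
        if item.unit is not None and lab.unit != item.unit:
            raise RecordValidationError(
                f"lab {lab.item_id!r} in visit {when} has unit {lab.unit!r}, MDS unit is {item.unit!r}"
            )


def validate_record(record: MedicalRecord, mds: MinimumDataset) -> None:
    for visit in record.visits:
        validate_visit(visit, mds)


def add_visit(record: MedicalRecord, visit: Visit, mds: MinimumDataset) -> MedicalRecord:
    """Return a new record with the visit inserted in date order.

    The input record is never mutated, so on error it is trivially unchanged.
    Duplicate visit dates and item ids that do not resolve in the MDS are
    rejected.
    """
    if any(v.date == visit.date for v in record.visits):
        raise RecordValidationError(f"duplicate visit date {visit.date.isoformat()}")
    validate_visit(visit, mds)
    visits = tuple(sorted(record.visits + (visit,), key=lambda v: v.date))
    return record.model_copy(update={"visits": visits})


def session_entries(record: MedicalRecord, date: dt.date, mds: MinimumDataset) -> SessionEntries:
    """Partition one visit's entries into the three session-view columns.

    Symptom and medical-history items both land in "symptoms and diseases";
    every recorded entry appears in exactly one column.
    """
    visit = record.visit_on(date)
    validate_visit(visit, mds)
    return SessionEntries(
        date=visit.date,
        symptoms_and_diseases=visit.symptoms,
        medication=visit.medications,
        lab_tests=visit.labs,
    )


def topic_series(record: MedicalRecord, item_id: str, mds: MinimumDataset) -> TopicTimeline:
    """Chronological series of an item's recorded values across visits.

    The value is the lab result for lab items, the dose for medication
    orders, and 1.0/0.0 (present/absent) for symptom and disease flags.
    One point per visit at which the item was recorded; empty when never
    recorded.
    """
    mds.get(item_id)  # raises on unknown id
    points: list[tuple[dt.date, float]] = []
    for visit in sorted(record.visits, key=lambda v: v.date):
        for lab in visit.labs:
            if lab.item_id == item_id:
                points.append((visit.date, lab.value))
        for order in visit.medications:
            if order.item_id == item_id:
                points.append((visit.date, order.dose_value))
        for obs in visit.symptoms:
            if obs.item_id == item_id:
                points.append((visit.date, 1.0 if obs.present else 0.0))
    return TopicTimeline(item_id=item_id, points=tuple(points))


# -- serialization ------------------------------------------------------------

def record_to_dict(record: MedicalRecord) -> dict:
    doc = record.model_dump(exclude_none=True, mode="json")
    return doc


def record_from_dict(doc: dict) -> MedicalRecord:
    try:
        return MedicalRecord.model_validate(doc)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first.get("loc", ()))
        raise RecordValidationError(f"invalid record document at {loc or '<root>'}: {first['msg']}") from exc


def serialize_record(record: MedicalRecord) -> str:
    return yaml.safe_dump(record_to_dict(record), sort_keys=False, allow_unicode=True)


def load_record(source: Union[str, Path, io.IOBase]) -> MedicalRecord:
    try:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
    except OSError as exc:
        raise RecordValidationError(f"cannot read record document: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RecordValidationError(f"record document does not parse: {exc}") from exc
    if not isinstance(doc, dict):
        raise RecordValidationError("record document must be a mapping")
    return record_from_dict(doc)
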