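"""Two-tier explanation generation — the system's core computation.

For every item recorded in a patient's record the engine produces an
:class:`Explanation` with two tiers:

* a **general tier** of canned-text sections retrieved from the content
  library when the entry's applicability conditions all hold against the
  patient profile.  The level of detail deepens with exposure: the level used
  is ``min(1 + prior visits at which the item was recorded, L)``;
* a **tailored tier** rendered by fill-in-the-blank slot substitution from
  the patient's own data.  For lab items the tier additionally embeds the
  reference-range interpretation (below / within / above the normal range,
  boundaries inclusive).

``generate_document`` assembles the full personalized document: every
recorded item of every visit in date order, with items lacking library
content collected into a missing-content appendix.  Output is a pure
function of (record, library, MDS, mode) — identical inputs give
byte-identical documents.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Literal, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict

from .content_library import Condition, ContentLibrary, ContentSection, template_slots
from .errors import ConditionError, RecordValidationError, TailoringError
from .mds_schema import ItemDefinition, MinimumDataset
from .record_model import LabResult, MedicalRecord, MedicationOrder, SymptomObservation, Visit

Mode = Literal["strict", "lenient"]

_MISSING = object()


def format_quantity(value: Union[int, float]) -> str:
    """Locale-free number rendering: decimal point, no thousands separator."""
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, int):
        return str(value)
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return f"{value:.10g}"


class PatientProfile(BaseModel):
    """Read-only tailoring view over a record as of a given date (the user model).

    Holds the demographic fields, the latest lab value and latest medication
    order per item up to and including ``as_of``, and per-item exposure
    counts (visits strictly before ``as_of`` at which the item was recorded).
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    age: int
    sex: str
    education_level: str
    years_since_diagnosis: float
    regimen: str
    as_of: Optional[dt.date]
    latest_labs: dict[str, tuple[LabResult, dt.date]]
    latest_medications: dict[str, tuple[MedicationOrder, dt.date]]
    exposure: dict[str, int]

    @classmethod
    def from_record(
        cls, record: MedicalRecord, mds: MinimumDataset, as_of: Optional[dt.date] = None
    ) -> "PatientProfile":
        labs: dict[str, tuple[LabResult, dt.date]] = {}
        meds: dict[str, tuple[MedicationOrder, dt.date]] = {}
        exposure: dict[str, int] = {}
        for visit in record.visits:
            if as_of is not None and visit.date > as_of:
                continue
            for lab in visit.labs:
                labs[lab.item_id] = (lab, visit.date)
            for order in visit.medications:
                meds[order.item_id] = (order, visit.date)
            if as_of is None or visit.date < as_of:
                for item_id in set(visit.recorded_item_ids()):
                    exposure[item_id] = exposure.get(item_id, 0) + 1
        d = record.demographics
        return cls(
            age=d.age,
            sex=d.sex,
            education_level=d.education_level,
            years_since_diagnosis=d.years_since_diagnosis,
            regimen=d.regimen,
            as_of=as_of,
            latest_labs=labs,
            latest_medications=meds,
            exposure=exposure,
        )

    def resolve(self, path: str):
        """Resolve a dotted profile field path; returns the missing sentinel
        (not an exception) when the path walks off recorded data."""
        return _resolve_path(
            path,
            {
                "age": self.age,
                "sex": self.sex,
                "education_level": self.education_level,
                "years_since_diagnosis": self.years_since_diagnosis,
                "regimen": self.regimen,
                "labs": {k: v[0] for k, v in self.latest_labs.items()},
                "medications": {k: v[0] for k, v in self.latest_medications.items()},
                "exposure": self.exposure,
            },
        )


def _resolve_path(path: str, root):
    obj = root
    for part in path.split("."):
        if isinstance(obj, dict):
            if part not in obj:
                return _MISSING
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                return _MISSING
            obj = getattr(obj, part)
        if obj is None:
            return _MISSING
    return obj


def evaluate_conditions(conditions: Sequence[Condition], profile: PatientProfile) -> bool:
    """True iff every condition holds (empty list is vacuously true).

    A field that does not resolve makes comparison conditions false,
    ``present`` false, and ``absent`` true.
    """
    for cond in conditions:
        value = profile.resolve(cond.field)
        missing = value is _MISSING
        if cond.op == "present":
            ok = not missing
        elif cond.op == "absent":
            ok = missing
        elif missing:
            ok = False
        else:
            ok = _compare(cond.op, value, cond.value, cond.field)
        if not ok:
            return False
    return True


def _compare(op: str, left, right, field: str) -> bool:
    try:
        if op == "eq":
            return left == right
        if op == "ne":
            return left != right
        if op == "lt":
            return left < right
        if op == "le":
            return left <= right
        if op == "gt":
            return left > right
        return left >= right
    except TypeError as exc:
        raise ConditionError(
            f"condition on {field!r}: cannot compare {left!r} {op} {right!r}"
        ) from exc


class LabInterpretation(BaseModel):
    """Classification of a lab value against its inclusive reference range."""

    model_config = ConfigDict(frozen=True)

    status: Literal["below", "within", "above"]
    value: float
    low: float
    high: float
    message: str


def interpret_lab(
    value: float, reference_range: tuple[float, float], unit: Optional[str] = None
) -> LabInterpretation:
    """Classify a lab value as below/within/above its normal range.

    Boundaries are inclusive: a value equal to either bound is within range.
    """
    low, high = reference_range
    if not (low < high):
        raise TailoringError(f"degenerate reference range ({low}, {high}): low must be < high")
    if not math.isfinite(value):
        raise TailoringError(f"lab value must be finite, got {value!r}")
    if value < low:
        status = "below"
    elif value > high:
        status = "above"
    else:
        status = "within"
    suffix = f" {unit}" if unit else ""
    span = f"{format_quantity(low)}-{format_quantity(high)}{suffix}"
    if status == "within":
        message = f"Your value of {format_quantity(value)}{suffix} is within the normal range ({span})."
    else:
        message = f"Your value of {format_quantity(value)}{suffix} is {status} the normal range ({span})."
    return LabInterpretation(status=status, value=value, low=low, high=high, message=message)


class SlotProvenance(BaseModel):
    model_config = ConfigDict(frozen=True)

    value: str
    source: str
    source_date: Optional[dt.date] = None


def _render_value(obj) -> str:
    if isinstance(obj, dt.date):
        return obj.isoformat()
    if isinstance(obj, LabResult):
        return f"{format_quantity(obj.value)} {obj.unit}"
    if isinstance(obj, MedicationOrder):
        return f"{format_quantity(obj.dose_value)} {obj.dose_unit}"
    if isinstance(obj, SymptomObservation):
        return "present" if obj.present else "absent"
    if isinstance(obj, (int, float, bool)):
        return format_quantity(obj)
    return str(obj)


def fill_template(
    template: str,
    bindings: dict[str, str],
    context: dict[str, object],
    mode: Mode = "strict",
    source_date: Optional[dt.date] = None,
) -> tuple[str, dict[str, SlotProvenance]]:
    """Render a ``{slot}`` template by substituting bound context values.

    Every slot is replaced by the rendered value of its bound field path;
    quantities carry their unit when the binding targets a whole lab result
    or medication order, and the bare number when it targets a numeric field.
    Doubled braces render as literal braces; the surrounding text is
    otherwise untouched.  In strict mode a missing value raises
    :class:`TailoringError` naming the slot; lenient mode substitutes a
    visible ``[missing: slot]`` marker.
    """
    slots = template_slots(template)
    values: dict[str, str] = {}
    provenance: dict[str, SlotProvenance] = {}
    for slot in slots:
        if slot not in bindings:
            raise TailoringError(f"slot {slot!r} has no binding")
        path = bindings[slot]
        resolved = _resolve_path(path, context)
        if resolved is _MISSING or (isinstance(resolved, str) and resolved == ""):
            if mode == "strict":
                raise TailoringError(f"missing value for slot {slot!r} (field {path!r})")
            rendered = f"[missing: {slot}]"
        else:
            rendered = _render_value(resolved)
        values[slot] = rendered
        provenance[slot] = SlotProvenance(value=rendered, source=path, source_date=source_date)
    rendered_text = template.format(**values) if slots else template.format()
    return rendered_text, provenance


class Explanation(BaseModel):
    """The generated two-tier output for one recorded item at one visit."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    item_label: str
    visit_date: dt.date
    status: Literal["ok", "not_applicable", "content_missing"]
    level_used: int = 0
    general_sections: tuple[ContentSection, ...] = ()
    tailored_text: str = ""
    slots_used: dict[str, SlotProvenance] = {}


class VisitExplanations(BaseModel):
    model_config = ConfigDict(frozen=True)

    date: dt.date
    explanations: tuple[Explanation, ...]


class TailoredDocument(BaseModel):
    """The personalized document: per-visit explanations plus an appendix of
    recorded items for which the library has no content."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    visits: tuple[VisitExplanations, ...]
    missing_content: tuple[tuple[dt.date, str], ...]

    def all_explanations(self) -> list[Explanation]:
        return [e for v in self.visits for e in v.explanations]


def _find_entry_object(visit: Visit, item_id: str):
    for obs in visit.symptoms:
        if obs.item_id == item_id:
            return obs
    for order in visit.medications:
        if order.item_id == item_id:
            return order
    for lab in visit.labs:
        if lab.item_id == item_id:
            return lab
    return None


def prior_exposure(record: MedicalRecord, item_id: str, visit_date: dt.date) -> int:
    """Number of visits strictly before ``visit_date`` recording the item."""
    return sum(
        1
        for v in record.visits
        if v.date < visit_date and item_id in v.recorded_item_ids()
    )


def explain_item(
    record: MedicalRecord,
    visit_date: dt.date,
    item_id: str,
    library: ContentLibrary,
    mds: MinimumDataset,
    mode: Mode = "strict",
) -> Explanation:
    """Generate the two-tier explanation for one item recorded at one visit.

    Returns an Explanation with status ``content_missing`` when the library
    has no entry for the item, and ``not_applicable`` (tailored tier only,
    no canned text) when the entry's conditions fail against the profile.
    """
    visit = record.visit_on(visit_date)
    item = mds.get(item_id)
    recorded = _find_entry_object(visit, item_id)
    if recorded is None:
        raise RecordValidationError(
            f"item {item_id!r} was not recorded at visit {visit_date.isoformat()}"
        )
    entry = library.get(item_id)
    if entry is None:
        return Explanation(
            item_id=item_id, item_label=item.label, visit_date=visit_date, status="content_missing"
        )
    profile = PatientProfile.from_record(record, mds, as_of=visit_date)
    applicable = evaluate_conditions(entry.conditions, profile)
    level_used = min(1 + prior_exposure(record, item_id, visit_date), entry.max_level)
    context = {
        "item": item,
        "entry": recorded,
        "visit": visit,
        "demographics": record.demographics,
        "profile": profile,
    }
    tailored_text, slots_used = fill_template(
        entry.tailored_template, entry.slot_bindings, context, mode=mode, source_date=visit_date
    )
    if isinstance(recorded, LabResult) and item.reference_range is not None:
        interp = interpret_lab(
            recorded.value, (item.reference_range.low, item.reference_range.high), unit=item.unit
        )
        tailored_text = f"{tailored_text} {interp.message}"
    return Explanation(
        item_id=item_id,
        item_label=item.label,
        visit_date=visit_date,
        status="ok" if applicable else "not_applicable",
        level_used=level_used,
        general_sections=entry.general_levels[level_used - 1] if applicable else (),
        tailored_text=tailored_text,
        slots_used=slots_used,
    )


def generate_document(
    record: MedicalRecord,
    library: ContentLibrary,
    mds: MinimumDataset,
    mode: Mode = "strict",
) -> TailoredDocument:
    """Assemble the full personalized document for a record.

    Visits appear in date order; within a visit, explanations follow the
    recorded order (symptoms and diseases, then medications, then labs).
    Recorded items without library content are listed in the
    missing-content appendix instead of the body.
    """
    visit_blocks: list[VisitExplanations] = []
    missing: list[tuple[dt.date, str]] = []
    for visit in sorted(record.visits, key=lambda v: v.date):
        explanations: list[Explanation] = []
        for item_id in visit.recorded_item_ids():
            exp = explain_item(record, visit.date, item_id, library, mds, mode=mode)
            if exp.status == "content_missing":
                missing.append((visit.date, item_id))
            else:
                explanations.append(exp)
        visit_blocks.append(VisitExplanations(date=visit.date, explanations=tuple(explanations)))
    return TailoredDocument(
        patient_id=record.patient_id,
        visits=tuple(visit_blocks),
        missing_content=tuple(missing),
    )
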