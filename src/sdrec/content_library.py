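"""Education-content library: per-item leveled sections, templates, conditions.

Each MDS item that patients may click on has one content entry with

* one or more *general levels* — ordered lists of canned-text sections shown
  as the less-tailored tier.  Level 1 is basic; later levels carry the more
  complex material offered once the item has already been explained at prior
  visits;
* a *tailored template* — a sentence with named ``{slot}`` blanks, each bound
  to a record field path, rendered per patient (shallow / fill-in-the-blanks
  text generation);
* an AND-list of applicability *conditions* over the patient profile gating
  the canned text.

Required sections per category: symptoms → definition, diagnostic_symptoms,
causes, advice; medication → side_effects, dosage, administration_and_use;
lab_tests → definition, normal_range, patient_status; medical_history →
definition, causes, advice.  Demographic items carry no content.

Text is treated as opaque Unicode throughout, so right-to-left content
(e.g. Persian) drops in unchanged.
"""

from __future__ import annotations

import io
import string
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import ContentValidationError
from .mds_schema import MinimumDataset

REQUIRED_SECTIONS: dict[str, tuple[str, ...]] = {
    "symptoms": ("definition", "diagnostic_symptoms", "causes", "advice"),
    "medical_history": ("definition", "causes", "advice"),
    "medication": ("side_effects", "dosage", "administration_and_use"),
    "lab_tests": ("definition", "normal_range", "patient_status"),
}

CONDITION_OPS = ("eq", "ne", "lt", "le", "gt", "ge", "present", "absent")
_NULLARY_OPS = ("present", "absent")


class ContentSection(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    text: str

    @field_validator("text")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("section text must be non-empty")
        return v


class Condition(BaseModel):
    """One profile-field comparison; a condition list is an AND-conjunction."""

    model_config = ConfigDict(frozen=True)

    field: str
    op: str
    value: Optional[Union[int, float, str, bool]] = None

    @field_validator("op")
    @classmethod
    def _op(cls, v: str) -> str:
        if v not in CONDITION_OPS:
            raise ValueError(f"unknown op {v!r}")
        return v

    @model_validator(mode="after")
    def _arity(self) -> "Condition":
        if self.op in _NULLARY_OPS and self.value is not None:
            raise ValueError(f"op {self.op!r} takes no value")
        if self.op not in _NULLARY_OPS and self.value is None:
            raise ValueError(f"op {self.op!r} requires a value")
        return self


class ContentEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    category: str
    general_levels: tuple[tuple[ContentSection, ...], ...]
    tailored_template: str
    slot_bindings: dict[str, str]
    conditions: tuple[Condition, ...] = ()

    @model_validator(mode="after")
    def _has_level(self) -> "ContentEntry":
        if not self.general_levels:
            raise ValueError("at least one general level is required")
        return self

    @property
    def max_level(self) -> int:
        return len(self.general_levels)


class ContentLibrary(BaseModel):
    model_config = ConfigDict(frozen=True)

    version: str
    entries: dict[str, ContentEntry]

    def get(self, item_id: str) -> Optional[ContentEntry]:
        return self.entries.get(item_id)


def template_slots(template: str) -> list[str]:
    """Slot names appearing in a ``{slot}`` template, in order of first use.

    Doubled braces escape a literal brace and introduce no slot.
    """
    seen: list[str] = []
    try:
        for _literal, field, _spec, _conv in string.Formatter().parse(template):
            if field is not None and field != "" and field not in seen:
                seen.append(field)
    except ValueError as exc:
        raise ContentValidationError(f"malformed template {template!r}: {exc}") from exc
    return seen


def validate_entry(entry: ContentEntry, mds: MinimumDataset) -> list[str]:
    """Return the (possibly empty) list of issues for one entry.

    Validation is total: any parseable entry yields a finite issue list.
    Issues are reported in a deterministic order — item resolution, category
    match, missing sections level by level, then unbound slots.
    """
    issues: list[str] = []
    if entry.item_id not in mds:
        issues.append(f"unknown item id {entry.item_id!r}")
    else:
        actual = mds.get(entry.item_id).category
        if actual != entry.category:
            issues.append(
                f"category mismatch for {entry.item_id!r}: entry says {entry.category!r}, MDS says {actual!r}"
            )
    required = REQUIRED_SECTIONS.get(entry.category, ())
    for level_no, level in enumerate(entry.general_levels, start=1):
        names = {s.name for s in level}
        for section in required:
            if section not in names:
                issues.append(
                    f"entry {entry.item_id!r} level {level_no} missing required section {section!r}"
                )
    try:
        slots = template_slots(entry.tailored_template)
    except ContentValidationError as exc:
        issues.append(str(exc))
        slots = []
    for slot in slots:
        if slot not in entry.slot_bindings:
            issues.append(f"entry {entry.item_id!r}: unbound slot {slot!r}")
    return issues


def load_library(source: Union[str, Path, io.IOBase, dict], mds: MinimumDataset) -> ContentLibrary:
    """Load a content-library document and validate every entry against the MDS."""
    doc = _read_document(source)
    raw_entries = doc.get("entries")
    if not isinstance(raw_entries, list):
        raise ContentValidationError("library document must carry an 'entries' list")
    entries: dict[str, ContentEntry] = {}
    for raw in raw_entries:
        try:
            entry = ContentEntry.model_validate(raw)
        except ValidationError as exc:
            ident = raw.get("item_id", "<missing>") if isinstance(raw, dict) else "<malformed>"
            first = exc.errors()[0]
            raise ContentValidationError(f"invalid entry {ident!r}: {first['msg']}") from exc
        if entry.item_id in entries:
            raise ContentValidationError(f"duplicate content entry for {entry.item_id!r}")
        issues = validate_entry(entry, mds)
        if issues:
            raise ContentValidationError("; ".join(issues))
        entries[entry.item_id] = entry
    return ContentLibrary(version=str(doc.get("version", "unversioned")), entries=entries)


def serialize_library(library: ContentLibrary) -> str:
    doc = {
        "version": library.version,
        "entries": [e.model_dump(exclude_none=True) for e in library.entries.values()],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# -- placeholder library ------------------------------------------------------

def build_placeholder_library(mds: MinimumDataset, version: str = "placeholder_v1") -> ContentLibrary:
    """Synthesize a full-coverage placeholder library for an MDS.

    One entry per item in the symptoms, medical_history, medication, and
    lab_tests categories, with the required sections per category, a tailored
    template matching the entry kind, and two general levels for lab items
    (so content deepens on repeat exposure).  The prose is English filler;
    real deployments replace it with authored content in any language.
    """
    entries: list[ContentEntry] = []
    for item in mds.items.values():
        if item.category == "demographic":
            continue
        entries.append(_placeholder_entry(item))
    lib = ContentLibrary(version=version, entries={e.item_id: e for e in entries})
    return lib


def _sections(names: Iterable[str], label: str) -> tuple[ContentSection, ...]:
    return tuple(
        ContentSection(
            name=n,
            text=f"{n.replace('_', ' ').capitalize()} for {label}: placeholder explanation text.",
        )
        for n in names
    )


def _placeholder_entry(item) -> ContentEntry:
    cat = item.category
    required = REQUIRED_SECTIONS[cat]
    if cat == "symptoms":
        template = "You reported {symptom} at your visit on {visit_date}."
        bindings = {"symptom": "item.label", "visit_date": "visit.date"}
        levels = (_sections(required, item.label),)
        conditions: tuple[Condition, ...] = ()
    elif cat == "medical_history":
        template = "Your record lists {condition} as part of your medical history (visit of {visit_date})."
        bindings = {"condition": "item.label", "visit_date": "visit.date"}
        levels = (_sections(required, item.label),)
        conditions = ()
    elif cat == "medication":
        template = "Take {dose} {unit} of {drug} {frequency}, {timing}."
        bindings = {
            "dose": "entry.dose_value",
            "unit": "entry.dose_unit",
            "drug": "item.label",
            "frequency": "entry.frequency",
            "timing": "entry.timing",
        }
        levels = (_sections(required, item.label),)
        # insulin canned text only applies to insulin-treated patients
        conditions = (
            (Condition(field="regimen", op="eq", value="drug_plus_insulin"),)
            if item.id.startswith("insulin_")
            else ()
        )
    else:  # lab_tests
        template = "Your result for {test} on {visit_date} was {result}."
        bindings = {"test": "item.label", "visit_date": "visit.date", "result": "entry"}
        basic = _sections(required, item.label)
        deeper = tuple(
            ContentSection(
                name=s.name,
                text=s.text + " More detailed follow-up material for repeat readers.",
            )
            for s in basic
        )
        levels = (basic, deeper)
        conditions = ()
    return ContentEntry(
        item_id=item.id,
        category=cat,
        general_levels=levels,
        tailored_template=template,
        slot_bindings=bindings,
        conditions=conditions,
    )


def _read_document(source: Union[str, Path, io.IOBase, dict]) -> dict:
    if isinstance(source, dict):
        return source
    try:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
    except OSError as exc:
        raise ContentValidationError(f"cannot read library document: {exc}") from exc
    try:
        parsed = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ContentValidationError(f"library document does not parse: {exc}") from exc
    if not isinstance(parsed, dict):
        raise ContentValidationError("library document must be a mapping")
    return parsed
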