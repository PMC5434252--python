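"""Minimum dataset (MDS) for diabetes medical records.

The MDS is the validated catalogue of everything a visit may record,
organised into five categories: demographic information, symptoms, medical
history, medication, and lab tests and measurements.  Each item carries its
value semantics (flag / coded / quantity), a measurement unit where it is a
quantity, and — for lab items — the reference ("normal") range used when a
result is interpreted for the patient.

Schema documents are YAML (JSON, being a YAML subset, also parses).  The
packaged fixture ``mds_diabetes_v1`` holds 110 items split 10/25/15/45/15
across the five categories.
"""

from __future__ import annotations

import io
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import SchemaValidationError

CATEGORIES: Tuple[str, ...] = (
    "demographic",
    "symptoms",
    "medical_history",
    "medication",
    "lab_tests",
)

VALUE_KINDS: Tuple[str, ...] = ("flag", "coded", "quantity")

_FIXTURE_NAME = "mds_diabetes_v1.yaml"


class ReferenceRange(BaseModel):
    """Inclusive (low, high) normal range for a lab item, in the item's unit."""

    model_config = ConfigDict(frozen=True)

    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "ReferenceRange":
        if not self.low < self.high:
            raise ValueError(f"reference range low ({self.low}) must be < high ({self.high})")
        return self


class ItemDefinition(BaseModel):
    """One recordable item of the minimum dataset."""

    model_config = ConfigDict(frozen=True)

    id: str
    label: str
    category: str
    value_kind: str
    unit: Optional[str] = None
    reference_range: Optional[ReferenceRange] = None

    @field_validator("id")
    @classmethod
    def _slug(cls, v: str) -> str:
        if not v or not all(c.islower() or c.isdigit() or c == "_" for c in v) or not v[0].isalpha():
            raise ValueError(f"item id {v!r} is not a lowercase ASCII slug")
        return v

    @field_validator("category")
    @classmethod
    def _category(cls, v: str) -> str:
        if v not in CATEGORIES:
            raise ValueError(f"unknown category {v!r}; expected one of {', '.join(CATEGORIES)}")
        return v

    @field_validator("value_kind")
    @classmethod
    def _value_kind(cls, v: str) -> str:
        if v not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {v!r}")
        return v

    @model_validator(mode="after")
    def _consistency(self) -> "ItemDefinition":
        if self.value_kind == "quantity" and not self.unit:
            raise ValueError(f"quantity item {self.id!r} requires a unit")
        if self.value_kind != "quantity" and self.unit is not None:
            raise ValueError(f"non-quantity item {self.id!r} must not carry a unit")
        if self.reference_range is not None and self.category != "lab_tests":
            raise ValueError(f"reference_range only allowed on lab_tests items (item {self.id!r})")
        return self


class MinimumDataset(BaseModel):
    """The validated item catalogue, keyed by item id."""

    model_config = ConfigDict(frozen=True)

    version: str
    items: dict[str, ItemDefinition]

    @model_validator(mode="after")
    def _keys_match(self) -> "MinimumDataset":
        for key, item in self.items.items():
            if key != item.id:
                raise ValueError(f"items key {key!r} does not match item id {item.id!r}")
        return self

    @classmethod
    def from_items(cls, version: str, items: Iterable[ItemDefinition]) -> "MinimumDataset":
        mapping: dict[str, ItemDefinition] = {}
        for item in items:
            if item.id in mapping:
                raise SchemaValidationError(f"duplicate item id {item.id!r}")
            mapping[item.id] = item
        return cls(version=version, items=mapping)

    def get(self, item_id: str) -> ItemDefinition:
        try:
            return self.items[item_id]
        except KeyError:
            raise SchemaValidationError(f"unknown item id {item_id!r}") from None

    def __contains__(self, item_id: object) -> bool:
        return item_id in self.items

    def ids_in(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise SchemaValidationError(f"unknown category {category!r}")
        return [i.id for i in self.items.values() if i.category == category]


def load_mds(source: Union[str, Path, io.IOBase, dict]) -> MinimumDataset:
    """Load and validate an MDS document from a path, stream, or parsed dict.

    Raises :class:`SchemaValidationError` on duplicate ids, unknown categories,
    quantity items without a unit, or any other invariant violation.
    """
    doc = _read_document(source)
    if not isinstance(doc, dict) or "items" not in doc:
        raise SchemaValidationError("MDS document must be a mapping with an 'items' list")
    raw_items = doc["items"]
    if not isinstance(raw_items, list):
        raise SchemaValidationError("'items' must be a list of item definitions")
    items = []
    for raw in raw_items:
        try:
            items.append(ItemDefinition.model_validate(raw))
        except ValidationError as exc:
            ident = raw.get("id", "<missing id>") if isinstance(raw, dict) else "<malformed>"
            raise SchemaValidationError(f"invalid item {ident!r}: {_first_message(exc)}") from exc
    return MinimumDataset.from_items(version=str(doc.get("version", "unversioned")), items=items)


def serialize_mds(mds: MinimumDataset) -> str:
    """Serialize an MDS back to its YAML document form (round-trip safe)."""
    doc = {
        "version": mds.version,
        "items": [item.model_dump(exclude_none=True) for item in mds.items.values()],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def count_items(mds: MinimumDataset, category: str = "all") -> int:
    """Number of items in one canonical category, or in the whole dataset."""
    if category == "all":
        return len(mds.items)
    if category not in CATEGORIES:
        raise SchemaValidationError(
            f"unknown category {category!r}; expected 'all' or one of {', '.join(CATEGORIES)}"
        )
    return sum(1 for item in mds.items.values() if item.category == category)


def load_default_mds() -> MinimumDataset:
    """Load the packaged 110-item diabetes MDS fixture."""
    text = resources.files("sdrec.data").joinpath(_FIXTURE_NAME).read_text(encoding="utf-8")
    return load_mds(yaml.safe_load(text))


def _read_document(source: Union[str, Path, io.IOBase, dict]) -> dict:
    if isinstance(source, dict):
        return source
    try:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
    except OSError as exc:
        raise SchemaValidationError(f"cannot read MDS document: {exc}") from exc
    try:
        parsed = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaValidationError(f"MDS document does not parse as YAML/JSON: {exc}") from exc
    if not isinstance(parsed, dict):
        raise SchemaValidationError("MDS document must be a mapping")
    return parsed


def _first_message(exc: ValidationError) -> str:
    err = exc.errors()[0]
    return str(err.get("msg", err))
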