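"""Need-analysis question taxonomy.

Field observation of clinic visits and education classes yields the thematic
categories of questions patients actually ask.  Only some of those categories
can be answered from the patient's own record; those are flagged
``record_linked`` and are the ones the content structures are built around.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import SchemaValidationError

_FIXTURE_NAME = "question_taxonomy_v1.yaml"


class QuestionCategory(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    record_linked: bool
    concepts: tuple[str, ...] = ()

    @field_validator("concepts", mode="before")
    @classmethod
    def _tuple(cls, v):
        return tuple(v) if v is not None else ()


class QuestionTaxonomy(BaseModel):
    model_config = ConfigDict(frozen=True)

    version: str
    categories: tuple[QuestionCategory, ...]

    def record_linked(self) -> list[QuestionCategory]:
        return [c for c in self.categories if c.record_linked]


def load_taxonomy(source: Optional[Union[str, Path]] = None) -> QuestionTaxonomy:
    """Load a question taxonomy document; default is the packaged fixture."""
    if source is None:
        text = resources.files("sdrec.data").joinpath(_FIXTURE_NAME).read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "categories" not in doc:
        raise SchemaValidationError("taxonomy document must be a mapping with 'categories'")
    names = [c.get("name") for c in doc["categories"]]
    if len(names) != len(set(names)):
        raise SchemaValidationError("duplicate category names in taxonomy")
    return QuestionTaxonomy(
        version=str(doc.get("version", "unversioned")),
        categories=tuple(QuestionCategory.model_validate(c) for c in doc["categories"]),
    )
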