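"""Content-quality checklist aggregation.

Clinicians and patients score each item group of the education content on
1-5 Likert checklists (clinician criteria: accuracy, simplicity, usefulness,
adequacy; patient criteria: comprehensibility, practicality, essentiality,
novelty).  Scores aggregate into an item-group x criterion matrix of means
and population standard deviations, summarized with an unweighted total row
and column.  Display values are truncated (floored) at one decimal — the
rule under which the summary totals are consistent with their cells.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import RatingError

ITEM_GROUPS = ("symptoms", "diseases", "drugs", "tests")
CLINICIAN_CRITERIA = ("accuracy", "simplicity", "usefulness", "adequacy")
PATIENT_CRITERIA = ("comprehensibility", "practicality", "essentiality", "novelty")

Family = Literal["clinician", "patient"]


def criterion_family(criterion: str) -> Family:
    if criterion in CLINICIAN_CRITERIA:
        return "clinician"
    if criterion in PATIENT_CRITERIA:
        return "patient"
    raise RatingError(f"unknown criterion {criterion!r}")


class Rating(BaseModel):
    model_config = ConfigDict(frozen=True)

    rater_id: str
    item_group: str
    criterion: str
    score: int

    @field_validator("item_group")
    @classmethod
    def _group(cls, v: str) -> str:
        if v not in ITEM_GROUPS:
            raise ValueError(f"item_group must be one of {ITEM_GROUPS}")
        return v

    @field_validator("criterion")
    @classmethod
    def _criterion(cls, v: str) -> str:
        criterion_family(v)  # raises RatingError on unknown
        return v

    @field_validator("score")
    @classmethod
    def _score(cls, v: int) -> int:
        if v not in (1, 2, 3, 4, 5):
            raise ValueError("score must be an integer in 1..5")
        return v


class CellStats(BaseModel):
    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float
    n: int


class RatingMatrix(BaseModel):
    """Item-group x criterion cells of (mean, population SD, n)."""

    model_config = ConfigDict(frozen=True)

    family: Family
    cells: dict[str, CellStats]  # key "group/criterion"

    def cell(self, group: str, criterion: str) -> Optional[CellStats]:
        return self.cells.get(f"{group}/{criterion}")

    @property
    def criteria(self) -> tuple[str, ...]:
        return CLINICIAN_CRITERIA if self.family == "clinician" else PATIENT_CRITERIA

    @classmethod
    def from_cells(
        cls,
        family: Family,
        means: dict[tuple[str, str], float],
        sds: Optional[dict[tuple[str, str], float]] = None,
        n: int = 1,
    ) -> "RatingMatrix":
        """Build a matrix directly from per-cell summary values (e.g. a
        published summary table) rather than raw scores."""
        cells = {}
        for (group, criterion), mean in means.items():
            if group not in ITEM_GROUPS:
                raise RatingError(f"unknown item_group {group!r}")
            if criterion_family(criterion) != family:
                raise RatingError(f"criterion {criterion!r} is not in the {family} family")
            sd = sds.get((group, criterion), 0.0) if sds else 0.0
            cells[f"{group}/{criterion}"] = CellStats(mean=mean, sd=sd, n=n)
        return cls(family=family, cells=cells)


class SummaryTable(BaseModel):
    """A rating matrix plus unweighted total row/column.

    ``display`` values are truncated to one decimal; the exact full-precision
    means are kept alongside.
    """

    model_config = ConfigDict(frozen=True)

    family: Family
    groups: tuple[str, ...]
    criteria: tuple[str, ...]
    cell_means: dict[str, float]
    cell_sds: dict[str, float]
    total_by_criterion: dict[str, float]  # exact
    total_by_group: dict[str, float]  # exact
    display_total_by_criterion: dict[str, float]
    display_total_by_group: dict[str, float]


def truncate_display(value: float) -> float:
    """Floor at one decimal (4.475 -> 4.4, 4.95 -> 4.9).

    A 1e-9 guard absorbs binary floating-point noise so that a mean that is
    exactly representable at one decimal is not pushed down a notch.
    """
    return math.floor(value * 10 + 1e-9) / 10


def aggregate_ratings(ratings: Sequence[Rating]) -> RatingMatrix:
    """Aggregate raw checklist scores into per-cell mean / population SD / n.

    All ratings must belong to one checklist family; aggregation is
    permutation-invariant in the rating list.
    """
    if not ratings:
        raise RatingError("no ratings to aggregate")
    families = {criterion_family(r.criterion) for r in ratings}
    if len(families) > 1:
        raise RatingError("mixed clinician/patient criteria in one rating set")
    family = families.pop()
    buckets: dict[str, list[int]] = {}
    for r in ratings:
        buckets.setdefault(f"{r.item_group}/{r.criterion}", []).append(r.score)
    cells = {}
    for key, scores in buckets.items():
        n = len(scores)
        mean = sum(scores) / n
        sd = math.sqrt(sum((s - mean) ** 2 for s in scores) / n)  # divisor n (population)
        cells[key] = CellStats(mean=mean, sd=sd, n=n)
    return RatingMatrix(family=family, cells=cells)


def summarize_matrix(matrix: RatingMatrix) -> SummaryTable:
    """Add the unweighted total row (per criterion) and column (per group).

    Requires all four groups x four criteria to be populated.  Totals are
    arithmetic means of the four cell means, exposed both exactly and
    truncated to one decimal for display.
    """
    criteria = matrix.criteria
    for group in ITEM_GROUPS:
        for criterion in criteria:
            if matrix.cell(group, criterion) is None:
                raise RatingError(f"missing cell {group}/{criterion}")
    cell_means = {k: c.mean for k, c in matrix.cells.items()}
    cell_sds = {k: c.sd for k, c in matrix.cells.items()}
    total_by_criterion = {
        c: sum(matrix.cell(g, c).mean for g in ITEM_GROUPS) / len(ITEM_GROUPS) for c in criteria
    }
    total_by_group = {
        g: sum(matrix.cell(g, c).mean for c in criteria) / len(criteria) for g in ITEM_GROUPS
    }
    return SummaryTable(
        family=matrix.family,
        groups=ITEM_GROUPS,
        criteria=criteria,
        cell_means=cell_means,
        cell_sds=cell_sds,
        total_by_criterion=total_by_criterion,
        total_by_group=total_by_group,
        display_total_by_criterion={c: truncate_display(v) for c, v in total_by_criterion.items()},
        display_total_by_group={g: truncate_display(v) for g, v in total_by_group.items()},
    )


# -- I/O ----------------------------------------------------------------------

def read_ratings_csv(source: Union[str, Path, io.IOBase]) -> list[Rating]:
    """Read ratings from a CSV with header ``rater_id,item_group,criterion,score``."""
    try:
        frame = pd.read_csv(source)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise RatingError(f"cannot read ratings CSV: {exc}") from exc
    expected = ["rater_id", "item_group", "criterion", "score"]
    if list(frame.columns) != expected:
        raise RatingError(f"ratings CSV must have columns {expected}, got {list(frame.columns)}")
    ratings = []
    for row in frame.itertuples(index=False):
        try:
            ratings.append(
                Rating(
                    rater_id=str(row.rater_id),
                    item_group=str(row.item_group),
                    criterion=str(row.criterion),
                    score=int(row.score),
                )
            )
        except (ValueError, TypeError) as exc:
            raise RatingError(f"invalid rating row {tuple(row)!r}: {exc}") from exc
    return ratings


def summary_to_frame(summary: SummaryTable, display: bool = True) -> pd.DataFrame:
    """Summary as a DataFrame in the published layout: one row per item group
    plus a total row, one column per criterion plus a total column.

    With ``display=True`` cell means show truncated to one decimal as
    ``mean (sd)`` strings; otherwise exact floats (total cells NaN-free)."""
    rows = {}
    for group in summary.groups:
        row = {}
        for criterion in summary.criteria:
            mean = summary.cell_means[f"{group}/{criterion}"]
            sd = summary.cell_sds[f"{group}/{criterion}"]
            if display:
                row[criterion] = f"{truncate_display(mean):g} ({sd:g})"
            else:
                row[criterion] = mean
        row["total"] = (
            f"{summary.display_total_by_group[group]:g}" if display else summary.total_by_group[group]
        )
        rows[group] = row
    total_row = {}
    for criterion in summary.criteria:
        total_row[criterion] = (
            f"{summary.display_total_by_criterion[criterion]:g}"
            if display
            else summary.total_by_criterion[criterion]
        )
    total_row["total"] = ""
    rows["total"] = total_row
    return pd.DataFrame.from_dict(rows, orient="index")


def load_clinician_reference_cells() -> RatingMatrix:
    """The packaged clinician quality-cell summary from the pilot evaluation
    (n=3 raters), as a cells-only matrix."""
    from importlib import resources

    text = resources.files("sdrec.data").joinpath("clinician_quality_cells.csv").read_text("utf-8")
    frame = pd.read_csv(io.StringIO(text))
    means = {(r.item_group, r.criterion): float(r.mean) for r in frame.itertuples(index=False)}
    sds = {(r.item_group, r.criterion): float(r.sd) for r in frame.itertuples(index=False)}
    return RatingMatrix.from_cells("clinician", means, sds, n=3)
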