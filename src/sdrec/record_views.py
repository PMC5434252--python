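"""Patient-mode views: session view, topic timeline, printable booklet.

Each view is produced as a :class:`RenderedView` in Markdown or HTML.  Every
listed record item is a hyperlink to the anchor of its explanation, so a
session view links into the booklet built from the same record.  Rendering
is deterministic and never alters explanation text.
"""

from __future__ import annotations

import datetime as dt
import html as _html
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .errors import RecordValidationError
from .mds_schema import MinimumDataset
from .record_model import MedicalRecord, TopicTimeline, session_entries, topic_series
from .tailoring_engine import Explanation, TailoredDocument, format_quantity

Format = Literal["markdown", "html"]

#: relative change (first vs last point) at or below which a series is "stable"
TREND_STABLE_THRESHOLD = 0.05


class RenderedView(BaseModel):
    model_config = ConfigDict(frozen=True)

    format: Format
    body: str
    anchors: dict[str, str]


def explanation_anchor(date: dt.date, item_id: str) -> str:
    return f"exp-{date.isoformat()}-{item_id}"


# -- internal block emitter ----------------------------------------------------

class _Doc:
    """Accumulates structural blocks, emitted as Markdown or HTML."""

    def __init__(self) -> None:
        self.blocks: list[tuple] = []

    def heading(self, level: int, text: str, anchor: Optional[str] = None) -> None:
        self.blocks.append(("heading", level, text, anchor))

    def para(self, text: str) -> None:
        self.blocks.append(("para", text))

    def bullet_list(self, items: Sequence[tuple[str, Optional[str]]]) -> None:
        # items: (text, href-fragment or None)
        self.blocks.append(("list", tuple(items)))

    def table(self, headers: Sequence[str], rows: Sequence[Sequence[str]]) -> None:
        self.blocks.append(("table", tuple(headers), tuple(tuple(r) for r in rows)))

    def emit(self, fmt: Format) -> str:
        return _emit_markdown(self.blocks) if fmt == "markdown" else _emit_html(self.blocks)


def _emit_markdown(blocks: list[tuple]) -> str:
    out: list[str] = []
    for block in blocks:
        kind = block[0]
        if kind == "heading":
            _, level, text, anchor = block
            if anchor:
                out.append(f'<a id="{anchor}"></a>')
            out.append(f"{'#' * level} {text}")
        elif kind == "para":
            out.append(block[1])
        elif kind == "list":
            items = block[1]
            if not items:
                out.append("*(none recorded)*")
            else:
                out.append(
                    "\n".join(
                        f"- [{text}](#{href})" if href else f"- {text}" for text, href in items
                    )
                )
        elif kind == "table":
            _, headers, rows = block
            lines = ["| " + " | ".join(headers) + " |", "| " + " | ".join("---" for _ in headers) + " |"]
            lines += ["| " + " | ".join(row) + " |" for row in rows]
            out.append("\n".join(lines))
    return "\n\n".join(out) + "\n"


def _emit_html(blocks: list[tuple]) -> str:
    esc = _html.escape
    out: list[str] = []
    for block in blocks:
        kind = block[0]
        if kind == "heading":
            _, level, text, anchor = block
            attr = f' id="{anchor}"' if anchor else ""
            out.append(f"<h{level}{attr}>{esc(text)}</h{level}>")
        elif kind == "para":
            out.append(f"<p>{esc(block[1])}</p>")
        elif kind == "list":
            items = block[1]
            if not items:
                out.append("<p><em>(none recorded)</em></p>")
            else:
                lis = [
                    f'<li><a href="#{href}">{esc(text)}</a></li>' if href else f"<li>{esc(text)}</li>"
                    for text, href in items
                ]
                out.append("<ul>" + "".join(lis) + "</ul>")
        elif kind == "table":
            _, headers, rows = block
            head = "".join(f"<th>{esc(h)}</th>" for h in headers)
            body = "".join(
                "<tr>" + "".join(f"<td>{esc(c)}</td>" for c in row) + "</tr>" for row in rows
            )
            out.append(f"<table><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>")
    body = "\n".join(out)
    return f"<!DOCTYPE html>\n<html><body>\n{body}\n</body></html>\n"


# -- views --------------------------------------------------------------------

def render_session_view(
    record: MedicalRecord, date: dt.date, mds: MinimumDataset, format: Format = "markdown"
) -> RenderedView:
    """One visit's entries in the three fixed columns, each item linked to its
    explanation anchor.  Empty columns are rendered empty, never omitted."""
    groups = session_entries(record, date, mds)
    doc = _Doc()
    doc.heading(1, f"Visit {date.isoformat()}")
    anchors: dict[str, str] = {}

    def link_items(entries, describe):
        items = []
        for e in entries:
            anchor = explanation_anchor(date, e.item_id)
            anchors[e.item_id] = anchor
            items.append((describe(e), anchor))
        return items

    doc.heading(2, "Symptoms and diseases")
    doc.bullet_list(link_items(groups.symptoms_and_diseases, lambda e: mds.get(e.item_id).label))
    doc.heading(2, "Medication")
    doc.bullet_list(
        link_items(
            groups.medication,
            lambda e: f"{mds.get(e.item_id).label} ({format_quantity(e.dose_value)} {e.dose_unit})",
        )
    )
    doc.heading(2, "Lab tests")
    doc.bullet_list(
        link_items(
            groups.lab_tests,
            lambda e: f"{mds.get(e.item_id).label}: {format_quantity(e.value)} {e.unit}",
        )
    )
    return RenderedView(format=format, body=doc.emit(format), anchors=anchors)


def trend_label(timeline: TopicTimeline) -> str:
    """Trend of a series from its first vs last value.

    ``n/a`` with fewer than two points; ``stable`` when the relative change
    is at most 5%; otherwise ``rising`` or ``falling``.
    """
    if len(timeline.points) < 2:
        return "n/a"
    first = timeline.points[0][1]
    last = timeline.points[-1][1]
    if first == 0:
        if last == 0:
            return "stable"
        return "rising" if last > 0 else "falling"
    rel = (last - first) / abs(first)
    if abs(rel) <= TREND_STABLE_THRESHOLD:
        return "stable"
    return "rising" if rel > 0 else "falling"


def render_topic_timeline(
    record: MedicalRecord, item_id: str, mds: MinimumDataset, format: Format = "markdown"
) -> RenderedView:
    """Chronological table of one item's values across visits plus a trend label."""
    timeline = topic_series(record, item_id, mds)
    item = mds.get(item_id)
    unit = f" {item.unit}" if item.unit else ""
    doc = _Doc()
    anchor = f"timeline-{item_id}"
    doc.heading(1, f"Timeline: {item.label}", anchor=anchor)
    if timeline.points:
        doc.table(
            ("Date", "Value"),
            [(d.isoformat(), f"{format_quantity(v)}{unit}") for d, v in timeline.points],
        )
    else:
        doc.para("*(never recorded)*" if format == "markdown" else "(never recorded)")
    doc.para(f"Trend: {trend_label(timeline)}")
    return RenderedView(format=format, body=doc.emit(format), anchors={item_id: anchor})


def render_booklet(
    document: TailoredDocument, mds: MinimumDataset, format: Format = "markdown"
) -> RenderedView:
    """The printable booklet: table of contents, one section per visit with one
    subsection per explanation (general tier before tailored tier), and the
    missing-content appendix last."""
    doc = _Doc()
    doc.heading(1, f"Personal health booklet - patient {document.patient_id}")
    anchors: dict[str, str] = {}

    toc: list[tuple[str, str]] = []
    for block in document.visits:
        toc.append((f"Visit {block.date.isoformat()}", f"visit-{block.date.isoformat()}"))
    toc.append(("Appendix: items without content", "missing-content"))
    doc.heading(2, "Contents")
    doc.bullet_list(toc)

    for block in document.visits:
        doc.heading(2, f"Visit {block.date.isoformat()}", anchor=f"visit-{block.date.isoformat()}")
        if not block.explanations:
            doc.para("No explainable items were recorded at this visit.")
        for exp in block.explanations:
            anchor = explanation_anchor(exp.visit_date, exp.item_id)
            anchors[anchor] = anchor
            doc.heading(3, exp.item_label, anchor=anchor)
            _emit_explanation(doc, exp)

    doc.heading(2, "Appendix: items without content", anchor="missing-content")
    if document.missing_content:
        doc.bullet_list(
            [
                (f"{mds.get(item_id).label} (visit {d.isoformat()})", None)
                for d, item_id in document.missing_content
            ]
        )
    else:
        doc.para("All recorded items had library content.")
    return RenderedView(format=format, body=doc.emit(format), anchors=anchors)


def _emit_explanation(doc: _Doc, exp: Explanation) -> None:
    if exp.status == "not_applicable":
        doc.para("General explanation: not applicable to this patient's profile.")
    else:
        doc.para(f"General explanation (level {exp.level_used}):")
        doc.bullet_list(
            [(f"{s.name.replace('_', ' ')}: {s.text}", None) for s in exp.general_sections]
        )
    doc.para("About you:")
    doc.para(exp.tailored_text)
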