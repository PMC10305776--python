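"""Contraindication surfacing report.

Groups the detected entity mentions of one letter by category and entity,
attaches a context snippet to every mention, and lists the eligibility
checklist items whose linked entities were detected.  The report is advisory
display only: it never answers a checklist question, it just surfaces where
the relevant information sits in the letter.  Rendering is pure — identical
inputs produce byte-identical text or HTML.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from typing import Sequence

from .ontology import ChecklistItem, Ontology
from .standoff import AnnotatedDocument, EntitySpan


@dataclass(frozen=True)
class Snippet:
    doc_id: str
    start: int
    end: int
    surface: str
    context: str  # span text ± context_chars, truncated at document bounds
    context_start: int


@dataclass(frozen=True)
class SurfaceReport:
    doc_id: str
    groups: dict[str, dict[str, list[Snippet]]]  # category -> entity -> snippets
    checklist: list[tuple[ChecklistItem, list[str]]]  # item, detected entity ids

    @property
    def empty(self) -> bool:
        return not any(self.groups.values())


def render_report(
    doc: AnnotatedDocument,
    spans: Sequence[EntitySpan],
    context_chars: int = 60,
    ontology: Ontology | None = None,
) -> SurfaceReport:
    """Build the two-pane report structure for one document."""
    from .ontology import load_default_ontology

    onto = ontology if ontology is not None else load_default_ontology()
    for s in spans:
        s.validate(doc.text, onto)
    groups: dict[str, dict[str, list[Snippet]]] = {c: {} for c in onto.categories}
    detected: set[str] = set()
    for span in sorted(spans, key=lambda s: (s.start, s.end, s.label)):
        category = onto.category_of(span.label)
        lo = max(0, span.start - context_chars)
        hi = min(len(doc.text), span.end + context_chars)
        snippet = Snippet(
            doc_id=doc.doc_id,
            start=span.start,
            end=span.end,
            surface=span.surface,
            context=doc.text[lo:hi],
            context_start=lo,
        )
        groups[category].setdefault(span.label, []).append(snippet)
        detected.add(span.label)
    checklist = [
        (item, [e for e in item.entities if e in detected])
        for item in onto.checklist
    ]
    return SurfaceReport(doc_id=doc.doc_id, groups=groups, checklist=checklist)


def format_text(report: SurfaceReport) -> str:
    lines = [f"Entity report for document {report.doc_id}", ""]
    if report.empty:
        lines.append("(no entities detected)")
    for category, entities in report.groups.items():
        if not entities:
            continue
        lines.append(f"== {category} ==")
        for entity, snippets in entities.items():
            lines.append(f"  {entity} ({len(snippets)} mention(s))")
            for sn in snippets:
                ctx = " ".join(sn.context.split())
                lines.append(f"    [{sn.start}:{sn.end}] {sn.surface!r} … {ctx}")
        lines.append("")
    flagged = [(item, hits) for item, hits in report.checklist if hits]
    if flagged:
        lines.append("== Checklist items with detected entities (advisory) ==")
        for item, hits in flagged:
            lines.append(f"  [{item.polarity}] {item.text}")
            lines.append(f"      detected: {', '.join(hits)}")
    return "\n".join(lines) + "\n"


def format_html(report: SurfaceReport) -> str:
    """Single-file static HTML with a two-pane layout (mentions | context)."""
    left, right = [], []
    for category, entities in report.groups.items():
        if not entities:
            continue
        left.append(f"<h3>{html.escape(category)}</h3><ul>")
        for entity, snippets in entities.items():
            left.append(
                f'<li><a href="#e-{html.escape(entity)}">{html.escape(entity)}</a>'
                f" ({len(snippets)})</li>"
            )
            right.append(f'<h4 id="e-{html.escape(entity)}">{html.escape(entity)}</h4>')
            for sn in snippets:
                pre = sn.context[: sn.start - sn.context_start]
                post = sn.context[sn.end - sn.context_start :]
                right.append(
                    "<p><code>"
                    + html.escape(pre)
                    + "<mark>"
                    + html.escape(sn.surface)
                    + "</mark>"
                    + html.escape(post)
                    + f"</code> <small>[{sn.start}:{sn.end}]</small></p>"
                )
        left.append("</ul>")
    if report.empty:
        left.append("<p><em>no entities detected</em></p>")
    checklist_rows = []
    for item, hits in report.checklist:
        if not hits:
            continue
        checklist_rows.append(
            f"<tr><td>{html.escape(item.polarity)}</td>"
            f"<td>{html.escape(item.text)}</td>"
            f"<td>{html.escape(', '.join(hits))}</td></tr>"
        )
    checklist_html = (
        "<h3>Checklist items with detected entities (advisory)</h3>"
        "<table><tr><th>required</th><th>item</th><th>detected</th></tr>"
        + "".join(checklist_rows)
        + "</table>"
        if checklist_rows
        else ""
    )
    return (
        "<!doctype html><html><head><meta charset='utf-8'>"
        f"<title>Entity report {html.escape(report.doc_id)}</title>"
        "<style>body{display:flex;font-family:sans-serif}"
        ".pane{flex:1;padding:1em;overflow:auto}</style></head><body>"
        f"<div class='pane'><h2>{html.escape(report.doc_id)}</h2>"
        + "".join(left)
        + "</div><div class='pane'>"
        + "".join(right)
        + checklist_html
        + "</div></body></html>"
    )
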