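"""Domain types, brat standoff I/O, tokenization, and the IOB tag codec.

Character offsets throughout the toolkit are 0-based and half-open
(``[start, end)``), matching the brat standoff convention.  The tokenizer is a
deterministic word-level rule — maximal alphanumeric runs, with every other
non-space character emitted as a single-character token — chosen so that token
offsets always map back into the letter text exactly.  Case is preserved at
this layer; all case normalization happens downstream.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import Ontology

logger = logging.getLogger(__name__)

DOC_TYPES = (
    "GP referral",
    "IDL",
    "FDL",
    "OPCL",
    "ED Letter",
    "Endoscopy report",
)


class StandoffError(ValueError):
    """Base class for annotation-format errors."""


class MalformedAnnotationError(StandoffError):
    """A standoff line that cannot be interpreted against its text."""


class UnknownLabelError(StandoffError):
    """An annotation label absent from the active ontology."""


class SpanCollisionError(StandoffError):
    """Overlapping gold spans with conflicting labels during IOB encoding."""


@dataclass(frozen=True)
class EntitySpan:
    """A labelled character interval ``[start, end)`` within one document."""

    start: int
    end: int
    label: str
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MalformedAnnotationError(
                f"invalid span offsets ({self.start}, {self.end})"
            )

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end

    def overlap_chars(self, other: "EntitySpan") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def validate(self, text: str, ontology: "Ontology | None" = None) -> None:
        if self.end > len(text):
            raise MalformedAnnotationError(
                f"span ({self.start}, {self.end}) exceeds text length {len(text)}"
            )
        if text[self.start : self.end] != self.surface:
            raise MalformedAnnotationError(
                f"surface {self.surface!r} does not match text slice "
                f"{text[self.start:self.end]!r} at ({self.start}, {self.end})"
            )
        if ontology is not None and not ontology.contains(self.label):
            raise UnknownLabelError(f"label {self.label!r} not in ontology")


def _sorted_spans(spans: Iterable[EntitySpan]) -> tuple[EntitySpan, ...]:
    return tuple(sorted(spans, key=lambda s: (s.start, s.end, s.label)))


@dataclass(frozen=True)
class AnnotatedDocument:
    """One clinical letter with its annotation spans."""

    doc_id: str
    patient_id: str
    doc_type: str
    text: str
    spans: tuple[EntitySpan, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "spans", _sorted_spans(self.spans))
        seen: set[tuple[int, int, str]] = set()
        for s in self.spans:
            key = (s.start, s.end, s.label)
            if key in seen:
                raise MalformedAnnotationError(
                    f"duplicate span {key} in document {self.doc_id}"
                )
            seen.add(key)

    def with_spans(self, spans: Iterable[EntitySpan]) -> "AnnotatedDocument":
        return replace(self, spans=tuple(spans))

    def validate(self, ontology: "Ontology | None" = None) -> None:
        for s in self.spans:
            s.validate(self.text, ontology)


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


class TokenSequence(Sequence[Token]):
    """Ordered, non-overlapping tokens with offsets into the parent text."""

    def __init__(self, tokens: Iterable[Token]):
        self._tokens = tuple(tokens)
        prev_end = -1
        for t in self._tokens:
            if t.start < max(prev_end, 0) or t.end <= t.start:
                raise ValueError(f"tokens out of order at {t}")
            prev_end = t.end

    def __len__(self) -> int:
        return len(self._tokens)

    def __getitem__(self, i):  # type: ignore[override]
        return self._tokens[i]

    def __iter__(self) -> Iterator[Token]:
        return iter(self._tokens)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TokenSequence) and self._tokens == other._tokens

    def __repr__(self) -> str:
        return f"TokenSequence({list(self._tokens)!r})"

    def surfaces(self) -> list[str]:
        return [t.surface for t in self._tokens]


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")


def tokenize(text: str) -> TokenSequence:
    """Split ``text`` into word and single-character punctuation tokens.

    Maximal alphanumeric runs form word tokens; every remaining non-space
    character becomes its own token.  Offsets index into ``text`` so each
    token's surface equals its slice.
    """
    return TokenSequence(
        Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)
    )


@dataclass(frozen=True)
class TagSequence:
    """One IOB tag per token, drawn from ``{O} ∪ {B-e, I-e}``."""

    tags: tuple[str, ...]

    def __init__(self, tags: Iterable[str]):
        object.__setattr__(self, "tags", tuple(tags))

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tags)

    def validate(self, tag_space: Sequence[str]) -> None:
        allowed = set(tag_space)
        for t in self.tags:
            if t not in allowed:
                raise ValueError(f"tag {t!r} outside tag space")


def tag_space(ontology: "Ontology") -> list[str]:
    """Ordered IOB tag inventory: ``O`` first, then ``B-e, I-e`` per entity.

    For N entities the list has length 2N+1.  The order is stable (ontology
    order) and shared by every classifier in an ensemble.
    """
    tags = ["O"]
    for ent in ontology.entities:
        tags.append(f"B-{ent.id}")
        tags.append(f"I-{ent.id}")
    return tags


def encode_iob(
    tokens: TokenSequence,
    spans: Sequence[EntitySpan],
    *,
    on_collision: str = "error",
) -> TagSequence:
    """Encode character spans as one IOB tag per token.

    A token belongs to a span when their character intervals overlap; a span
    that starts or ends mid-token claims the whole token (the least
    destructive rule under lenient evaluation).  Overlapping spans with
    conflicting claims raise :class:`SpanCollisionError` unless
    ``on_collision="keep-longest"``, which gives priority to longer spans.
    """
    if on_collision not in ("error", "keep-longest"):
        raise ValueError(f"unknown collision policy {on_collision!r}")
    order = sorted(spans, key=lambda s: (-(s.end - s.start), s.start))
    tags: list[str] = ["O"] * len(tokens)
    owner: list[EntitySpan | None] = [None] * len(tokens)
    for span in order:
        idx = [
            i
            for i, t in enumerate(tokens)
            if t.start < span.end and span.start < t.end
        ]
        if not idx:
            continue
        claimed = [i for i in idx if owner[i] is not None]
        if claimed:
            if on_collision == "error":
                other = owner[claimed[0]]
                raise SpanCollisionError(
                    f"span ({span.start}, {span.end}, {span.label}) overlaps "
                    f"({other.start}, {other.end}, {other.label})"  # type: ignore[union-attr]
                )
            idx = [i for i in idx if owner[i] is None]
            # keep-longest: the longer span was placed first and wins
            if not idx:
                continue
        runs = _contiguous_runs(idx)
        for run in runs:
            tags[run[0]] = f"B-{span.label}"
            for i in run[1:]:
                tags[i] = f"I-{span.label}"
            for i in run:
                owner[i] = span
    return TagSequence(tags)


def _contiguous_runs(indices: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for i in indices:
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def decode_iob(
    tags: TagSequence | Sequence[str],
    tokens: TokenSequence,
    text: str,
) -> list[EntitySpan]:
    """Decode an IOB tag sequence back into character spans.

    Maximal ``B, I…I`` runs of one entity become spans covering
    ``[first token start, last token end)``.  An orphan ``I-e`` (not preceded
    by ``B-e`` or ``I-e``) is repaired to ``B-e``, so decoding is total.
    """
    tag_list = list(tags)
    if len(tag_list) != len(tokens):
        raise ValueError("tag/token length mismatch")
    spans: list[EntitySpan] = []
    run_label: str | None = None
    run_start = 0
    last = -1

    def flush(upto: int) -> None:
        nonlocal run_label
        if run_label is not None:
            start = tokens[run_start].start
            end = tokens[upto].end
            spans.append(EntitySpan(start, end, run_label, text[start:end]))
            run_label = None

    for i, tag in enumerate(tag_list):
        if tag == "O":
            flush(i - 1)
        else:
            prefix, label = tag.split("-", 1)
            if prefix == "I" and run_label == label:
                pass  # continue the run
            else:  # B-, or orphan I- repaired as B-
                flush(i - 1)
                run_label = label
                run_start = i
        last = i
    flush(last)
    return spans


# ---------------------------------------------------------------------------
# brat standoff serialization
# ---------------------------------------------------------------------------

_TEXTBOUND_RE = re.compile(r"^T\d+\t(\S+) (\d+) (\d+)\t(.*)$", re.DOTALL)


def read_standoff(
    text_content: str,
    ann_content: str,
    ontology: "Ontology | None" = None,
    *,
    doc_id: str = "",
    patient_id: str = "",
    doc_type: str = "",
    skip_unknown_labels: bool = False,
) -> AnnotatedDocument:
    """Parse a brat ``.txt``/``.ann`` pair into an :class:`AnnotatedDocument`.

    Only text-bound ``T`` lines are consumed; notes, attributes and relations
    are ignored with a logged warning.  Offsets and surfaces are checked
    against ``text_content``; labels are checked against ``ontology`` when one
    is given (``skip_unknown_labels=True`` drops unknown-label lines instead
    of raising).
    """
    spans: list[EntitySpan] = []
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            logger.warning("ignoring non-text-bound annotation line %d: %r", lineno, line)
            continue
        m = _TEXTBOUND_RE.match(line)
        if m is None:
            raise MalformedAnnotationError(f"unparseable annotation line {lineno}: {line!r}")
        label, start_s, end_s, surface = m.groups()
        start, end = int(start_s), int(end_s)
        if not (0 <= start < end <= len(text_content)):
            raise MalformedAnnotationError(
                f"line {lineno}: offsets ({start}, {end}) out of range for "
                f"text of length {len(text_content)}"
            )
        if text_content[start:end] != surface:
            raise MalformedAnnotationError(
                f"line {lineno}: surface {surface!r} does not match text slice "
                f"{text_content[start:end]!r}"
            )
        if ontology is not None and not ontology.contains(label):
            if skip_unknown_labels:
                logger.warning("line %d: skipping unknown label %r", lineno, label)
                continue
            raise UnknownLabelError(f"line {lineno}: unknown label {label!r}")
        spans.append(EntitySpan(start, end, label, surface))
    return AnnotatedDocument(
        doc_id=doc_id,
        patient_id=patient_id,
        doc_type=doc_type,
        text=text_content,
        spans=tuple(spans),
    )


def write_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Emit the (text, ann) pair for a document in brat standoff form."""
    lines = [
        f"T{i}\t{s.label} {s.start} {s.end}\t{s.surface}"
        for i, s in enumerate(doc.spans, start=1)
    ]
    ann = "\n".join(lines)
    if lines:
        ann += "\n"
    return doc.text, ann


# ---------------------------------------------------------------------------
# Corpus-level I/O: brat directories and line-delimited JSON records
# ---------------------------------------------------------------------------


def write_brat_dir(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    """Write one ``.txt``/``.ann`` pair per document plus a manifest TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for doc in docs:
        text, ann = write_standoff(doc)
        (path / f"{doc.doc_id}.txt").write_text(text)
        (path / f"{doc.doc_id}.ann").write_text(ann)
        rows.append(f"{doc.doc_id}\t{doc.patient_id}\t{doc.doc_type}")
    (path / "manifest.tsv").write_text(
        "doc_id\tpatient_id\tdoc_type\n" + "".join(r + "\n" for r in rows)
    )


def read_brat_dir(
    path: str | Path, ontology: "Ontology | None" = None, **kwargs
) -> list[AnnotatedDocument]:
    path = Path(path)
    manifest = path / "manifest.tsv"
    meta: dict[str, tuple[str, str]] = {}
    if manifest.exists():
        for line in manifest.read_text().splitlines()[1:]:
            doc_id, patient_id, doc_type = line.split("\t")
            meta[doc_id] = (patient_id, doc_type)
    docs = []
    for txt in sorted(path.glob("*.txt")):
        doc_id = txt.stem
        ann = txt.with_suffix(".ann")
        patient_id, doc_type = meta.get(doc_id, ("", ""))
        docs.append(
            read_standoff(
                txt.read_text(),
                ann.read_text() if ann.exists() else "",
                ontology,
                doc_id=doc_id,
                patient_id=patient_id,
                doc_type=doc_type,
                **kwargs,
            )
        )
    return docs


def write_jsonl_corpus(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    """One JSON record per line: id, patient id, type, text, spans."""
    with open(path, "w") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "patient_id": doc.patient_id,
                        "doc_type": doc.doc_type,
                        "text": doc.text,
                        "spans": [
                            [s.start, s.end, s.label] for s in doc.spans
                        ],
                    }
                )
                + "\n"
            )


def read_jsonl_corpus(path: str | Path) -> list[AnnotatedDocument]:
    docs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            text = rec["text"]
            spans = tuple(
                EntitySpan(s, e, lab, text[s:e]) for s, e, lab in rec["spans"]
            )
            docs.append(
                AnnotatedDocument(
                    doc_id=rec["doc_id"],
                    patient_id=rec["patient_id"],
                    doc_type=rec["doc_type"],
                    text=text,
                    spans=spans,
                )
            )
    return docs


LogitMatrix = np.ndarray
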