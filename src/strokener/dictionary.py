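"""Exact string-search NER baseline.

Training annotations are compiled into a mapping from normalized surface form
to entity label; a form observed under two or more distinct labels is
ambiguous and excluded outright (never assigned a majority label).
Prediction scans each document for dictionary forms anchored at token
boundaries, resolving overlaps longest-match-first, leftmost-first.

Normalization (shared with the label-property statistics): lowercase and
collapse internal whitespace.  Matching never fires inside a word — "fall"
cannot hit inside "falls" — because candidates are built from whole tokens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .standoff import AnnotatedDocument, EntitySpan, TokenSequence, tokenize


def normalize(surface: str) -> str:
    """Canonical form of a surface string: lowercase, whitespace collapsed."""
    return " ".join(surface.lower().split())


@dataclass
class SpanDictionary:
    """Surface-form → label mapping with the ambiguous forms excluded."""

    forms: dict[str, str]
    ambiguous: frozenset[str] = frozenset()
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.forms) & set(self.ambiguous)
        if overlap:
            raise ValueError(f"forms both mapped and ambiguous: {sorted(overlap)[:5]}")
        if any(not f for f in self.forms):
            raise ValueError("empty surface form in dictionary")
        self._max_tokens = max(
            (len(tokenize(f)) for f in self.forms), default=0
        )

    def __len__(self) -> int:
        return len(self.forms)

    @property
    def max_form_tokens(self) -> int:
        return self._max_tokens

    def save(self, path: str | Path) -> None:
        payload = {
            "forms": dict(sorted(self.forms.items())),
            "ambiguous": sorted(self.ambiguous),
            "counts": {f: dict(c) for f, c in sorted(self.counts.items())},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SpanDictionary":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            forms=dict(raw["forms"]),
            ambiguous=frozenset(raw.get("ambiguous", ())),
            counts={f: dict(c) for f, c in raw.get("counts", {}).items()},
        )


def compile_dictionary(train_docs: Iterable[AnnotatedDocument]) -> SpanDictionary:
    """Compile the string-search dictionary from gold training spans.

    Forms differing only in case or internal whitespace collapse to one
    entry.  An empty corpus yields a valid empty dictionary.
    """
    counts: dict[str, Counter] = {}
    for doc in train_docs:
        for span in doc.spans:
            form = normalize(span.surface)
            if not form:
                continue
            counts.setdefault(form, Counter())[span.label] += 1
    forms: dict[str, str] = {}
    ambiguous: set[str] = set()
    for form, label_counts in counts.items():
        if len(label_counts) > 1:
            ambiguous.add(form)
        else:
            forms[form] = next(iter(label_counts))
    return SpanDictionary(
        forms=forms,
        ambiguous=frozenset(ambiguous),
        counts={f: dict(c) for f, c in counts.items()},
    )


def _candidate_form(tokens: Sequence, i: int, j: int) -> str:
    """Normalized surface of tokens ``i..j`` (inclusive), gap-aware.

    Tokens separated by whitespace in the source text are joined with a
    single space; adjacent tokens (punctuation splits) are concatenated —
    exactly what ``normalize`` yields on the original text slice.
    """
    parts = [tokens[i].surface]
    for k in range(i + 1, j + 1):
        if tokens[k].start > tokens[k - 1].end:
            parts.append(" ")
        parts.append(tokens[k].surface)
    return "".join(parts).lower()


def match_tokens(
    tokens: TokenSequence, dictionary: SpanDictionary
) -> list[tuple[int, int, str]]:
    """Non-overlapping dictionary hits as (first token, last token, label).

    Scans left to right, trying the longest candidate first at each
    position; a hit consumes its tokens, so output is deterministic and
    independent of document iteration order.
    """
    hits: list[tuple[int, int, str]] = []
    n = len(tokens)
    max_len = dictionary.max_form_tokens
    i = 0
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            j = i + length - 1
            label = dictionary.forms.get(_candidate_form(tokens, i, j))
            if label is not None:
                hits.append((i, j, label))
                i = j + 1
                matched = True
                break
        if not matched:
            i += 1
    return hits


def predict(doc: AnnotatedDocument, dictionary: SpanDictionary) -> list[EntitySpan]:
    """All token-boundary occurrences of dictionary forms in one document."""
    tokens = tokenize(doc.text)
    spans = []
    for i, j, label in match_tokens(tokens, dictionary):
        start, end = tokens[i].start, tokens[j].end
        spans.append(EntitySpan(start, end, label, doc.text[start:end]))
    return spans
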