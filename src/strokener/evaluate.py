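"""Strict and lenient span-matching evaluation.

Strict matching pairs a prediction with a gold span only when (start, end,
label) are identical; lenient matching requires the same label and at least
one shared character.  Pairing is one-to-one and greedy: candidate pairs are
taken in order of descending character overlap, ties broken by earlier gold
span, then earlier prediction.  The same machinery scores model predictions
against gold and human annotators against consensus gold.

Zero-denominator conventions: precision (or recall) is 0 when its denominator
is 0 while the other side is non-empty; labels with neither gold spans nor
predictions are excluded from macro averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .dictionary import normalize
from .standoff import AnnotatedDocument, EntitySpan

Mode = Literal["strict", "lenient"]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching of predictions onto gold spans for one document."""

    pairs: tuple[tuple[EntitySpan, EntitySpan], ...]  # (gold, pred)
    unmatched_gold: tuple[EntitySpan, ...]
    unmatched_pred: tuple[EntitySpan, ...]
    mode: Mode

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gold)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)


def _compatible(gold: EntitySpan, pred: EntitySpan, mode: Mode) -> bool:
    if gold.label != pred.label:
        return False
    if mode == "strict":
        return gold.start == pred.start and gold.end == pred.end
    return gold.overlap_chars(pred) > 0


def match_spans(
    gold: Sequence[EntitySpan], pred: Sequence[EntitySpan], mode: Mode
) -> MatchResult:
    """Greedy one-to-one matching by descending character overlap."""
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    candidates = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            if _compatible(g, p, mode):
                candidates.append(
                    (-g.overlap_chars(p), g.start, g.end, p.start, p.end, gi, pi)
                )
    candidates.sort()
    gold_used = [False] * len(gold)
    pred_used = [False] * len(pred)
    pairs = []
    for _, _, _, _, _, gi, pi in candidates:
        if not gold_used[gi] and not pred_used[pi]:
            gold_used[gi] = True
            pred_used[pi] = True
            pairs.append((gold[gi], pred[pi]))
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_gold=tuple(g for g, u in zip(gold, gold_used) if not u),
        unmatched_pred=tuple(p for p, u in zip(pred, pred_used) if not u),
        mode=mode,
    )


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class Aggregate:
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    """Per-label and pooled precision/recall/F1 under one matching mode."""

    mode: Mode
    per_label: pd.DataFrame  # index label; columns tp fp fn precision recall f1 support
    micro: Aggregate
    macro: Aggregate

    def f1_by_label(self) -> dict[str, float]:
        return self.per_label["f1"].to_dict()

    def to_text(self) -> str:
        lines = [self.per_label.to_string(float_format=lambda v: f"{v:.3f}")]
        lines.append(
            f"micro ({self.mode}): P={self.micro.precision:.3f} "
            f"R={self.micro.recall:.3f} F1={self.micro.f1:.3f}"
        )
        lines.append(
            f"macro ({self.mode}): P={self.macro.precision:.3f} "
            f"R={self.macro.recall:.3f} F1={self.macro.f1:.3f}"
        )
        return "\n".join(lines)


def _pair_docs(
    gold_docs: Sequence[AnnotatedDocument], pred_docs: Sequence[AnnotatedDocument]
) -> list[tuple[AnnotatedDocument, AnnotatedDocument]]:
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(pred_by_id) != {d.doc_id for d in gold_docs} or len(pred_docs) != len(
        pred_by_id
    ):
        raise ValueError("gold and prediction document ids do not align")
    return [(g, pred_by_id[g.doc_id]) for g in gold_docs]


def score_corpus(
    gold_docs: Sequence[AnnotatedDocument],
    pred_docs: Sequence[AnnotatedDocument],
    mode: Mode,
) -> EvalReport:
    """Corpus-level evaluation: per-label counts, micro and macro averages.

    Documents are aligned by ``doc_id``; a mismatch raises.  Micro metrics
    pool TP/FP/FN over all labels and documents; macro metrics average the
    per-label metrics over labels with any gold or predicted spans.
    """
    counts: dict[str, list[int]] = {}  # label -> [tp, fp, fn]
    for gold_doc, pred_doc in _pair_docs(gold_docs, pred_docs):
        labels = {s.label for s in gold_doc.spans} | {s.label for s in pred_doc.spans}
        for label in labels:
            g = [s for s in gold_doc.spans if s.label == label]
            p = [s for s in pred_doc.spans if s.label == label]
            m = match_spans(g, p, mode)
            row = counts.setdefault(label, [0, 0, 0])
            row[0] += m.tp
            row[1] += m.fp
            row[2] += m.fn
    rows = {}
    for label in sorted(counts):
        tp, fp, fn = counts[label]
        p, r, f1 = _prf(tp, fp, fn)
        rows[label] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": p,
            "recall": r,
            "f1": f1,
            "support": tp + fn,
        }
    per_label = pd.DataFrame.from_dict(rows, orient="index")
    if per_label.empty:
        per_label = pd.DataFrame(
            columns=["tp", "fp", "fn", "precision", "recall", "f1", "support"]
        )
    tp = int(per_label["tp"].sum()) if len(per_label) else 0
    fp = int(per_label["fp"].sum()) if len(per_label) else 0
    fn = int(per_label["fn"].sum()) if len(per_label) else 0
    micro = Aggregate(*_prf(tp, fp, fn))
    if len(per_label):
        macro = Aggregate(
            float(per_label["precision"].mean()),
            float(per_label["recall"].mean()),
            float(per_label["f1"].mean()),
        )
    else:
        macro = Aggregate(0.0, 0.0, 0.0)
    return EvalReport(mode=mode, per_label=per_label, micro=micro, macro=macro)


def agreement(
    annotator_docs: Sequence[AnnotatedDocument],
    gold_docs: Sequence[AnnotatedDocument],
    mode: Mode,
) -> EvalReport:
    """Annotator-vs-consensus scoring: the annotator is the prediction side."""
    return score_corpus(gold_docs, annotator_docs, mode)


def indict_partition(
    train_docs: Sequence[AnnotatedDocument],
    test_gold: Sequence[AnnotatedDocument],
    test_pred: Sequence[AnnotatedDocument],
    mode: Mode,
) -> tuple[float | None, float | None]:
    """Recall split into in-dict and out-dict portions of the test gold.

    A gold test span is in-dict when its normalized surface occurred with
    the same label anywhere in the training gold; recall is computed
    separately for each class.  An empty class yields ``None`` rather than
    a number.
    """
    seen = {
        (normalize(s.surface), s.label)
        for doc in train_docs
        for s in doc.spans
    }
    matched = {"in": 0, "out": 0}
    total = {"in": 0, "out": 0}
    for gold_doc, pred_doc in _pair_docs(test_gold, test_pred):
        m = match_spans(gold_doc.spans, pred_doc.spans, mode)
        matched_gold = {id(g) for g, _ in m.pairs}
        for g in gold_doc.spans:
            cls = "in" if (normalize(g.surface), g.label) in seen else "out"
            total[cls] += 1
            if id(g) in matched_gold:
                matched[cls] += 1
    recall_in = matched["in"] / total["in"] if total["in"] else None
    recall_out = matched["out"] / total["out"] if total["out"] else None
    return recall_in, recall_out
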