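"""Synthetic annotated clinical-letter generator with an annotator-noise model.

The real training material for this problem — letters held in an NHS safe
haven — cannot be redistributed, so the toolkit ships a generator that
emulates its structural features: several document types per patient, a
long-tailed (Zipf) distribution of entity-label frequencies, per-label pools
of alternative surface forms (controlling name regularity), and per-label
pools of sentence templates (controlling context regularity).  Letters are
assembled from a header, entity-bearing sentences instantiated from
templates, and entity-free filler sentences; every gold span carries exact
character offsets and falls on token boundaries of the default tokenizer.

The noise model perturbs gold annotations the way human annotators err:
missed spans (deletions), boundary slack (token-level jitter), label
confusions, and spurious spans.  All generation is deterministic given the
seed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ontology import Ontology, load_default_ontology
from .standoff import DOC_TYPES, AnnotatedDocument, EntitySpan, tokenize

# Document-type mix defaults follow the corpus composition the generator
# emulates (GP referrals dominate; ED letters and endoscopy reports are rare).
DEFAULT_DOC_TYPE_MIX: dict[str, float] = {
    "GP referral": 4403 / 8067,
    "IDL": 1850 / 8067,
    "FDL": 1474 / 8067,
    "OPCL": 582 / 8067,
    "ED Letter": 56 / 8067,
    "Endoscopy report": 192 / 8067,
}


class SimulationError(ValueError):
    pass


def _load_lines(name: str) -> list[str]:
    text = (resources.files("strokener.data") / name).read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def default_templates() -> list[str]:
    return _load_lines("templates.txt")


def default_fillers() -> list[str]:
    return _load_lines("fillers.txt")


@dataclass(frozen=True)
class LabelConfig:
    """Surface-form pool (with optional weights) and template pool for one label."""

    forms: tuple[str, ...]
    form_weights: tuple[float, ...] | None = None
    templates: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.form_weights is not None and len(self.form_weights) != len(self.forms):
            raise SimulationError("form_weights length must match forms")


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for one synthetic corpus.

    Defaults are scaled for desk-speed experiments (200 patients, ~560
    documents, 5,000 spans) while keeping the shape of the emulated data:
    about 2.8 documents per patient, 7–9 spans per document, Zipf-tailed
    label frequencies over the full 86-entity inventory.
    """

    seed: int
    n_patients: int = 200
    docs_per_patient_mean: float = 2.8
    doc_type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOC_TYPE_MIX)
    )
    total_spans: int = 5000
    zipf_exponent: float = 1.1
    labels: Mapping[str, LabelConfig] | None = None  # None → ontology seed pools
    templates_per_label: int | None = None
    filler_rate: float = 0.5

    def resolve_labels(self, ontology: Ontology | None = None) -> dict[str, LabelConfig]:
        if self.labels is not None:
            return dict(self.labels)
        onto = ontology if ontology is not None else load_default_ontology()
        return {
            ent.id: LabelConfig(forms=tuple(ent.surface_forms())) for ent in onto
        }


@dataclass(frozen=True)
class NoiseConfig:
    """Annotator-error rates: deletions, spurious spans, jitter, confusions."""

    deletion_prob: float = 0.0
    spurious_rate: float = 0.0  # expected spurious spans per document
    jitter_prob: float = 0.0
    jitter_max_tokens: int = 1
    confusion_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("deletion_prob", "jitter_prob", "confusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.spurious_rate < 0:
            raise SimulationError("spurious_rate must be non-negative")
        if self.jitter_max_tokens < 1:
            raise SimulationError("jitter_max_tokens must be >= 1")


_HEADER = (
    "Document-ID: {doc_id}\n"
    "Patient-ID: {patient_id}\n"
    "Document type: {doc_type}\n"
    "\n"
    "Dear Doctor ,\n"
    "\n"
)
_FOOTER = "\nYours sincerely ,\nThe clinical team\n"


def _label_templates(
    label_index: int,
    cfg: LabelConfig,
    pool: Sequence[str],
    per_label: int | None,
) -> list[str]:
    if cfg.templates is not None:
        return list(cfg.templates)
    if per_label is None:
        return list(pool)
    k = min(per_label, len(pool))
    # rotate through the global pool so different labels get different subsets
    return [pool[(label_index + t) % len(pool)] for t in range(k)]


def generate_corpus(
    config: CorpusConfig, ontology: Ontology | None = None
) -> list[AnnotatedDocument]:
    """Generate a gold-annotated synthetic corpus; byte-identical per seed."""
    rng = np.random.default_rng(config.seed)
    labels = config.resolve_labels(ontology)
    if not labels:
        raise SimulationError("no labels configured")
    for name, cfg in labels.items():
        if not cfg.forms:
            raise SimulationError(
                f"label {name!r} has an empty surface-form pool; "
                "its frequency target cannot be satisfied"
            )
    label_names = list(labels)
    weights = np.array(
        [1.0 / (r + 1) ** config.zipf_exponent for r in range(len(label_names))]
    )
    weights /= weights.sum()
    label_counts = rng.multinomial(config.total_spans, weights)

    mix_types = list(config.doc_type_mix)
    mix_probs = np.array([config.doc_type_mix[t] for t in mix_types], dtype=float)
    if mix_probs.sum() <= 0:
        raise SimulationError("doc_type_mix does not normalize")
    mix_probs /= mix_probs.sum()

    template_pool = default_templates()
    fillers = default_fillers()

    # document skeletons
    doc_meta: list[tuple[str, str, str]] = []
    for p in range(config.n_patients):
        patient_id = f"P{p:04d}"
        n_docs = 1 + rng.poisson(max(config.docs_per_patient_mean - 1.0, 0.0))
        for _ in range(n_docs):
            doc_type = mix_types[rng.choice(len(mix_types), p=mix_probs)]
            doc_meta.append((f"D{len(doc_meta):05d}", patient_id, doc_type))
    n_docs = len(doc_meta)

    # mention plan: (label, surface, template), shuffled, then dealt to docs
    mentions: list[tuple[str, str, str]] = []
    for li, (name, cfg) in enumerate(labels.items()):
        count = int(label_counts[li])
        if count == 0:
            continue
        ltemplates = _label_templates(li, cfg, template_pool, config.templates_per_label)
        form_p = None
        if cfg.form_weights is not None:
            form_p = np.array(cfg.form_weights, dtype=float)
            form_p /= form_p.sum()
        form_idx = rng.choice(len(cfg.forms), size=count, p=form_p)
        tmpl_idx = rng.choice(len(ltemplates), size=count)
        for fi, ti in zip(form_idx, tmpl_idx):
            mentions.append((name, cfg.forms[fi], ltemplates[ti]))
    order = rng.permutation(len(mentions))
    doc_of = rng.integers(0, n_docs, size=len(mentions))
    per_doc: list[list[tuple[str, str, str]]] = [[] for _ in range(n_docs)]
    for k, mi in enumerate(order):
        per_doc[doc_of[k]].append(mentions[mi])

    docs: list[AnnotatedDocument] = []
    for (doc_id, patient_id, doc_type), doc_mentions in zip(doc_meta, per_doc):
        parts = [_HEADER.format(doc_id=doc_id, patient_id=patient_id, doc_type=doc_type)]
        pos = len(parts[0])
        spans: list[EntitySpan] = []
        if not doc_mentions:
            n_fill = int(1 + rng.integers(0, 2))
            for _ in range(n_fill):
                line = fillers[rng.integers(0, len(fillers))] + "\n"
                parts.append(line)
                pos += len(line)
        for label, surface, template in doc_mentions:
            if rng.random() < config.filler_rate:
                line = fillers[rng.integers(0, len(fillers))] + "\n"
                parts.append(line)
                pos += len(line)
            pre, post = template.split("{E}", 1)
            line = pre + surface + post + "\n"
            start = pos + len(pre)
            spans.append(EntitySpan(start, start + len(surface), label, surface))
            parts.append(line)
            pos += len(line)
        parts.append(_FOOTER)
        text = "".join(parts)
        doc = AnnotatedDocument(
            doc_id=doc_id,
            patient_id=patient_id,
            doc_type=doc_type,
            text=text,
            spans=tuple(spans),
        )
        doc.validate()
        docs.append(doc)
    return docs


def _token_range(tokens, span: EntitySpan) -> tuple[int, int] | None:
    idx = [
        i for i, t in enumerate(tokens) if t.start < span.end and span.start < t.end
    ]
    if not idx:
        return None
    return idx[0], idx[-1]


def perturb_annotations(
    gold_docs: Sequence[AnnotatedDocument],
    noise: NoiseConfig,
    seed: int,
) -> list[AnnotatedDocument]:
    """Apply the annotator-noise model to a gold corpus.

    Deletion drops a span outright; jitter moves each boundary by up to
    ``jitter_max_tokens`` whole tokens (never losing all overlap with the
    original span, so lenient matching survives while strict matching
    breaks); confusion relabels a span to a random other corpus label;
    spurious spans annotate a random 1–2 token run that overlaps no existing
    span.  All-zero noise returns documents equal to the gold input.
    """
    rng = np.random.default_rng(seed)
    corpus_labels = sorted({s.label for d in gold_docs for s in d.spans})
    out: list[AnnotatedDocument] = []
    for doc in gold_docs:
        tokens = tokenize(doc.text)
        new_spans: list[EntitySpan] = []
        for span in doc.spans:
            if noise.deletion_prob > 0 and rng.random() < noise.deletion_prob:
                continue
            label = span.label
            if noise.confusion_prob > 0 and rng.random() < noise.confusion_prob:
                others = [l for l in corpus_labels if l != label]
                if others:
                    label = others[rng.integers(0, len(others))]
            start, end = span.start, span.end
            if noise.jitter_prob > 0 and rng.random() < noise.jitter_prob:
                rng_range = _token_range(tokens, span)
                if rng_range is not None:
                    first, last = rng_range
                    m = noise.jitter_max_tokens
                    side = 2 * m + 1
                    # draw a non-zero (ds, de) pair uniformly
                    flat = int(rng.integers(0, side * side - 1))
                    if flat >= (side * side) // 2:
                        flat += 1  # skip the (0, 0) centre cell
                    ds, de = flat // side - m, flat % side - m
                    nf = min(max(first + ds, 0), len(tokens) - 1)
                    nl = min(max(last + de, 0), len(tokens) - 1)
                    if nf <= nl and nf <= last and nl >= first:
                        start, end = tokens[nf].start, tokens[nl].end
            new_spans.append(EntitySpan(start, end, label, doc.text[start:end]))
        if noise.spurious_rate > 0:
            n_spurious = int(rng.poisson(noise.spurious_rate))
            occupied = [(s.start, s.end) for s in new_spans] + [
                (s.start, s.end) for s in doc.spans
            ]
            for _ in range(n_spurious):
                for _attempt in range(20):
                    i = int(rng.integers(0, len(tokens)))
                    j = min(i + int(rng.integers(1, 3)) - 1, len(tokens) - 1)
                    start, end = tokens[i].start, tokens[j].end
                    if any(start < e and s < end for s, e in occupied):
                        continue
                    label = corpus_labels[rng.integers(0, len(corpus_labels))]
                    new_spans.append(
                        EntitySpan(start, end, label, doc.text[start:end])
                    )
                    occupied.append((start, end))
                    break
        # drop duplicates that jitter may have created
        seen: set[tuple[int, int, str]] = set()
        unique = []
        for s in sorted(new_spans, key=lambda s: (s.start, s.end, s.label)):
            key = (s.start, s.end, s.label)
            if key not in seen:
                seen.add(key)
                unique.append(s)
        out.append(doc.with_spans(unique))
    return out


def split_patients(
    docs: Sequence[AnnotatedDocument],
    test_fraction: float,
    k_folds: int,
    seed: int,
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument], dict[str, int]]:
    """Patient-level train/test split plus a k-fold assignment of train patients.

    Every document of one patient lands on one side of the split and in one
    fold; fold sizes differ by at most one patient.
    """
    if k_folds < 2:
        raise SimulationError("k_folds must be at least 2")
    if not 0.0 <= test_fraction < 1.0:
        raise SimulationError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    patients = sorted({d.patient_id for d in docs})
    if any(not p for p in patients):
        raise SimulationError("every document needs a patient id")
    perm = [patients[i] for i in rng.permutation(len(patients))]
    n_test = int(round(test_fraction * len(perm)))
    test_patients = set(perm[:n_test])
    train_patients = perm[n_test:]
    folds = {p: i % k_folds for i, p in enumerate(train_patients)}
    train = [d for d in docs if d.patient_id not in test_patients]
    test = [d for d in docs if d.patient_id in test_patients]
    return train, test, folds
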