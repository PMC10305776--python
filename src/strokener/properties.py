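"""Per-label properties and the regression linking them to per-label F1.

Three properties are computed for each entity label from a gold-annotated
training corpus:

* **Training-set frequency** ``N`` — the number of annotated spans.
* **Name regularity** — ``(N - N_unique) / (N - 1)`` where ``N_unique``
  counts distinct normalized surface forms.  The statistic is 1 exactly when
  every span is the same string and 0 exactly when all spans differ, and it
  is invariant to span order and casing.
* **Semantic context regularity** — for each mention, take up to 5 tokens on
  either side of the span, average their word embeddings, L2-normalize the
  mean, and report the mean pairwise dot product (cosine similarity) over all
  unordered mention pairs: ``2/(N(N-1)) Σ_{i<j} x_i · x_j``.

A multiple linear regression (ordinary least squares with intercept) then
relates per-label lenient F1 to [log10 frequency, name regularity, context
regularity], reporting coefficients with classical standard errors, two-sided
t-test p-values, and r².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dictionary import normalize
from .standoff import AnnotatedDocument, EntitySpan, tokenize

logger = logging.getLogger(__name__)

PREDICTORS = ("log10_frequency", "name_regularity", "context_regularity")


class SingularDesignError(ValueError):
    """The regression design matrix is rank-deficient."""


def name_regularity(spans: Sequence[str]) -> float:
    """Surface-form repetitiveness of one label, in [0, 1].

    Spans are normalized (lowercase, whitespace collapsed) before counting
    distinct forms.  A single span returns 1 by convention; an empty list is
    an error.
    """
    if not spans:
        raise ValueError("name_regularity of an empty span list is undefined")
    forms = [normalize(s) for s in spans]
    n = len(forms)
    if n == 1:
        return 1.0
    n_unique = len(set(forms))
    return (n - n_unique) / (n - 1)


def _context_window(
    tokens, span: EntitySpan, window: int
) -> list[str]:
    """Up to ``window`` token surfaces on each side of the span."""
    inside = [
        i for i, t in enumerate(tokens) if t.start < span.end and span.start < t.end
    ]
    if not inside:
        return []
    lo = max(0, inside[0] - window)
    hi = min(len(tokens), inside[-1] + 1 + window)
    return [tokens[i].surface.lower() for i in list(range(lo, inside[0])) + list(range(inside[-1] + 1, hi))]


@dataclass(frozen=True)
class ContextVector:
    """L2-normalized mean embedding of one mention's context tokens."""

    vector: np.ndarray
    n_tokens: int


def _mention_vectors(
    mentions: Iterable[tuple[AnnotatedDocument, EntitySpan]],
    embeddings,
    window: int,
    _token_cache: dict | None = None,
) -> tuple[list[ContextVector], int]:
    cache = _token_cache if _token_cache is not None else {}
    vectors: list[ContextVector] = []
    skipped = 0
    for doc, span in mentions:
        toks = cache.get(doc.doc_id)
        if toks is None:
            toks = tokenize(doc.text)
            cache[doc.doc_id] = toks
        words = [w for w in _context_window(toks, span, window) if w in embeddings]
        if not words:
            skipped += 1
            continue
        mean = np.mean([embeddings[w] for w in words], axis=0)
        norm = np.linalg.norm(mean)
        if norm == 0:
            skipped += 1
            continue
        vectors.append(ContextVector(mean / norm, len(words)))
    return vectors, skipped


def context_regularity(
    mentions: Sequence[tuple[AnnotatedDocument, EntitySpan]],
    embeddings,
    window: int = 5,
) -> float | None:
    """Mean pairwise cosine similarity of mention context vectors.

    Mentions whose window holds no in-vocabulary token are skipped (and
    logged); fewer than two usable mentions returns ``None``.  Values are not
    clamped: with embedding spaces admitting negative similarities the
    statistic can fall below 0.
    """
    vectors, skipped = _mention_vectors(mentions, embeddings, window)
    if skipped:
        logger.debug("context_regularity: skipped %d mentions without context", skipped)
    if len(vectors) < 2:
        return None
    mat = np.stack([cv.vector for cv in vectors])
    gram = mat @ mat.T
    n = len(vectors)
    upper = gram[np.triu_indices(n, k=1)]
    return float(upper.mean())


@dataclass(frozen=True)
class LabelProperties:
    label: str
    frequency: int
    n_unique: int
    name_regularity: float
    context_regularity: float | None
    n_context_mentions: int

    @property
    def log10_frequency(self) -> float:
        return math.log10(self.frequency)


def compute_properties(
    train_docs: Sequence[AnnotatedDocument],
    embeddings=None,
    window: int = 5,
) -> list[LabelProperties]:
    """One property row per label observed in the training gold."""
    by_label: dict[str, list[tuple[AnnotatedDocument, EntitySpan]]] = {}
    for doc in train_docs:
        for span in doc.spans:
            by_label.setdefault(span.label, []).append((doc, span))
    token_cache: dict = {}
    out = []
    for label in sorted(by_label):
        mentions = by_label[label]
        surfaces = [s.surface for _, s in mentions]
        if embeddings is not None:
            vectors, _ = _mention_vectors(mentions, embeddings, window, token_cache)
            if len(vectors) >= 2:
                mat = np.stack([cv.vector for cv in vectors])
                upper = (mat @ mat.T)[np.triu_indices(len(vectors), k=1)]
                ctx: float | None = float(upper.mean())
            else:
                ctx = None
            n_ctx = len(vectors)
        else:
            ctx, n_ctx = None, 0
        out.append(
            LabelProperties(
                label=label,
                frequency=len(surfaces),
                n_unique=len({normalize(s) for s in surfaces}),
                name_regularity=name_regularity(surfaces),
                context_regularity=ctx,
                n_context_mentions=n_ctx,
            )
        )
    return out


def properties_table(props: Sequence[LabelProperties]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [p.label for p in props],
            "frequency": [p.frequency for p in props],
            "log10_frequency": [p.log10_frequency for p in props],
            "n_unique": [p.n_unique for p in props],
            "name_regularity": [p.name_regularity for p in props],
            "context_regularity": [
                np.nan if p.context_regularity is None else p.context_regularity
                for p in props
            ],
            "n_context_mentions": [p.n_context_mentions for p in props],
        }
    ).set_index("label")


@dataclass(frozen=True)
class Coefficient:
    beta: float
    se: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    coefficients: Mapping[str, Coefficient]  # predictors + "intercept"
    r_squared: float
    n_labels: int
    dropped_labels: tuple[str, ...]

    def to_text(self) -> str:
        lines = [f"n_labels={self.n_labels}  r2={self.r_squared:.3f}"]
        for name in ("intercept", *PREDICTORS):
            c = self.coefficients[name]
            lines.append(
                f"{name:>20s}  beta={c.beta:+.4f}  SE={c.se:.4f}  p={c.p_value:.3g}"
            )
        if self.dropped_labels:
            lines.append(
                "dropped (no F1 score or undefined predictors): "
                + ", ".join(self.dropped_labels)
            )
        return "\n".join(lines)


def regress_f1(
    props: Sequence[LabelProperties],
    per_label_f1: Mapping[str, float],
) -> RegressionResult:
    """OLS of per-label lenient F1 on the three label properties.

    Labels missing an F1 score or with undefined context regularity are
    dropped and reported.  A rank-deficient design (for instance a constant
    predictor) raises :class:`SingularDesignError`.
    """
    rows, dropped = [], []
    for p in props:
        if p.label not in per_label_f1 or p.context_regularity is None:
            dropped.append(p.label)
            continue
        rows.append(
            (
                p.label,
                p.log10_frequency,
                p.name_regularity,
                p.context_regularity,
                per_label_f1[p.label],
            )
        )
    if len(rows) < len(PREDICTORS) + 2:
        raise ValueError(
            f"need at least {len(PREDICTORS) + 2} usable labels, got {len(rows)}"
        )
    frame = pd.DataFrame(
        rows, columns=["label", *PREDICTORS, "f1"]
    ).set_index("label")
    X = sm.add_constant(frame[list(PREDICTORS)].to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")
    model = sm.OLS(frame["f1"].to_numpy(), X).fit()
    names = ("intercept", *PREDICTORS)
    coeffs = {
        name: Coefficient(
            beta=float(model.params[i]),
            se=float(model.bse[i]),
            p_value=float(model.pvalues[i]),
        )
        for i, name in enumerate(names)
    }
    return RegressionResult(
        coefficients=coeffs,
        r_squared=float(model.rsquared),
        n_labels=len(rows),
        dropped_labels=tuple(dropped),
    )
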