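"""Token-classifier contract and logit-averaging ensembling.

Any object exposing ``tag_space`` (the shared ordered IOB tag list) and
``logits(tokens) -> (n_tokens, 2N+1)`` can join an ensemble.  Member logits
are averaged elementwise — not softmaxed first — so a confidently scored
minority member can outvote a lukewarm majority, and rescaling one member's
logits changes the outcome.  The per-token argmax uses a deterministic
tie-break: the lowest tag index wins, and since ``O`` is index 0 the ensemble
is conservative toward precision at exact ties.

A dictionary-backed adapter realizes the contract so ensembling is fully
exercisable without any trained neural model.
"""

from __future__ import annotations

from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .dictionary import SpanDictionary, match_tokens
from .standoff import TagSequence, TokenSequence


class TagSpaceMismatchError(ValueError):
    pass


@runtime_checkable
class TokenClassifier(Protocol):
    tag_space: Sequence[str]

    def logits(self, tokens: TokenSequence) -> np.ndarray: ...


def tag_space_fingerprint(tags: Sequence[str]) -> str:
    import hashlib

    return hashlib.sha256("\x00".join(tags).encode()).hexdigest()[:16]


def average_logits(
    tokens: TokenSequence, members: Sequence[TokenClassifier]
) -> np.ndarray:
    """Elementwise mean of member logit matrices over a shared tag space."""
    if not members:
        raise ValueError("ensemble needs at least one member")
    space = tuple(members[0].tag_space)
    for m in members[1:]:
        if tuple(m.tag_space) != space:
            raise TagSpaceMismatchError(
                "ensemble members declare different tag spaces "
                f"({tag_space_fingerprint(space)} vs "
                f"{tag_space_fingerprint(m.tag_space)})"
            )
    mats = []
    for m in members:
        mat = np.asarray(m.logits(tokens), dtype=float)
        if mat.shape != (len(tokens), len(space)):
            raise ValueError(
                f"member logits shape {mat.shape} != {(len(tokens), len(space))}"
            )
        if not np.all(np.isfinite(mat)):
            raise ValueError("non-finite logits")
        mats.append(mat)
    return np.mean(mats, axis=0)


def ensemble_predict(
    tokens: TokenSequence, members: Sequence[TokenClassifier]
) -> TagSequence:
    """Average member logits and take the per-token argmax.

    At an exact tie of mean logits, ``O`` wins over entity tags and
    otherwise the lowest tag index wins (``np.argmax`` takes the first
    maximal index; in the standard tag ordering ``O`` is index 0, so both
    rules coincide).
    """
    mean = average_logits(tokens, members)
    space = list(members[0].tag_space)
    o_col = space.index("O") if "O" in space else None
    idx = np.argmax(mean, axis=1)
    if o_col is not None:
        row_max = mean[np.arange(len(idx)), idx]
        idx = np.where(mean[:, o_col] == row_max, o_col, idx)
    return TagSequence(space[i] for i in idx)


class DictionaryClassifier:
    """String-search baseline wrapped as a token classifier.

    Tokens inside a dictionary match score ``+confidence`` on their B-/I- tag
    and 0 on ``O``; unmatched tokens score ``+confidence`` on ``O``.  With
    confidence 0 every row ties and the tie-break yields all-``O``.
    """

    def __init__(
        self,
        dictionary: SpanDictionary,
        tag_space: Sequence[str],
        confidence: float = 1.0,
    ):
        if confidence < 0:
            raise ValueError("confidence must be non-negative")
        self.dictionary = dictionary
        self.tag_space = list(tag_space)
        self.confidence = float(confidence)
        self._tag_index = {t: i for i, t in enumerate(self.tag_space)}

    def logits(self, tokens: TokenSequence) -> np.ndarray:
        mat = np.zeros((len(tokens), len(self.tag_space)))
        o_col = self._tag_index["O"]
        mat[:, o_col] = self.confidence
        for i, j, label in match_tokens(tokens, self.dictionary):
            b = self._tag_index.get(f"B-{label}")
            inner = self._tag_index.get(f"I-{label}")
            if b is None or inner is None:
                continue  # dictionary label outside the declared tag space
            mat[i : j + 1, o_col] = 0.0
            mat[i, b] = self.confidence
            if j > i:
                mat[i + 1 : j + 1, inner] = self.confidence
        return mat


# ---------------------------------------------------------------------------
# Logit interchange format: one TSV row per token (start, end, 2N+1 scores),
# preceded by a header line naming the tag columns.
# ---------------------------------------------------------------------------


def write_logits(
    tokens: TokenSequence, logits: np.ndarray, tag_space: Sequence[str], path: str | Path
) -> None:
    logits = np.asarray(logits)
    if logits.shape != (len(tokens), len(tag_space)):
        raise ValueError("logit matrix shape does not match tokens/tag space")
    with open(path, "w") as fh:
        fh.write("start\tend\t" + "\t".join(tag_space) + "\n")
        for tok, row in zip(tokens, logits):
            fh.write(
                f"{tok.start}\t{tok.end}\t"
                + "\t".join(f"{x:.8g}" for x in row)
                + "\n"
            )


def read_logits(path: str | Path) -> tuple[list[tuple[int, int]], np.ndarray, list[str]]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    tag_space = header[2:]
    offsets, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        offsets.append((int(parts[0]), int(parts[1])))
        rows.append([float(x) for x in parts[2:]])
    return offsets, np.array(rows), tag_space


class StoredLogitClassifier:
    """Replays a logit interchange file as an ensemble member."""

    def __init__(self, path: str | Path):
        self._offsets, self._logits, self.tag_space = read_logits(path)

    def logits(self, tokens: TokenSequence) -> np.ndarray:
        if [(t.start, t.end) for t in tokens] != self._offsets:
            raise ValueError("stored logits do not align with these tokens")
        return self._logits
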