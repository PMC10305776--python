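"""Word-embedding tables for the context-regularity statistic.

Two sources are supported: any table in plain word2vec text format (header
line ``<count> <dim>``, then one ``word v1 ... vd`` line per word), and a
deterministic hash-based table that assigns every word a fixed pseudo-random
unit vector.  The hash table carries no distributional semantics — it is a
reproducible stand-in that makes identical contexts score 1 and unrelated
contexts score near 0, which is what the simulator-based tests need.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np


class WordEmbeddings:
    """In-memory word → vector table with dict-style access."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding table")
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {dims}")
        self._vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dim = next(iter(self._vectors.values())).shape[0]

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def __len__(self) -> int:
        return len(self._vectors)

    @classmethod
    def from_word2vec_text(cls, path: str | Path) -> "WordEmbeddings":
        """Read a plain-text word2vec table (``count dim`` header line)."""
        vectors: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError("expected 'count dim' header line")
            _, dim = int(header[0]), int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"bad embedding line for {parts[0]!r}")
                vectors[parts[0]] = np.array(parts[1:], dtype=float)
        return cls(vectors)

    def to_word2vec_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self._vectors)} {self.dim}\n")
            for word, vec in self._vectors.items():
                fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


class HashEmbeddings:
    """Deterministic pseudo-random unit vector per word; full vocabulary.

    The vector for a word is drawn from a generator seeded by the BLAKE2
    digest of the word, so the table is identical across processes and
    platforms without storing any data.
    """

    def __init__(self, dim: int = 32, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def __contains__(self, word: str) -> bool:
        return True

    def __getitem__(self, word: str) -> np.ndarray:
        vec = self._cache.get(word)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{word}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim)
            vec /= np.linalg.norm(vec)
            self._cache[word] = vec
        return vec


def load_embeddings(spec: str) -> "WordEmbeddings | HashEmbeddings":
    """Resolve an embedding source: ``hash`` / ``hash:<dim>`` or a file path."""
    if spec == "hash":
        return HashEmbeddings()
    if spec.startswith("hash:"):
        return HashEmbeddings(dim=int(spec.split(":", 1)[1]))
    return WordEmbeddings.from_word2vec_text(spec)
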