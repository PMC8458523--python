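"""Repertoire and sequence similarity: DCI, token-level Levenshtein LSI,
set-median strings, and singer-by-singer similarity matrices.

DCI (Dice coincidence index) compares phrase-type repertoires::

    DCI = 2 * |A shared| / (|B| + |C|)

LSI (Levenshtein similarity index) compares theme sequences token-wise::

    LSI(a, b) = 1 - min(I + D + S) / max(L(a), L(b))

Edit operations act on whole theme tokens ("Cb" is one symbol), never on
characters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import ThemeSequence

__all__ = [
    "EmptyRepertoireError",
    "SimilarityMatrix",
    "dci",
    "token_edit_distance",
    "lsi",
    "set_median",
    "dci_matrix",
    "lsi_matrix",
]

Tokens = Union[ThemeSequence, Sequence[str]]


class EmptyRepertoireError(ValueError):
    pass


def _as_tokens(seq: Tokens) -> tuple[str, ...]:
    if isinstance(seq, ThemeSequence):
        return seq.tokens
    return tuple(seq)


def dci(rep_a: Iterable[str], rep_b: Iterable[str],
        label_a: str = "a", label_b: str = "b") -> float:
    """Dice coincidence index of two phrase-type repertoires, in [0, 1].

    1 iff the sets are equal, 0 iff disjoint.  Empty repertoires are an
    error naming the offending singer.
    """
    a, b = set(rep_a), set(rep_b)
    if not a:
        raise EmptyRepertoireError(f"singer {label_a!r} has an empty repertoire")
    if not b:
        raise EmptyRepertoireError(f"singer {label_b!r} has an empty repertoire")
    return 2.0 * len(a & b) / (len(a) + len(b))


def token_edit_distance(a: Tokens, b: Tokens) -> int:
    """Levenshtein distance over theme tokens: the minimum number of
    insertions, deletions and substitutions (unit cost) turning ``a`` into
    ``b``.  Standard dynamic programming."""
    s, t = _as_tokens(a), _as_tokens(b)
    if len(s) < len(t):
        s, t = t, s
    prev = list(range(len(t) + 1))
    for i, sa in enumerate(s, start=1):
        cur = [i] + [0] * len(t)
        for j, tb in enumerate(t, start=1):
            cost = 0 if sa == tb else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[-1]


def lsi(a: Tokens, b: Tokens) -> float:
    """Levenshtein similarity index: 1 - distance / max(length); in [0, 1],
    1 iff the token sequences are identical."""
    s, t = _as_tokens(a), _as_tokens(b)
    if not s or not t:
        raise ValueError("LSI is undefined for empty sequences")
    return 1.0 - token_edit_distance(s, t) / max(len(s), len(t))


def set_median(sequences: Sequence[Tokens]) -> tuple[str, ...]:
    """The member sequence with the highest total LSI to all other members
    (self-similarity excluded).  Ties break to the earliest input position;
    a singleton set returns its element.
    """
    seqs = [_as_tokens(s) for s in sequences]
    if not seqs:
        raise ValueError("set_median of an empty set")
    if len(seqs) == 1:
        return seqs[0]
    best_idx = 0
    best_score = -np.inf
    for i, cand in enumerate(seqs):
        score = sum(lsi(cand, other) for j, other in enumerate(seqs) if j != i)
        if score > best_score:
            best_idx, best_score = i, score
    return seqs[best_idx]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric singer-by-singer similarity matrix in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: str  # "DCI" or "LSI"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        if self.method not in ("DCI", "LSI"):
            raise ValueError("method must be 'DCI' or 'LSI'")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_distance(self) -> np.ndarray:
        """d = 1 - s."""
        return 1.0 - self.values

    def to_csv(self, path: str | Path, metadata: Optional[dict] = None) -> None:
        """Write as labelled CSV with a JSON sidecar recording the method."""
        path = Path(path)
        df = pd.DataFrame(self.values, index=list(self.labels),
                          columns=list(self.labels))
        df.to_csv(path, index_label="singer_id")
        sidecar = {"method": self.method, "n": len(self.labels)}
        if metadata:
            sidecar.update(metadata)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path, method: Optional[str] = None
                 ) -> "SimilarityMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        if method is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            method = json.loads(sidecar.read_text())["method"]
        return cls(tuple(df.index), df.to_numpy(float), method)


def dci_matrix(repertoires: Mapping[str, Iterable[str]]) -> SimilarityMatrix:
    """Full symmetric DCI matrix over singers' phrase-type repertoires."""
    labels = tuple(repertoires.keys())
    sets = [frozenset(repertoires[lab]) for lab in labels]
    for lab, s in zip(labels, sets):
        if not s:
            raise EmptyRepertoireError(f"singer {lab!r} has an empty repertoire")
    n = len(labels)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dci(sets[i], sets[j], labels[i], labels[j])
    return SimilarityMatrix(labels, m, "DCI")


def lsi_matrix(medians: Mapping[str, Tokens]) -> SimilarityMatrix:
    """Full symmetric LSI matrix over singers' set-median theme sequences."""
    labels = tuple(medians.keys())
    seqs = [_as_tokens(medians[lab]) for lab in labels]
    for lab, s in zip(labels, seqs):
        if not s:
            raise ValueError(f"singer {lab!r} has an empty theme sequence")
    n = len(labels)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = lsi(seqs[i], seqs[j])
    return SimilarityMatrix(labels, m, "LSI")
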