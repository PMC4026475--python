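"""Kimura 2-parameter distances and Nei net between-group divergence.

Distances are computed on a gapped alignment with the R2 repeat region
masked out (the array cannot be aligned across length variants).  Sites
with a gap or ambiguity in either member of a pair are excluded pairwise
("pairwise deletion"); complete deletion is available behind a flag.
K2P separates the transition proportion P from the transversion
proportion Q:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignedSet",
    "DistanceMatrix",
    "K2PSaturationError",
    "k2p",
    "k2p_matrix",
    "group_mean_divergence",
    "net_divergence",
]

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i
_PURINE = np.array([1, 0, 1, 0], dtype=np.int8)  # A, G purines; C, T pyrimidines


class K2PSaturationError(ValueError):
    """Raised when 1-2P-Q <= 0 or 1-2Q <= 0 and the K2P log diverges."""


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class AlignedSet:
    """Equal-length gapped sequences plus a set of masked columns."""

    labels: list[str]
    sequences: list[str]
    mask: frozenset[int] = frozenset()
    _codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences must have equal length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"gapped sequence lengths differ: {sorted(lengths)}")
        self.mask = frozenset(self.mask)
        n_col = lengths.pop() if lengths else 0
        if any(c < 0 or c >= n_col for c in self.mask):
            raise ValueError("mask refers to columns outside the alignment")
        self._codes = (
            np.vstack([_encode(s) for s in self.sequences])
            if self.sequences
            else np.empty((0, 0), dtype=np.int8)
        )

    @property
    def n_columns(self) -> int:
        return self._codes.shape[1]

    @property
    def codes(self) -> np.ndarray:
        """(n, columns) int8 matrix; -1 encodes gaps/ambiguity."""
        return self._codes

    def column_keep(self) -> np.ndarray:
        keep = np.ones(self.n_columns, dtype=bool)
        if self.mask:
            keep[list(self.mask)] = False
        return keep

    def sequence(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]

    def core_sequences(self) -> dict[str, str]:
        """Sequences restricted to unmasked columns (the alignable core)."""
        keep = self.column_keep()
        return {
            label: "".join(ch for ch, k in zip(seq, keep) if k)
            for label, seq in zip(self.labels, self.sequences)
        }

    @classmethod
    def from_fasta(cls, path, mask: Iterable[int] = ()) -> "AlignedSet":
        from Bio import SeqIO

        labels, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(labels, seqs, frozenset(mask))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, seq in zip(self.labels, self.sequences):
                fh.write(f">{label}\n{seq}\n")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distances with per-pair P and Q retained for audit."""

    labels: tuple[str, ...]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        for m in (self.d, self.P, self.Q):
            if m.shape != (n, n):
                raise ValueError("matrix shape does not match labels")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix_mean(self, rows: Sequence[int], cols: Sequence[int]) -> float:
        return float(self.d[np.ix_(rows, cols)].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style output."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, label in enumerate(self.labels):
                row = " ".join(f"{self.d[i, j]:.6f}" for j in range(i))
                fh.write(f"{label}\t{row}\n".rstrip() + "\n")


def _pq(ci: np.ndarray, cj: np.ndarray, keep: np.ndarray) -> tuple[float, float, int]:
    valid = (ci >= 0) & (cj >= 0) & keep
    n = int(valid.sum())
    if n == 0:
        return np.nan, np.nan, 0
    a, b = ci[valid], cj[valid]
    diff = a != b
    ts = diff & (_PURINE[a] == _PURINE[b])
    P = float(ts.sum()) / n
    Q = float(diff.sum() - ts.sum()) / n
    return P, Q, n


def _k2p_from_pq(P: float, Q: float, pair: str) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise K2PSaturationError(f"K2P distance saturated for pair {pair} (P={P:.4f}, Q={Q:.4f})")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p(
    seq_i: str,
    seq_j: str,
    mask: Iterable[int] = (),
) -> float:
    """K2P distance between two equal-length gapped sequences.

    Masked columns and sites with a gap/ambiguity in either sequence are
    excluded.  Raises on zero comparable sites or a saturated distance.
    """
    if len(seq_i) != len(seq_j):
        raise ValueError("sequences must have equal gapped length")
    keep = np.ones(len(seq_i), dtype=bool)
    mask = list(mask)
    if mask:
        keep[mask] = False
    P, Q, n = _pq(_encode(seq_i), _encode(seq_j), keep)
    if n == 0:
        raise ValueError("no comparable sites between the two sequences")
    return _k2p_from_pq(P, Q, "(i,j)")


def k2p_matrix(aligned: AlignedSet, *, complete_deletion: bool = False) -> DistanceMatrix:
    """All-pairs K2P distances over an aligned set (pairwise deletion by default)."""
    codes = aligned.codes
    n = codes.shape[0]
    keep = aligned.column_keep()
    if complete_deletion:
        keep = keep & (codes >= 0).all(axis=0)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q, m = _pq(codes[i], codes[j], keep)
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {aligned.labels[i]} and {aligned.labels[j]}"
                )
            pair = f"({aligned.labels[i]}, {aligned.labels[j]})"
            d[i, j] = d[j, i] = _k2p_from_pq(p, q, pair)
            P[i, j] = P[j, i] = p
            Q[i, j] = Q[j, i] = q
    return DistanceMatrix(tuple(aligned.labels), d, P, Q)


def _group_indices(dm: DistanceMatrix, group: Iterable[str]) -> list[int]:
    idx = [dm.index(label) for label in group]
    if not idx:
        raise ValueError("group must be non-empty")
    return idx


def group_mean_divergence(dm: DistanceMatrix, group_x: Iterable[str], group_y: Iterable[str]) -> float:
    """Plain between-group mean distance (the 'average sequence divergence')."""
    xi, yi = _group_indices(dm, group_x), _group_indices(dm, group_y)
    if set(xi) & set(yi):
        raise ValueError("groups overlap")
    return dm.submatrix_mean(xi, yi)


def _within_mean(dm: DistanceMatrix, idx: list[int]) -> float:
    if len(idx) < 2:
        return 0.0
    sub = dm.d[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))


def net_divergence(dm: DistanceMatrix, group_x: Iterable[str], group_y: Iterable[str]) -> float:
    """Nei net divergence: between-mean minus the average of the within-means.

    Within-group mean of a singleton group is 0, so for two singletons the
    net divergence equals the pairwise distance.
    """
    xi, yi = _group_indices(dm, group_x), _group_indices(dm, group_y)
    if set(xi) & set(yi):
        raise ValueError("groups overlap")
    between = dm.submatrix_mean(xi, yi)
    return between - 0.5 * (_within_mean(dm, xi) + _within_mean(dm, yi))
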