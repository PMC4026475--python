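"""Poisson model of polymerase/cloning artefacts in cloned PCR products.

Every cloned sequence is a single molecule sampled from the PCR, so each
carries the substitution errors its template lineage accumulated over the
amplification.  Treating errors as rare and independent per base and per
cycle gives a Poisson number of errors per clone with mean

    lambda = rate * length * cycles

(e.g. 7.2e-5 errors/bp/cycle * 724 bp * 34 cycles = 1.77 errors/clone).
Tail probabilities of that distribution say how many clones are expected
to carry more than k errors, and a re-cloning experiment (re-cloning a
single cloned molecule and sequencing the daughters) measures the real
per-clone error load against the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ErrorModel", "CloneErrorSummary", "expected_errors", "tail_fraction", "summarize_recloning"]


def expected_errors(rate: float, length: float, cycles: float) -> float:
    """Expected errors per cloned sequence: rate x length x cycles."""
    if rate < 0 or length < 0 or cycles < 0:
        raise ValueError("rate, length and cycles must all be non-negative")
    return rate * length * cycles


def tail_fraction(lam: float, k: int) -> float:
    """P(errors > k) for a clone under Poisson(lam)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(stats.poisson.sf(k, lam))


@dataclass(frozen=True)
class ErrorModel:
    """Per-clone polymerase error model.

    lambda is always recomputed from its factors; it is never stored.
    """

    rate: float = 7.2e-5
    length: int = 724
    cycles: int = 34

    def __post_init__(self) -> None:
        expected_errors(self.rate, self.length, self.cycles)  # validates

    @property
    def lam(self) -> float:
        return expected_errors(self.rate, self.length, self.cycles)

    def tail_fraction(self, k: int) -> float:
        return tail_fraction(self.lam, k)

    def error_free_fraction(self) -> float:
        """Poisson zero class: fraction of clones expected without any error."""
        return float(np.exp(-self.lam))

    def collapse_threshold(self) -> int:
        """Sites of difference attributable to polymerase error alone.

        ceil(lambda + 2*sqrt(lambda)): roughly mean + 2 SD of the per-clone
        error count.
        """
        lam = self.lam
        return int(np.ceil(lam + 2.0 * np.sqrt(lam)))

    def with_length(self, length: int) -> "ErrorModel":
        return ErrorModel(self.rate, length, self.cycles)


@dataclass(frozen=True)
class CloneErrorSummary:
    n_clones: int
    total_mutations: int
    n_identical: int
    tie_columns: tuple[int, ...] = ()

    @property
    def mean_per_clone(self) -> float:
        return self.total_mutations / self.n_clones

    @property
    def fraction_identical(self) -> float:
        return self.n_identical / self.n_clones


def summarize_recloning(clones: Sequence[str]) -> CloneErrorSummary:
    """Count mutations of re-cloned sequences against their consensus.

    The consensus is the per-site majority base; ties go to the base seen
    first in clone order and the tied columns are flagged.  A clone is
    "identical" when it matches the consensus at every site.
    """
    if len(clones) < 2:
        raise ValueError("need at least two clones")
    lengths = {len(c) for c in clones}
    if len(lengths) != 1:
        raise ValueError(f"clone lengths differ: {sorted(lengths)}")
    arr = np.vstack([np.frombuffer(c.upper().encode(), dtype=np.uint8) for c in clones])
    n, L = arr.shape
    consensus = np.empty(L, dtype=np.uint8)
    ties = []
    for col in range(L):
        values, counts = np.unique(arr[:, col], return_counts=True)
        top = counts.max()
        winners = set(values[counts == top])
        if len(winners) > 1:
            ties.append(col)
            for b in arr[:, col]:  # first-seen among the tied bases
                if int(b) in winners:
                    consensus[col] = b
                    break
        else:
            consensus[col] = values[np.argmax(counts)]
    diffs = (arr != consensus[None, :]).sum(axis=1)
    return CloneErrorSummary(
        n_clones=n,
        total_mutations=int(diffs.sum()),
        n_identical=int((diffs == 0).sum()),
        tie_columns=tuple(ties),
    )
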