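"""R2 tandem-array detection and run-length decomposition.

A control-region sequence may carry an R2 array: a tandem run of 11-bp
units, each belonging to one of a few motif classes that differ by one or
two substitutions, occasionally interrupted by a truncated (partial) unit.
This module finds the array, assigns every unit to its nearest motif
class, and reports the run-length structure, the full-unit count N and the
array length.  Sequences without an array (numts, in this system) yield an
empty decomposition with N = 0.
"""

from __future__ import annotations

import functools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .motifs import DEFAULT_INVENTORY, MotifInventory, Run, structure_string

__all__ = [
    "UnitCall",
    "RepeatDecomposition",
    "infer_period",
    "decompose",
    "discover_motifs",
    "structure_summary",
]


@dataclass(frozen=True)
class UnitCall:
    """One full unit inside an array: where it sits and how it was classified."""

    start: int
    observed: str
    label: str
    distance: int

    @property
    def exact(self) -> bool:
        return self.distance == 0


@dataclass(frozen=True)
class RepeatDecomposition:
    """Run-length structure of the R2 array of one sequence.

    Coordinates are 0-based half-open on the input sequence.  ``runs`` is an
    ordered list of ``(motif label | literal string, count)``; adjacent runs
    never share a label.  ``n_units`` (N) counts full units only; literal
    partial units contribute to ``array_length`` but not to N.
    """

    array_start: int
    array_end: int
    runs: tuple[Run, ...]
    unit_calls: tuple[UnitCall, ...] = field(default=(), repr=False)

    @property
    def is_empty(self) -> bool:
        return self.array_end == self.array_start

    @property
    def n_units(self) -> int:
        return sum(c for lab, c in self.runs if len(lab) == 1)

    @property
    def array_length(self) -> int:
        return self.array_end - self.array_start

    @property
    def flagged_units(self) -> tuple[UnitCall, ...]:
        """Units assigned to a class inexactly (edit distance 1-2)."""
        return tuple(u for u in self.unit_calls if not u.exact)

    @property
    def structure(self) -> str:
        return structure_string(self.runs)

    def array_sequence(self, inventory: MotifInventory = DEFAULT_INVENTORY) -> str:
        """Rebuild the array from the *observed* units and literals."""
        parts, i = [], 0
        for lab, count in self.runs:
            if len(lab) > 1:
                parts.append(lab * count)
            else:
                for _ in range(count):
                    parts.append(self.unit_calls[i].observed)
                    i += 1
        return "".join(parts)


EMPTY = RepeatDecomposition(0, 0, ())


def infer_period(
    seq: str,
    *,
    k: int = 8,
    min_period: int = 5,
    max_period: int = 50,
    min_recurrences: int = 3,
) -> int | None:
    """Infer the repeat-unit length by exact k-mer recurrence counting.

    For each candidate spacing ``p`` the number of positions ``i`` with
    ``seq[i:i+k] == seq[i+p:i+p+k]`` is counted; the spacing with the most
    recurrences wins (smallest period on ties).  Returns ``None`` when no
    spacing reaches ``min_recurrences`` — the signature of a sequence
    without tandem structure.
    """
    n = len(seq)
    if n < min_period + k:
        return None
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    best_p, best_count = None, min_recurrences - 1
    for p in range(min_period, max_period + 1):
        m = n - p - k + 1
        if m <= 0:
            break
        eq = codes[: m + k - 1] == codes[p : p + m + k - 1]
        # positions where all k consecutive comparisons hold
        run = np.convolve(eq.astype(np.int32), np.ones(k, dtype=np.int32), "valid")
        count = int(np.count_nonzero(run == k))
        if count > best_count:
            best_p, best_count = p, count
    return best_p


@functools.lru_cache(maxsize=200_000)
def _unit_distance(window: str, units: tuple[str, ...]) -> tuple[int, int]:
    """(best unit index, edit distance) of a window against an inventory."""
    best_i, best_d = 0, len(window) + 1
    for i, unit in enumerate(units):
        if window == unit:
            return i, 0
        d = edlib.align(window, unit, task="distance")["editDistance"]
        if d < best_d:
            best_i, best_d = i, d
    return best_i, best_d


def _auto_inventory(seq: str) -> MotifInventory | None:
    """Seed an inventory from the most frequent exact unit of the inferred period."""
    p = infer_period(seq)
    if p is None:
        return None
    counts: Counter[str] = Counter()
    for i in range(len(seq) - 2 * p + 1):
        if seq[i : i + p] == seq[i + p : i + 2 * p]:
            counts[seq[i : i + p]] += 1
    if not counts:
        return None
    top = max(counts.items(), key=lambda kv: (kv[1], -seq.find(kv[0])))[0]
    return MotifInventory.from_units([top])


def decompose(
    seq: str,
    inventory: MotifInventory | None = DEFAULT_INVENTORY,
    *,
    max_unit_distance: int = 2,
    min_units: int = 2,
    min_internal_literal: int = 2,
    min_flank_literal: int = 5,
) -> RepeatDecomposition:
    """Find and decompose the maximal R2 array in ``seq``.

    The array is the best-scoring contiguous tiling of the sequence by
    full units (11-bp windows within edit distance ``max_unit_distance``
    of some inventory unit) and short literal segments.  Literals model
    truncated units and must be an exact prefix or suffix of an inventory
    unit; internal literals may be as short as ``min_internal_literal``,
    while array-boundary literals must reach ``min_flank_literal`` so that
    random flanking sequence is not absorbed.  The tiling maximising
    (exact units, total units, −literal bp) wins, leftmost on ties; each
    inexact unit is assigned to its nearest class (earlier label on ties)
    and flagged.  Sequences with no qualifying tiling return an empty
    decomposition with N = 0.
    """
    seq = seq.upper()
    if inventory is None:
        inventory = _auto_inventory(seq)
        if inventory is None:
            return EMPTY
    units = inventory.units
    u = inventory.period
    L = len(seq)
    if L < u * min_units:
        return EMPTY

    affixes: dict[str, bool] = {}
    for unit in units:
        for l in range(1, u):
            affixes.setdefault(unit[:l], True)
            affixes.setdefault(unit[-l:], True)

    # Unit match per start position: substitution (Hamming) distance screens
    # first — it equals the edit distance for the substitution-dominated
    # variation seen in these arrays — with a Levenshtein fallback so that
    # indel-shifted units within the tolerance are still recognised.
    match: list[tuple[int, int] | None] = [None] * L
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(codes, u)
    unit_codes = np.array([np.frombuffer(x.encode(), dtype=np.uint8) for x in units])
    ham = (win[:, None, :] != unit_codes[None, :, :]).sum(axis=2)
    best_idx = ham.argmin(axis=1)  # argmin takes the first minimum: earlier label
    best_d = ham.min(axis=1)
    for i in range(L - u + 1):
        if best_d[i] <= max_unit_distance:
            match[i] = (int(best_idx[i]), int(best_d[i]))
        else:
            bi, bd = _unit_distance(seq[i : i + u], units)
            if bd <= max_unit_distance:
                match[i] = (bi, bd)

    # DP over tiling end positions. state[i] = best tiling ending exactly at i:
    # (value, start, prev_pos, op) with value = (n_exact, n_units, -literal_bp)
    # and op in {("unit", label_idx, dist), ("lit", length)}.
    Value = tuple[int, int, int]
    state: dict[int, tuple[Value, int, int | None, tuple]] = {}

    def offer(end: int, value: Value, start: int, prev: int | None, op: tuple) -> None:
        cur = state.get(end)
        if cur is None or value > cur[0] or (value == cur[0] and start < cur[1]):
            state[end] = (value, start, prev, op)

    for i in range(L):
        here = state.get(i)
        # full unit starting at i
        if i + u <= L and match[i] is not None:
            idx, dist = match[i]
            gain = (1 if dist == 0 else 0, 1, 0)
            op = ("unit", idx, dist)
            if here is not None:
                v = tuple(a + b for a, b in zip(here[0], gain))
                offer(i + u, v, here[1], i, op)
            offer(i + u, gain, i, None, op)
        # literal segment starting at i
        for l in range(1, u):
            if i + l > L:
                break
            w = seq[i : i + l]
            if w not in affixes:
                continue
            if here is not None and here[3][0] != "lit" and l >= min_internal_literal:
                v = (here[0][0], here[0][1], here[0][2] - l)
                offer(i + l, v, here[1], i, ("lit", l))
            if l >= min_flank_literal:
                offer(i + l, (0, 0, -l), i, None, ("lit", l))

    # best end, ignoring trailing literals shorter than the flank minimum
    best_end, best = None, None
    for end, (value, start, prev, op) in state.items():
        if op[0] == "lit" and op[1] < min_flank_literal:
            continue
        if (
            best is None
            or value > best[0]
            or (value == best[0] and (start, end) < (best[1], best_end))
        ):
            best_end, best = end, (value, start, prev, op)

    if best is None or best[0][1] < min_units:
        return EMPTY

    # backtrack
    ops: list[tuple[int, tuple]] = []
    end = best_end
    value, start, prev, op = best
    while True:
        ops.append((end if op[0] == "lit" else end, op))
        pos = prev
        if pos is None:
            seg_start = end - (op[1] if op[0] == "lit" else u)
            break
        end = pos
        value, start, prev, op = state[pos]
    ops.reverse()

    runs: list[Run] = []
    calls: list[UnitCall] = []
    pos = seg_start
    for _, op in ops:
        if op[0] == "unit":
            label = inventory.labels[op[1]]
            calls.append(UnitCall(pos, seq[pos : pos + u], label, op[2]))
            if runs and runs[-1][0] == label:
                runs[-1] = (label, runs[-1][1] + 1)
            else:
                runs.append((label, 1))
            pos += u
        else:
            runs.append((seq[pos : pos + op[1]], 1))
            pos += op[1]
    return RepeatDecomposition(seg_start, pos, tuple(runs), tuple(calls))


def discover_motifs(
    decompositions: Iterable[RepeatDecomposition],
    canonical: MotifInventory | None = None,
    *,
    min_count: int = 1,
) -> MotifInventory:
    """Build a frequency-ranked motif inventory from observed full units.

    Distinct observed unit sequences are ranked by total count and
    labelled A, B, ... in rank order.  When a ``canonical`` inventory is
    given, units present in it keep their canonical labels and novel units
    take the next free letters.  Raises if every decomposition is empty.
    """
    counts: Counter[str] = Counter()
    for dec in decompositions:
        for call in dec.unit_calls:
            counts[call.observed] += 1
    ranked = [u for u, c in counts.most_common() if c >= min_count]
    if not ranked:
        raise ValueError("no repeat arrays found")
    if canonical is None:
        return MotifInventory.from_units(ranked)
    labels, units = list(canonical.labels), list(canonical.units)
    next_ord = max((ord(l) for l in labels if len(l) == 1), default=ord("A") - 1) + 1
    for unit in ranked:
        if unit not in units:
            labels.append(chr(next_ord))
            units.append(unit)
            next_ord += 1
    return MotifInventory(tuple(labels), tuple(units))


def structure_summary(
    decompositions: Mapping[str, RepeatDecomposition],
    taxa: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-sequence array structure and per-taxon motif richness.

    Returns ``(per_sequence, per_taxon)`` frames.  ``per_sequence`` mirrors
    the published table layout (ID, array length, N, structure string);
    ``per_taxon`` counts the distinct motif classes used by each taxon's
    arrays.
    """
    rows = []
    for seq_id, dec in decompositions.items():
        rows.append(
            {
                "id": seq_id,
                "taxon": taxa.get(seq_id, "") if taxa else "",
                "array_length": dec.array_length,
                "n_units": dec.n_units,
                "structure": dec.structure,
            }
        )
    per_seq = pd.DataFrame(rows, columns=["id", "taxon", "array_length", "n_units", "structure"])
    if taxa:
        richness = []
        for taxon in sorted(set(taxa.values())):
            labels: set[str] = set()
            for seq_id, dec in decompositions.items():
                if taxa.get(seq_id) == taxon:
                    labels.update(lab for lab, _ in dec.runs if len(lab) == 1)
            richness.append({"taxon": taxon, "n_motif_classes": len(labels)})
        per_taxon = pd.DataFrame(richness, columns=["taxon", "n_motif_classes"])
    else:
        per_taxon = pd.DataFrame(columns=["taxon", "n_motif_classes"])
    return per_seq, per_taxon
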