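"""Independent brute-force oracles used to check the implementation.

These deliberately use naive enumeration / closed forms and share no code
with the package's own algorithms.
"""

from __future__ import annotations

import itertools
import math


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def oracle_period(seq: str, k: int, lo: int, hi: int, min_rec: int = 3) -> int | None:
    """Exhaustive k-mer recurrence count over every candidate spacing."""
    best_p, best_c = None, min_rec - 1
    for p in range(lo, hi + 1):
        c = sum(seq[i : i + k] == seq[i + p : i + p + k] for i in range(len(seq) - p - k + 1))
        if c > best_c:
            best_p, best_c = p, c
    return best_p


def oracle_decompose(seq: str, units: tuple[str, ...], labels: tuple[str, ...]) -> list[tuple[str, int]]:
    """Exhaustive-phase decomposition of a pure full-unit array.

    Tries every phase offset, tiles fixed-width windows, assigns each to
    its minimum-Hamming-distance class (earlier label on ties) and keeps
    the offset maximising exact units (smaller offset on ties).  Intended
    for sequences that are concatenations of (possibly fuzzed) full
    units, with no flanks or partial units.
    """
    u = len(units[0])
    best = None
    for offset in range(u):
        m = (len(seq) - offset) // u
        if m == 0:
            continue
        calls = []
        for t in range(m):
            w = seq[offset + t * u : offset + (t + 1) * u]
            ds = [hamming(w, unit) for unit in units]
            d = min(ds)
            calls.append((labels[ds.index(d)], d))
        n_exact = sum(1 for _, d in calls if d == 0)
        key = (n_exact, m, -offset)
        if best is None or key > best[0]:
            best = (key, calls)
    runs: list[tuple[str, int]] = []
    for label, _ in best[1]:
        if runs and runs[-1][0] == label:
            runs[-1] = (label, runs[-1][1] + 1)
        else:
            runs.append((label, 1))
    return runs


def oracle_k2p(P: float, Q: float) -> float:
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def oracle_poisson_sf(lam: float, k: int, terms: int = 400) -> float:
    """1 - CDF by direct series summation."""
    total = 0.0
    for i in range(k + 1):
        total += math.exp(-lam) * lam**i / math.factorial(i)
    return 1.0 - total


def oracle_gap_steps(a: str, b: str) -> int:
    """Steps by explicit event enumeration on short toy pairs.

    Counts substitutions site-by-site and compresses each maximal run of
    single-sided gap columns into one event, skipping shared-gap columns.
    """
    events = 0
    prev = None
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            side = "a" if x == "-" else "b"
            if side != prev:
                events += 1
            prev = side
        else:
            if x != y:
                events += 1
            prev = None
    return events


def oracle_msn_edges(
    nodes: list[str], weight: dict[tuple[str, str], int]
) -> set[tuple[str, str]]:
    """Union of all minimum spanning trees by full enumeration."""

    def w(a: str, b: str) -> int:
        return weight[(a, b)] if (a, b) in weight else weight[(b, a)]

    all_edges = list(itertools.combinations(nodes, 2))
    n = len(nodes)
    best_cost = None
    best_trees: list[tuple[tuple[str, str], ...]] = []
    for subset in itertools.combinations(all_edges, n - 1):
        # connectivity check
        parent = {x: x for x in nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if not ok:
            continue
        cost = sum(w(a, b) for a, b in subset)
        if best_cost is None or cost < best_cost:
            best_cost, best_trees = cost, [subset]
        elif cost == best_cost:
            best_trees.append(subset)
    out: set[tuple[str, str]] = set()
    for tree in best_trees:
        for a, b in tree:
            out.add((min(a, b), max(a, b)))
    return out
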