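"""Clade partitioning, haplotype networks, numt and heteroplasmy calls.

The analysis separates cloned control-region sequences into clades by
hierarchical clustering of K2P distances, then decides which clades are
nuclear copies (numts) rather than authentic mtDNA using three lines of
evidence: numts carry no R2 repeat array, they fall outside the clade
containing independently verified (anchor) mtDNA sequences, and their
haplotypes are separated by fewer mutational steps (reduced substitution
rate after translocation into the nucleus).  Within the authentic clade,
heteroplasmy is called per individual as extra core-sequence haplotypes
(sequence heteroplasmy) and as multiple R2 array-length classes (length
heteroplasmy), discounting variation attributable to polymerase error.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix
from .errors import ErrorModel
from .repeats import RepeatDecomposition

__all__ = [
    "CladePartition",
    "HaplotypeNetwork",
    "NumtCall",
    "NumtReport",
    "HeteroplasmyCall",
    "partition_clades",
    "mutational_steps",
    "build_network",
    "call_numts",
    "call_heteroplasmy",
]


# ---------------------------------------------------------------------------
# clade partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladePartition:
    """Clade label per sequence, with the dendrogram cut that produced it."""

    labels: tuple[str, ...]
    clades: tuple[int, ...]
    cut_height: float
    linkage: np.ndarray = field(repr=False)
    separation: Mapping[int, float] = field(default_factory=dict)

    @property
    def n_clades(self) -> int:
        return len(set(self.clades))

    def members(self, clade: int) -> list[str]:
        return [l for l, c in zip(self.labels, self.clades) if c == clade]

    def clade_of(self, label: str) -> int:
        return self.clades[self.labels.index(label)]

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for l, c in zip(self.labels, self.clades):
            out[c].append(l)
        return dict(out)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            bl_l = node.dist - node.left.dist
            bl_r = node.dist - node.right.dist
            return f"({rec(node.left)}:{bl_l:.6f},{rec(node.right)}:{bl_r:.6f})"

        return rec(tree) + ";"


def _silhouette(d: np.ndarray, clades: np.ndarray) -> dict[int, float]:
    """Mean silhouette width per clade (separation score)."""
    out: dict[int, float] = {}
    ids = np.unique(clades)
    if len(ids) < 2:
        return {int(ids[0]): 0.0} if len(ids) else {}
    for cid in ids:
        mine = np.where(clades == cid)[0]
        scores = []
        for i in mine:
            within = d[i, mine[mine != i]]
            a = within.mean() if within.size else 0.0
            b = min(d[i, clades == other].mean() for other in ids if other != cid)
            denom = max(a, b)
            scores.append(0.0 if denom == 0 else (b - a) / denom)
        out[int(cid)] = float(np.mean(scores))
    return out


def partition_clades(
    dm: DistanceMatrix,
    *,
    min_ratio: float = 5.0,
    height_floor: float | None = None,
) -> CladePartition:
    """Partition sequences into clades by average-linkage clustering.

    The dendrogram is cut at the largest relative gap between successive
    merge heights (heights below a noise floor — default a quarter of the
    median positive height — are floored so that merges of identical
    clones do not produce degenerate ratios).  The cut is accepted only if
    the resulting partition separates well: mean between-clade distance
    over mean within-clade distance must reach ``min_ratio``; otherwise
    the trivial one-clade partition is returned.
    """
    n = len(dm.labels)
    if n < 2:
        return CladePartition(tuple(dm.labels), (1,) * n, 0.0, np.empty((0, 4)), {1: 0.0})
    Z = hierarchy.linkage(squareform(dm.d, checks=False), method="average")
    heights = Z[:, 2]
    positive = heights[heights > 0]
    if positive.size == 0:
        return CladePartition(tuple(dm.labels), (1,) * n, 0.0, Z, {1: 0.0})
    if height_floor is None:
        height_floor = 0.25 * float(np.median(positive))
    floored = np.maximum(heights, height_floor)
    ratios = floored[1:] / floored[:-1]
    best = int(np.argmax(ratios))
    cut = float(np.sqrt(floored[best] * floored[best + 1]))
    clades = hierarchy.fcluster(Z, t=cut, criterion="distance")

    within_vals, between_vals = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within_vals if clades[i] == clades[j] else between_vals).append(dm.d[i, j])
    trivial = False
    if not between_vals:
        trivial = True
    else:
        within_mean = np.mean(within_vals) if within_vals else 0.0
        between_mean = np.mean(between_vals)
        if within_mean > 0 and between_mean / within_mean < min_ratio:
            trivial = True
    if trivial:
        return CladePartition(tuple(dm.labels), (1,) * n, float(heights[-1]), Z, {1: 0.0})
    return CladePartition(
        tuple(dm.labels),
        tuple(int(c) for c in clades),
        cut,
        Z,
        _silhouette(dm.d, np.asarray(clades)),
    )


# ---------------------------------------------------------------------------
# mutational steps and networks
# ---------------------------------------------------------------------------

def mutational_steps(h1: str, h2: str) -> int:
    """Mutational steps between two equal-length gapped haplotypes.

    Substitutions are counted per site; each maximal contiguous run of
    columns gapped in exactly one of the two sequences counts as a single
    step (an indel is one event regardless of its length).  Columns gapped
    in both sequences are ignored and do not interrupt a gap run.
    """
    if len(h1) != len(h2):
        raise ValueError("haplotypes must have equal gapped length")
    steps = 0
    prev_state = 0  # 0: aligned, 1: gap in h1, 2: gap in h2
    for a, b in zip(h1.upper(), h2.upper()):
        ga, gb = a == "-", b == "-"
        if ga and gb:
            continue  # transparent
        if ga or gb:
            state = 1 if ga else 2
            if state != prev_state:
                steps += 1
            prev_state = state
        else:
            if a != b:
                steps += 1
            prev_state = 0
    return steps


@dataclass(frozen=True)
class HaplotypeNetwork:
    """Minimum-spanning network over distinct haplotypes.

    Nodes carry clone multiplicity and taxon counts; edges carry the
    mutational-step count between their endpoints.  All co-minimal edges
    (members of at least one minimum spanning tree) are kept.
    """

    graph: nx.Graph

    @property
    def n_haplotypes(self) -> int:
        return self.graph.number_of_nodes()

    def edge_list(self) -> list[tuple[str, str, int]]:
        return sorted((u, v, d["steps"]) for u, v, d in self.graph.edges(data=True))

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, data in g.nodes(data=True):
            if isinstance(data.get("taxa"), dict):
                data["taxa"] = ";".join(f"{k}:{v}" for k, v in sorted(data["taxa"].items()))
            if isinstance(data.get("members"), (list, tuple)):
                data["members"] = ";".join(data["members"])
        nx.write_graphml(g, str(path))


def build_network(
    haplotypes: Mapping[str, str],
    multiplicity: Mapping[str, int] | None = None,
    taxa: Mapping[str, Mapping[str, int]] | None = None,
) -> HaplotypeNetwork:
    """Minimum spanning network of haplotypes keyed by name.

    Edge weights are mutational steps.  The network is the union of all
    minimum spanning trees (Kruskal with ties kept): an edge of weight w
    joins the network iff its endpoints lie in different components of the
    graph restricted to edges of weight < w.
    """
    names = list(haplotypes)
    g = nx.Graph()
    for name in names:
        g.add_node(
            name,
            multiplicity=int(multiplicity.get(name, 1)) if multiplicity else 1,
            taxa=dict(taxa.get(name, {})) if taxa else {},
        )
    if len(names) <= 1:
        return HaplotypeNetwork(g)
    edges = sorted(
        (mutational_steps(haplotypes[a], haplotypes[b]), a, b)
        for a, b in itertools.combinations(names, 2)
    )
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, group in itertools.groupby(edges, key=lambda e: e[0]):
        batch = list(group)
        keep = [(w, a, b) for w, a, b in batch if find(a) != find(b)]
        for w, a, b in keep:
            g.add_edge(a, b, steps=w)
        for _, a, b in keep:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return HaplotypeNetwork(g)


# ---------------------------------------------------------------------------
# numt calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumtCall:
    """Verdict and evidence for one clade."""

    clade: int
    verdict: str  # "numt" | "mtDNA"
    n_members: int
    repeat_absent_fraction: float
    contains_anchor: bool
    mean_internal_steps: float | None = None


@dataclass(frozen=True)
class NumtReport:
    calls: tuple[NumtCall, ...]
    warnings: tuple[str, ...] = ()

    def verdict_of(self, clade: int) -> str:
        for call in self.calls:
            if call.clade == clade:
                return call.verdict
        raise KeyError(clade)

    @property
    def mtdna_clades(self) -> tuple[int, ...]:
        return tuple(c.clade for c in self.calls if c.verdict == "mtDNA")

    @property
    def numt_clades(self) -> tuple[int, ...]:
        return tuple(c.clade for c in self.calls if c.verdict == "numt")


def _mean_internal_steps(members: Sequence[str], aligned_core: Mapping[str, str]) -> float | None:
    seqs = [aligned_core[m] for m in members if m in aligned_core]
    if len(seqs) < 2:
        return 0.0 if seqs else None
    total = 0
    count = 0
    for a, b in itertools.combinations(seqs, 2):
        total += mutational_steps(a, b)
        count += 1
    return total / count


def call_numts(
    partition: CladePartition,
    decompositions: Mapping[str, RepeatDecomposition],
    anchors: Iterable[str] = (),
    *,
    aligned_core: Mapping[str, str] | None = None,
    absent_threshold: float = 0.9,
) -> NumtReport:
    """Call each clade numt or authentic mtDNA.

    A clade is a numt when at least ``absent_threshold`` of its members
    lack an R2 array (N = 0) and it contains no anchor (independently
    verified mtDNA) sequence.  With no anchors supplied, the clade with
    the highest repeat-bearing fraction is presumed authentic regardless.
    Mean within-clade mutational steps (over ``aligned_core`` sequences,
    when given) is reported as corroborating evidence — numts are expected
    to show fewer steps.  An anchor split across clades is recorded as a
    warning, not an error.
    """
    anchors = set(anchors)
    groups = partition.groups()
    missing = [m for members in groups.values() for m in members if m not in decompositions]
    if missing:
        raise ValueError(f"decompositions missing for {len(missing)} sequences, e.g. {missing[0]!r}")
    warnings = []
    anchor_clades = {c for c, members in groups.items() if anchors & set(members)}
    if len(anchor_clades) > 1:
        warnings.append(
            f"anchor sequences split across {len(anchor_clades)} clades: "
            + ", ".join(str(c) for c in sorted(anchor_clades))
        )

    stats = {}
    for cid, members in groups.items():
        absent = sum(1 for m in members if decompositions[m].n_units == 0)
        stats[cid] = {
            "n": len(members),
            "absent_frac": absent / len(members),
            "anchor": bool(anchors & set(members)),
            "steps": _mean_internal_steps(members, aligned_core) if aligned_core else None,
        }

    presumed_mtdna = None
    if not anchors:
        presumed_mtdna = max(
            stats, key=lambda c: (1.0 - stats[c]["absent_frac"], stats[c]["n"], -c)
        )

    calls = []
    for cid in sorted(groups):
        s = stats[cid]
        is_numt = s["absent_frac"] >= absent_threshold and not s["anchor"]
        if cid == presumed_mtdna:
            is_numt = False
        calls.append(
            NumtCall(
                clade=cid,
                verdict="numt" if is_numt else "mtDNA",
                n_members=s["n"],
                repeat_absent_fraction=s["absent_frac"],
                contains_anchor=s["anchor"],
                mean_internal_steps=s["steps"],
            )
        )
    return NumtReport(tuple(calls), tuple(warnings))


# ---------------------------------------------------------------------------
# heteroplasmy calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeteroplasmyCall:
    individual: str
    sequence_het: bool
    length_het: bool
    n_core_haplotypes: int
    n_size_classes: int
    haplotype_support: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_core_haplotypes <= 1 and self.sequence_het:
            raise ValueError("sequence_het requires more than one core haplotype")
        if self.n_size_classes <= 1 and self.length_het:
            raise ValueError("length_het requires more than one size class")


def _core_haplotypes_site_support(
    seqs: Mapping[str, str], min_support: int
) -> dict[str, frozenset[tuple[int, str]]]:
    """Haplotype signature per clone over recurrent variant sites.

    A variant (column, base) pair must be carried by >= min_support clones
    to count; unsupported variants are treated as polymerase error and
    ignored.  Signatures over the supported variants define haplotypes.
    """
    names = list(seqs)
    arr = [seqs[n].upper() for n in names]
    L = len(arr[0])
    variant_counts: Counter[tuple[int, str]] = Counter()
    per_clone: dict[str, set[tuple[int, str]]] = {n: set() for n in names}
    for col in range(L):
        column = [s[col] for s in arr]
        bases = [b for b in column if b != "-"]
        if not bases:
            continue
        consensus = Counter(bases).most_common(1)[0][0]
        for n, b in zip(names, column):
            if b != "-" and b != consensus:
                variant_counts[(col, b)] += 1
                per_clone[n].add((col, b))
    supported = {v for v, c in variant_counts.items() if c >= min_support}
    return {n: frozenset(per_clone[n] & supported) for n in names}


def _core_haplotypes_distance(
    seqs: Mapping[str, str], threshold: int
) -> dict[str, str]:
    """Exact haplotypes with singleton collapse within a step threshold.

    Singleton haplotypes within ``threshold`` mutational steps of the
    nearest haplotype supported by >=2 clones are merged into it as
    putative polymerase error.  Haplotypes with >=2 clones are never
    removed.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for name, s in seqs.items():
        groups[s.upper()].append(name)
    assignment = {}
    multi = [h for h, members in groups.items() if len(members) >= 2]
    for hap, members in groups.items():
        target = hap
        if len(members) == 1 and multi:
            dists = [(mutational_steps(hap, m), m) for m in multi]
            best_d, best_h = min(dists)
            if best_d <= threshold:
                target = best_h
        for name in members:
            assignment[name] = target
    return assignment


def call_heteroplasmy(
    individual: str,
    core_seqs: Mapping[str, str],
    decompositions: Mapping[str, RepeatDecomposition],
    error_model: ErrorModel,
    *,
    method: str = "site_support",
    min_support: int = 2,
) -> HeteroplasmyCall:
    """Call sequence and length heteroplasmy for one individual's clones.

    ``core_seqs`` are the clones' aligned core sequences (R2 array
    excluded).  Sequence heteroplasmy: more than one core haplotype after
    discounting polymerase error.  The default ``site_support`` method
    keeps only variants recurring in at least ``min_support`` clones (a
    polymerase error is private to one clone; a genuine minor haplotype's
    sites recur).  The ``distance`` method instead collapses singleton
    haplotypes lying within ``ceil(lam + 2*sqrt(lam))`` steps of a
    multi-clone haplotype, with lam from ``error_model``.  Length
    heteroplasmy: more than one distinct R2 array length among the
    clones' decompositions.
    """
    if not core_seqs:
        raise ValueError("need at least one clone")
    if method == "site_support":
        signatures = _core_haplotypes_site_support(core_seqs, min_support)
        hap_of = signatures
    elif method == "distance":
        hap_of = _core_haplotypes_distance(core_seqs, error_model.collapse_threshold())
    else:
        raise ValueError(f"unknown method {method!r}")
    support = Counter(hap_of.values())
    lengths = {
        decompositions[n].array_length
        for n in core_seqs
        if n in decompositions and not decompositions[n].is_empty
    }
    n_haps = len(support)
    n_classes = len(lengths)
    return HeteroplasmyCall(
        individual=individual,
        sequence_het=n_haps >= 2,
        length_het=n_classes >= 2,
        n_core_haplotypes=n_haps,
        n_size_classes=n_classes,
        haplotype_support=tuple(sorted(support.values(), reverse=True)),
    )
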