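import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from numtscan.classify import (
    HeteroplasmyCall,
    build_network,
    call_heteroplasmy,
    call_numts,
    mutational_steps,
    partition_clades,
)
from numtscan.distances import AlignedSet, k2p_matrix
from numtscan.errors import ErrorModel
from numtscan.repeats import decompose

from oracles import oracle_gap_steps, oracle_msn_edges


def _aligned_from(seqs):
    return AlignedSet([f"s{i}" for i in range(len(seqs))], list(seqs))


class TestPartition:
    def test_all_identical_sequences_form_one_clade(self):
        dm = k2p_matrix(_aligned_from(["ACGTACGTAC"] * 4))
        part = partition_clades(dm)
        assert part.n_clades == 1

    def test_two_well_separated_groups(self, rng):
        base = "".join(rng.choice(list("ACGT"), 300))
        far = list(base)
        for p in range(0, 60):
            far[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[far[p]]
        dm = k2p_matrix(_aligned_from([base, base, base, "".join(far), "".join(far)]))
        part = partition_clades(dm)
        assert part.n_clades == 2
        groups = sorted(len(v) for v in part.groups().values())
        assert groups == [2, 3]

    def test_order_invariance_up_to_relabelling(self, default_dataset):
        dm = k2p_matrix(default_dataset.aligned)
        part = partition_clades(dm)
        order = np.random.default_rng(7).permutation(len(dm.labels))
        labels2 = [dm.labels[i] for i in order]
        from numtscan.distances import DistanceMatrix

        dm2 = DistanceMatrix(
            tuple(labels2), dm.d[np.ix_(order, order)], dm.P[np.ix_(order, order)],
            dm.Q[np.ix_(order, order)]
        )
        part2 = partition_clades(dm2)
        mapping1 = {lab: part.clade_of(lab) for lab in dm.labels}
        mapping2 = {lab: part2.clade_of(lab) for lab in dm.labels}
        # same partition as a set of member sets
        sets1 = {frozenset(l for l, c in mapping1.items() if c == cid) for cid in set(mapping1.values())}
        sets2 = {frozenset(l for l, c in mapping2.items() if c == cid) for cid in set(mapping2.values())}
        assert sets1 == sets2

    def test_weak_structure_collapses_to_single_clade(self, rng):
        # distances with no clear gap: uniform noise
        n = 10
        d = rng.uniform(0.01, 0.012, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        from numtscan.distances import DistanceMatrix

        dm = DistanceMatrix(tuple(f"s{i}" for i in range(n)), d, d * 0, d * 0)
        assert partition_clades(dm).n_clades == 1


class TestMutationalSteps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0),
            ("ACGT", "ATGT", 1),
            ("AC--GT", "ACTTGT", 1),
            ("A--T", "AGGT", 1),
            ("A--TT--A", "AGGTTCCA", 2),
            ("-ACGT", "TACGT", 1),
            ("A-C-T", "AGCGT", 2),
        ],
    )
    def test_enumerated_toy_pairs(self, a, b, expected):
        assert mutational_steps(a, b) == expected
        assert oracle_gap_steps(a, b) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal"):
            mutational_steps("AC", "ACG")

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.text(alphabet="AC-", min_size=0, max_size=6), st.text(alphabet="AC-", min_size=0, max_size=6))
    def test_symmetry_and_identity(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert mutational_steps(a, b) == mutational_steps(b, a)
        assert mutational_steps(a, a) == 0

    def test_equals_hamming_metric_on_gapless_strings(self):
        dom = ["".join(p) for p in itertools.product("ACG", repeat=3)]
        for x, y in itertools.combinations(dom, 2):
            assert mutational_steps(x, y) == sum(a != b for a, b in zip(x, y))
        # hence the triangle inequality holds on the gapless domain
        for x, y, z in itertools.islice(itertools.product(dom, dom, dom), 2000):
            assert mutational_steps(x, z) <= mutational_steps(x, y) + mutational_steps(y, z)


class TestNetwork:
    def test_single_haplotype(self):
        net = build_network({"h1": "ACGT"})
        assert net.n_haplotypes == 1
        assert net.edge_list() == []

    def test_three_haplotypes_keep_two_cheapest_edges(self):
        # steps: h1-h2 = 1, h2-h3 = 2, h1-h3 = 3 -> MST keeps {1, 2}
        haps = {"h1": "AAAA", "h2": "AAAC", "h3": "ACCC"}
        net = build_network(haps)
        weights = sorted(w for _, _, w in net.edge_list())
        assert weights == [1, 2]

    def test_co_minimal_ties_are_kept(self):
        # equilateral triple: every spanning tree is minimal, all edges kept
        haps = {"h1": "AAA", "h2": "AAC", "h3": "AAG"}
        net = build_network(haps)
        assert len(net.edge_list()) == 3

    def test_matches_spanning_tree_enumeration_on_random_cases(self, rng):
        for _ in range(15):
            n = int(rng.integers(3, 7))
            length = 8
            haps = {
                f"h{i}": "".join(rng.choice(list("ACGT"), length)) for i in range(n)
            }
            weight = {
                (a, b): mutational_steps(haps[a], haps[b])
                for a, b in itertools.combinations(haps, 2)
            }
            expected = oracle_msn_edges(list(haps), weight)
            got = {(min(a, b), max(a, b)) for a, b, _ in build_network(haps).edge_list()}
            assert got == expected

    def test_node_attributes_carry_multiplicity_and_taxa(self):
        net = build_network(
            {"h1": "AAAA", "h2": "AAAC"},
            multiplicity={"h1": 5, "h2": 2},
            taxa={"h1": {"East": 5}, "h2": {"Hainan": 2}},
        )
        assert net.graph.nodes["h1"]["multiplicity"] == 5
        assert net.graph.nodes["h2"]["taxa"] == {"Hainan": 2}


class TestCallNumts:
    def _partition(self, groups):
        from numtscan.classify import CladePartition

        labels, clades = [], []
        for cid, members in groups.items():
            labels += members
            clades += [cid] * len(members)
        return CladePartition(tuple(labels), tuple(clades), 0.1, np.empty((0, 4)))

    def test_repeat_bearing_anchor_clade_is_mtdna(self):
        arr = "AACGTATACGC" * 5
        part = self._partition({1: ["a", "b"], 2: ["c", "d"]})
        decs = {x: decompose(arr) for x in "ab"} | {x: decompose("ACGT" * 20) for x in "cd"}
        rep = call_numts(part, decs, anchors=["a"])
        assert rep.verdict_of(1) == "mtDNA"
        assert rep.verdict_of(2) == "numt"
        assert rep.calls[0].contains_anchor

    def test_single_repeat_bearing_clade_is_mtdna_without_anchors(self):
        arr = "AACGTATACGC" * 5
        part = self._partition({1: ["a", "b", "c"]})
        rep = call_numts(part, {x: decompose(arr) for x in "abc"})
        assert rep.verdict_of(1) == "mtDNA"
        assert rep.numt_clades == ()

    def test_anchor_clade_never_called_numt_even_without_repeats(self):
        part = self._partition({1: ["a", "b"], 2: ["c", "d"]})
        decs = {x: decompose("ACGT" * 20) for x in "abcd"}
        rep = call_numts(part, decs, anchors=["a"])
        assert rep.verdict_of(1) == "mtDNA"

    def test_anchor_split_across_clades_warns(self):
        arr = "AACGTATACGC" * 5
        part = self._partition({1: ["a", "b"], 2: ["c", "d"]})
        decs = {x: decompose(arr) for x in "abcd"}
        rep = call_numts(part, decs, anchors=["a", "c"])
        assert any("split" in w for w in rep.warnings)

    def test_missing_decomposition_raises(self):
        part = self._partition({1: ["a"]})
        with pytest.raises(ValueError, match="decompositions missing"):
            call_numts(part, {})


class TestCallHeteroplasmy:
    ARR = "AACGTATACGC"

    def _em(self):
        return ErrorModel(7.2e-5, 500, 34)

    def test_two_length_classes_one_haplotype(self):
        core = "ACGTACGTAC"
        seqs = {f"c{i}": core for i in range(6)}
        decs = {f"c{i}": decompose(self.ARR * (19 if i < 3 else 16)) for i in range(6)}
        call = call_heteroplasmy("TL07", seqs, decs, self._em())
        assert call.length_het and not call.sequence_het
        assert call.n_size_classes == 2
        assert call.n_core_haplotypes == 1

    def test_single_clone_has_no_heteroplasmy(self):
        call = call_heteroplasmy(
            "solo", {"c1": "ACGTAC"}, {"c1": decompose(self.ARR * 5)}, self._em()
        )
        assert not call.sequence_het and not call.length_het

    def test_recurrent_minor_variant_called(self):
        major, minor = "AAAAAAAAAA", "AACAAAAAGA"
        seqs = {"c1": major, "c2": major, "c3": minor, "c4": minor}
        decs = {c: decompose(self.ARR * 5) for c in seqs}
        call = call_heteroplasmy("ind", seqs, decs, self._em())
        assert call.sequence_het
        assert call.n_core_haplotypes == 2
        assert call.haplotype_support == (2, 2)

    def test_private_singleton_variants_discounted_as_error(self):
        major = "AAAAAAAAAA"
        seqs = {"c1": major, "c2": major, "c3": "AACAAAAAAA", "c4": "AAAAAGAAAA"}
        decs = {c: decompose(self.ARR * 5) for c in seqs}
        call = call_heteroplasmy("ind", seqs, decs, self._em())
        assert not call.sequence_het

    def test_distance_method_collapses_near_singletons_only(self):
        major = "A" * 100
        near = "C" + "A" * 99  # 1 step from the multi-clone haplotype
        far = "C" * 30 + "A" * 70  # far beyond the error threshold
        seqs = {"c1": major, "c2": major, "c3": near, "c4": far}
        decs = {c: decompose(self.ARR * 5) for c in seqs}
        call = call_heteroplasmy("ind", seqs, decs, self._em(), method="distance")
        assert call.n_core_haplotypes == 2  # near collapsed, far retained
        assert call.sequence_het

    def test_distance_method_never_removes_multi_clone_haplotypes(self):
        major = "A" * 100
        minor = "CC" + "A" * 98  # 2 steps away but supported by two clones
        seqs = {"c1": major, "c2": major, "c3": minor, "c4": minor}
        decs = {c: decompose(self.ARR * 5) for c in seqs}
        call = call_heteroplasmy("ind", seqs, decs, self._em(), method="distance")
        assert call.n_core_haplotypes == 2

    def test_flags_require_counts_above_one(self):
        with pytest.raises(ValueError):
            HeteroplasmyCall("x", True, False, 1, 1)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            call_heteroplasmy("x", {}, {}, self._em())
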