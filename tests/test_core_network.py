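"""Network validation, tier arithmetic, blobs, simplicity, canonical form."""

import networkx as nx
import pytest

from phylospace import (
    DegreeError,
    DisconnectedError,
    LabelError,
    LoopError,
    ParallelEdgeError,
    PhyloNetwork,
    blob_decomposition,
    is_isomorphic,
    is_pseudo_hamiltonian,
    is_simple,
    shrink_blobs,
)
from phylospace.core_network import longest_cycle, validate
from phylospace.echidna import EchidnaSpec, build_echidna
from phylospace.fileio import FixtureSpec, random_network

from conftest import brute_force_isomorphic

L3 = {"1": 0, "2": 1, "3": 2}


class TestValidation:
    def test_smallest_tree_is_valid_tier0(self):
        N = validate([(0, 3), (1, 3), (2, 3)], L3)
        assert N.tier() == 0 and N.num_leaves == 3 and N.n == 4

    @pytest.mark.parametrize(
        "edges, labels, err",
        [
            # one leaf unlabelled
            ([(0, 3), (1, 3), (2, 3)], {"1": 0, "2": 1}, LabelError),
            # label points at an internal vertex
            ([(0, 3), (1, 3), (2, 3)], {"1": 0, "2": 1, "3": 3}, LabelError),
            # loop
            ([(0, 3), (1, 3), (2, 3), (3, 3)], L3, LoopError),
            # doubled edge inside a triangle
            ([(10, 11), (10, 11), (11, 12), (12, 10),
              (0, 10), (1, 11), (2, 12)], L3, ParallelEdgeError),
            # degree-2 vertex
            ([(0, 3), (1, 3), (3, 4), (4, 1)], {"1": 0, "2": 1}, DegreeError),
            # two components (degrees all legal)
            ([(0, 3), (1, 3), (2, 3), (4, 5)], L3, DisconnectedError),
        ],
    )
    def test_each_violation_raises_its_own_error(self, edges, labels, err):
        with pytest.raises(err):
            validate(edges, labels)

    def test_disconnected_cubic_component_detected(self, tree3, tier1_3):
        edges = list(tree3.graph.edges()) + [(u + 100, v + 100)
                                             for u, v in tier1_3.graph.edges()]
        with pytest.raises(DisconnectedError):
            validate(edges, L3)


class TestTier:
    def test_fourteen_vertices_five_leaves_is_tier_three(self):
        # an echidna with p=5, q=2 has n = 2(5 + 3 - 1) = 14 vertices
        N, _ = build_echidna(EchidnaSpec((1, 0, 2, 3, 0, 4, 5)))
        assert N.n == 14 and N.num_leaves == 5
        assert N.tier() == 3
        assert N.reticulation_number() == 3

    def test_tree_is_tier_zero(self, tree3):
        assert tree3.tier() == 0 == tree3.reticulation_number()

    def test_triangle_network_has_one_independent_cycle(self, tier1_3):
        assert tier1_3.tier() == 1 == tier1_3.reticulation_number()

    def test_fig_style_echidna_tier_matches_cyclomatic_number(self, big_echidna):
        N, _ = big_echidna
        assert N.tier() == 5 == N.num_edges - N.n + 1

    def test_edge_count_identity(self, spaces):
        for ell, i in [(3, 0), (4, 0), (3, 1), (4, 1), (3, 2)]:
            for N in spaces(ell, i).networks.values():
                assert N.num_edges == 2 * ell - 3 + 3 * i
                assert N.tier() == i == N.reticulation_number()


class TestBlobs:
    def test_tree_has_no_blobs_and_all_edges_cut(self, tree4):
        dec = blob_decomposition(tree4)
        assert dec.blobs == []
        assert len(dec.cut_edges) == tree4.num_edges
        assert len(dec.nontrivial_cut_edges) == 1  # the single internal edge

    def test_echidna_is_one_blob_with_trivial_cuts(self, big_echidna):
        N, _ = big_echidna
        dec = blob_decomposition(N)
        assert len(dec.blobs) == 1
        assert len(dec.cut_edges) == N.num_leaves
        assert not dec.nontrivial_cut_edges

    def test_two_blob_fixture(self, two_blob):
        dec = blob_decomposition(two_blob)
        assert len(dec.blobs) == 2
        assert len(dec.nontrivial_cut_edges) == 1

    def test_cut_edges_match_removal_oracle(self, two_blob, big_echidna):
        # definitional oracle: an edge is a cut-edge iff removing it disconnects
        for N in (two_blob, big_echidna[0]):
            dec = blob_decomposition(N)
            for u, v in N.graph.edges():
                h = N.graph.copy()
                h.remove_edge(u, v)
                assert (frozenset((u, v)) in dec.cut_edges) == (not nx.is_connected(h))

    def test_nontrivial_cut_edge_bound(self, spaces):
        for ell, i in [(3, 1), (4, 1), (3, 2)]:
            for N in spaces(ell, i).networks.values():
                assert len(blob_decomposition(N).nontrivial_cut_edges) <= ell + i - 3


class TestSimplicityAndPseudoHamiltonicity:
    def test_trees_with_internal_edges_are_not_simple(self, tree3, tree4):
        # any tree with >= 4 leaves has an internal (non-trivial) cut-edge;
        # the 3-leaf star is the degenerate exception: every edge is pendant,
        # so it is simple by the all-cut-edges-trivial definition
        assert not is_simple(tree4)
        assert is_simple(tree3)

    def test_echidna_is_simple_and_pseudo_hamiltonian(self, big_echidna):
        N, witness = big_echidna
        assert is_simple(N)
        ok, cycle = is_pseudo_hamiltonian(N, return_witness=True)
        assert ok and set(cycle) == set(witness)

    def test_triangle_network_witness_is_the_triangle(self, tier1_3):
        ok, cycle = is_pseudo_hamiltonian(tier1_3, return_witness=True)
        assert ok and sorted(cycle) == [10, 11, 12]

    def test_two_blob_fixture_is_neither(self, two_blob):
        assert not is_simple(two_blob)
        assert not is_pseudo_hamiltonian(two_blob)

    def test_pseudo_hamiltonian_implies_simple(self, spaces):
        for ell, i in [(3, 1), (4, 1), (3, 2)]:
            for N in spaces(ell, i).networks.values():
                if is_pseudo_hamiltonian(N):
                    assert is_simple(N)

    def test_longest_cycle_is_exhaustive_on_k4(self):
        assert len(longest_cycle(nx.complete_graph(4))) == 4


class TestCanonicalForm:
    def test_vertex_renaming_preserves_key(self, two_blob):
        shift = {v: v + 1000 for v in two_blob.graph.nodes}
        M = PhyloNetwork([(shift[u], shift[v]) for u, v in two_blob.graph.edges()],
                         {x: shift[v] for x, v in two_blob.leaf_labels.items()})
        assert is_isomorphic(two_blob, M)

    def test_distinct_echidna_sequences_not_isomorphic(self):
        G1, _ = build_echidna(EchidnaSpec((1, 2, 0, 3)))
        G2, _ = build_echidna(EchidnaSpec((1, 0, 2, 3)))
        assert not is_isomorphic(G1, G2)

    def test_different_tier_same_taxa_not_isomorphic(self, tree3, tier1_3):
        assert not is_isomorphic(tree3, tier1_3)

    def test_differing_leaf_sets_raise(self, tree3, tree4):
        with pytest.raises(LabelError):
            is_isomorphic(tree3, tree4)

    def test_agrees_with_brute_force_oracle(self, spaces):
        nets = list(spaces(4, 1).networks.values())
        for A in nets:
            for B in nets:
                assert is_isomorphic(A, B) == brute_force_isomorphic(A, B)

    def test_agrees_with_oracle_on_random_walks(self):
        nets = [random_network(FixtureSpec(4, 2, "random-walk", 5, seed))
                for seed in range(6)]
        for A in nets:
            for B in nets:
                assert is_isomorphic(A, B) == brute_force_isomorphic(A, B)


class TestShrinkBlobs:
    def test_tree_shrinks_to_itself(self, tree4):
        t = shrink_blobs(tree4)
        assert sorted(map(sorted, t.edges())) == sorted(map(sorted, tree4.graph.edges()))

    def test_echidna_shrinks_to_star(self, big_echidna):
        N, _ = big_echidna
        t = shrink_blobs(N)
        assert t.number_of_nodes() == 1 + N.num_leaves
        degs = sorted(d for _, d in t.degree())
        assert degs == [1] * N.num_leaves + [N.num_leaves]

    def test_two_blob_fixture_shrinks_to_two_hub_path(self, two_blob):
        t = shrink_blobs(two_blob)
        assert t.number_of_nodes() == 6  # 2 hubs + 4 leaves
        assert nx.is_tree(t)
        hubs = [v for v, d in t.degree() if d == 3]
        assert len(hubs) == 2 and t.has_edge(*hubs)

    def test_shrunk_tree_size_bound(self, spaces):
        for ell, i in [(3, 1), (4, 1), (3, 2)]:
            for N in spaces(ell, i).networks.values():
                t = shrink_blobs(N)
                assert nx.is_tree(t)
                assert t.number_of_nodes() <= 2 * ell + i - 2
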