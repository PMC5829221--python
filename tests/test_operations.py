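"""Rearrangement operations: legality, inverses, neighborhoods, containment."""

import pytest

from phylospace import (
    IllegalMoveError,
    Move,
    PhyloNetwork,
    apply_move,
    is_isomorphic,
    nni_apply,
    nni_neighbors,
    spr_apply,
    spr_neighbors,
    tbr_neighbors,
    triangle_blowup,
    triangle_collapse,
)
from phylospace.bounds import spr_one_step_bound
from phylospace.operations import (
    nni_inverse,
    nni_moves,
    spr_moves,
    spr_raw_move_count,
    tbr_moves,
    triangles,
)
from phylospace.fileio import FixtureSpec, random_network


def walk_fixtures():
    return [random_network(FixtureSpec(ell, i, "random-walk", 6, seed))
            for ell, i in [(4, 1), (4, 2), (5, 2)] for seed in (0, 1)]


class TestNNI:
    def test_involution(self):
        for N in walk_fixtures():
            for anchor, M in nni_moves(N):
                back = nni_apply(M, nni_inverse(Move("NNI", anchor)).anchor)
                assert back.canonical_key() == N.canonical_key()
                break  # one anchor per fixture is enough

    def test_precondition_violations_are_rejected(self, tier1_3):
        # {v1, v3} is a triangle edge here
        with pytest.raises(IllegalMoveError):
            nni_apply(tier1_3, (10, 11, 12, 2))

    def test_singleton_tier_has_no_neighbors(self, tier1_3):
        assert nni_neighbors(tier1_3) == []

    def test_quartet_trees_have_two_tree_neighbors(self, spaces):
        for N in spaces(4, 0).networks.values():
            assert len(nni_neighbors(N)) == 2

    def test_move_enumeration_matches_path_quadruple_oracle(self, two_blob):
        # definitional oracle: try every ordered vertex quadruple
        got = {M.canonical_key() for _, M in nni_moves(two_blob)}
        oracle = set()
        g = two_blob.graph
        for v1 in g:
            for v2 in g.neighbors(v1):
                for v3 in g.neighbors(v2):
                    for v4 in g.neighbors(v3):
                        if len({v1, v2, v3, v4}) < 4:
                            continue
                        if g.has_edge(v1, v3) or g.has_edge(v2, v4):
                            continue
                        oracle.add(nni_apply(two_blob, (v1, v2, v3, v4)).canonical_key())
        assert got == oracle

    def test_preserves_tier_and_validity(self):
        for N in walk_fixtures():
            for _, M in nni_moves(N):
                assert M.tier() == N.tier() and M.taxa == N.taxa

    def test_neighborhood_symmetry(self, spaces):
        sp = spaces(4, 1)
        for N in sp.networks.values():
            for M in nni_neighbors(N):
                back = {B.canonical_key() for B in nni_neighbors(M)}
                assert N.canonical_key() in back


class TestTriangle:
    def test_blowup_of_3leaf_hub_gives_the_triangle_network(self, tree3, tier1_3):
        blown = triangle_blowup(tree3, 3)
        assert is_isomorphic(blown, tier1_3)

    def test_blowup_increases_tier_collapse_restores(self, tree4):
        blown = triangle_blowup(tree4, 5)
        assert blown.tier() == tree4.tier() + 1
        (tri,) = triangles(blown)
        back = triangle_collapse(blown, tri)
        assert back.tier() == tree4.tier()
        assert is_isomorphic(back, tree4)

    def test_blowup_of_leaf_rejected(self, tree4):
        with pytest.raises(IllegalMoveError):
            triangle_blowup(tree4, 1)

    def test_collapse_creating_parallel_edge_rejected(self, spaces):
        # in tier (3,2) some network has two triangles sharing an edge; the
        # shared-edge collapse would double an edge and must be refused
        hits = 0
        for N in spaces(3, 2).networks.values():
            for tri in triangles(N):
                try:
                    M = triangle_collapse(N, tri)
                except IllegalMoveError:
                    hits += 1
                else:
                    assert M.tier() == N.tier() - 1
        assert hits > 0


class TestSPR:
    def test_some_spr_on_the_path_edge_realizes_an_nni(self, spaces):
        # every NNI result must appear among the SPR results (containment),
        # and for anchors where the direct mimicry is legal, the SPR on the
        # path edge with the opposite path edge as target reproduces it
        for N in spaces(4, 1).networks.values():
            spr_keys = {M.canonical_key() for _, M in spr_moves(N)}
            for (v1, v2, v3, v4), M in nni_moves(N):
                assert M.canonical_key() in spr_keys

    def test_inverse_round_trip(self):
        N = random_network(FixtureSpec(4, 2, "random-walk", 6, 3))
        (e, target), M = next(iter(spr_moves(N)))
        v, w = e
        # undo: detach the fresh subdivision vertex from w, regraft onto the
        # edge created by suppressing v
        u = next(z for z in M.graph.neighbors(w) if z not in N.graph)
        v1, v2 = [z for z in N.graph.neighbors(v) if z != w]
        back = spr_apply(M, (u, w), (v1, v2))
        assert back.canonical_key() == N.canonical_key()

    def test_quartet_spr_superset_of_nni(self, spaces):
        for N in spaces(4, 0).networks.values():
            nk = {M.canonical_key() for M in nni_neighbors(N)}
            sk = {M.canonical_key() for M in spr_neighbors(N)}
            assert nk <= sk

    def test_raw_move_count_bound(self):
        for N in walk_fixtures():
            n, i = N.n, N.tier()
            assert spr_raw_move_count(N) <= spr_one_step_bound(n, i)

    def test_cut_edge_target_restriction(self):
        # caterpillar on 5 leaves: detaching one end of the internal cut-edge
        # {6,7} forbids regrafting inside the component that keeps vertex 7
        labels = {str(k): k for k in range(1, 6)}
        N = PhyloNetwork([(1, 6), (2, 6), (6, 7), (3, 7), (7, 8), (4, 8), (5, 8)],
                         labels)
        with pytest.raises(IllegalMoveError, match="cut-edge"):
            spr_apply(N, (6, 7), (8, 4))
        # detaching the other end makes that side the valid target region
        M = spr_apply(N, (7, 6), (8, 4))
        assert M.tier() == 0 and M.taxa == N.taxa


class TestTBR:
    def test_singleton_tier_has_no_tbr_neighbors(self, tier1_3):
        assert tbr_neighbors(tier1_3) == []

    def test_every_spr_is_a_tbr(self, spaces):
        for ell, i in [(4, 0), (4, 1), (3, 2)]:
            for N in spaces(ell, i).networks.values():
                sk = {M.canonical_key() for M in spr_neighbors(N)}
                tk = {M.canonical_key() for M in tbr_neighbors(N)}
                assert sk <= tk

    def test_containment_chain(self, spaces):
        for ell, i in [(3, 1), (4, 1), (3, 2), (4, 0), (5, 0)]:
            for N in spaces(ell, i).networks.values():
                nk = {M.canonical_key() for M in nni_neighbors(N)}
                sk = {M.canonical_key() for M in spr_neighbors(N)}
                tk = {M.canonical_key() for M in tbr_neighbors(N)}
                assert nk <= sk <= tk

    def test_every_tbr_within_two_sprs(self, spaces):
        sp = spaces(4, 1)
        g = sp.move_graph("spr")
        import networkx as nx
        for key, N in sp.networks.items():
            for M in tbr_neighbors(N):
                assert nx.shortest_path_length(g, key, M.canonical_key()) <= 2

    def test_identity_round_trip_via_inverse(self):
        N = random_network(FixtureSpec(4, 2, "random-walk", 6, 4))
        anchor, M = next(iter(tbr_moves(N)))
        # the inverse TBR deletes the fresh bridge and regrafts both stubs
        # onto the edges merged by suppression; an exhaustive search over
        # TBR moves of M must recover N
        assert any(B.canonical_key() == N.canonical_key()
                   for _, B in tbr_moves(M))

    def test_preserves_tier(self):
        N = random_network(FixtureSpec(4, 1, "random-walk", 4, 5))
        for _, M in tbr_moves(N):
            assert M.tier() == N.tier()


class TestMoveSerialization:
    def test_round_trip(self):
        moves = [
            Move("NNI", (1, 2, 3, 4)),
            Move("TRIANGLE_BLOWUP", (7,)),
            Move("TRIANGLE_COLLAPSE", (1, 2, 3)),
            Move("SPR", ((1, 2), (3, 4))),
            Move("TBR", ((1, 2), (3, 4, 0), (5, 6, 1))),
        ]
        for m in moves:
            again = Move.deserialize(m.serialize())
            assert again.kind == m.kind and again.anchor == m.anchor

    def test_apply_move_dispatch(self, tree3, tier1_3):
        blown = apply_move(tree3, Move("TRIANGLE_BLOWUP", (3,)))
        assert is_isomorphic(blown, tier1_3)
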