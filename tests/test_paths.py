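"""Constructive path certificates: budgets, replay, BFS soundness."""

import itertools
import math

import pytest

from phylospace import (
    PhyloNetwork,
    is_pseudo_hamiltonian,
    is_simple,
    make_pseudo_hamiltonian,
    make_simple,
    connect_any,
    connect_same_tier,
    sort_cycle,
)
from phylospace.bounds import cross_tier_upper, nni_diameter_upper
from phylospace.echidna import EchidnaSpec, build_echidna
from phylospace.explore import bfs_distance
from phylospace.fileio import FixtureSpec, random_network
from phylospace.operations import triangle_blowup


class TestMakeSimple:
    def test_already_simple_is_empty(self, tier1_3):
        cert = make_simple(tier1_3)
        assert len(cert) == 0

    def test_two_blob_fixture_needs_one_move(self, two_blob):
        cert = make_simple(two_blob)
        assert len(cert) == 1
        assert is_simple(cert.target)
        cert.replay()

    def test_trees_are_unsupported(self, tree4):
        with pytest.raises(ValueError):
            make_simple(tree4)

    @pytest.mark.parametrize("ell,i", [(4, 2), (5, 2), (5, 3)])
    def test_bound_on_random_fixtures(self, ell, i):
        for seed in range(25):
            N = random_network(FixtureSpec(ell, i, "random-walk", 10, seed))
            cert = make_simple(N)
            assert len(cert) <= ell + i - 3
            assert is_simple(cert.target)


class TestMakePseudoHamiltonian:
    def test_already_pseudo_hamiltonian_is_empty(self, tier1_3):
        assert len(make_pseudo_hamiltonian(tier1_3)) == 0

    def test_requires_simple_input(self, two_blob):
        with pytest.raises(ValueError):
            make_pseudo_hamiltonian(two_blob)

    @pytest.mark.parametrize("ell,i", [(4, 2), (5, 2), (5, 3)])
    def test_cycle_grows_each_move_within_budget(self, ell, i):
        for seed in range(15):
            N = random_network(FixtureSpec(ell, i, "random-walk", 10, seed))
            simple = make_simple(N).target
            cert = make_pseudo_hamiltonian(simple)
            assert len(cert) <= N.n
            assert is_pseudo_hamiltonian(cert.target)
            lens = cert.meta["cycle_lengths"]
            assert all(b > a for a, b in zip(lens, lens[1:]))
            cert.replay()


class TestSortCycle:
    def test_isomorphic_inputs_give_empty_certificate(self, tier1_3):
        shifted = PhyloNetwork(
            [(u + 50, v + 50) for u, v in tier1_3.graph.edges()],
            {x: v + 50 for x, v in tier1_3.leaf_labels.items()})
        assert len(sort_cycle(tier1_3, shifted)) == 0

    def test_adjacent_transposition_echidnas(self):
        A, wa = build_echidna(EchidnaSpec((1, 2, 0, 3, 4)))
        B, wb = build_echidna(EchidnaSpec((1, 3, 0, 2, 4)))
        cert = sort_cycle(A, B, witness=wa, witness_target=wb)
        n, ell = A.n, A.num_leaves
        assert len(cert) <= math.comb(n - ell, 2)
        cert.replay()

    def test_swap_count_bounded_by_symmetric_group_diameter(self):
        for s1, s2 in itertools.combinations(
                [(1, 0, 2, 3), (1, 2, 0, 3)], 2):
            A, wa = build_echidna(EchidnaSpec(s1))
            B, wb = build_echidna(EchidnaSpec(s2))
            cert = sort_cycle(A, B, witness=wa, witness_target=wb)
            assert len(cert) <= math.comb(A.n - A.num_leaves, 2)
            cert.replay()


class TestConnectSameTier:
    def test_identical_networks_give_empty_certificate(self, tier1_3):
        assert len(connect_same_tier(tier1_3, tier1_3)) == 0

    def test_all_pairs_tier1_four_leaves_sandwich(self, spaces):
        # certificate length must lie between the exact BFS distance and the
        # constructive diameter bound
        sp = spaces(4, 1)
        nets = list(sp.networks.values())
        bound = nni_diameter_upper(8, 1)
        for A, B in itertools.combinations(nets, 2):
            cert = connect_same_tier(A, B)
            cert.replay()
            d = sp.distance(A, B, "nni")
            assert d <= len(cert) <= bound

    def test_tree_space_falls_back_to_bfs(self, spaces):
        trees = list(spaces(4, 0).networks.values())
        cert = connect_same_tier(trees[0], trees[1])
        cert.replay()
        assert len(cert) == 1  # quartet trees are mutual NNI neighbors
        assert all(m.phase == "bfs-fallback" for m in cert.moves)

    @pytest.mark.parametrize("ell,i", [(4, 1), (4, 2), (5, 2)])
    def test_phase_budgets_on_random_pairs(self, ell, i):
        n = 2 * (ell + i - 1)
        total_bound = 3 * n + math.comb(n // 2 + i - 1, 2) - 2
        for seed in range(10):
            A = random_network(FixtureSpec(ell, i, "random-walk", 8, 2 * seed))
            B = random_network(FixtureSpec(ell, i, "random-walk", 8, 2 * seed + 1))
            cert = connect_same_tier(A, B)
            cert.replay()
            per = cert.meta["per_side"]
            assert per["simplify_source"] <= ell + i - 3
            assert per["simplify_target"] <= ell + i - 3
            assert per["hamiltonize_source"] <= n
            assert per["hamiltonize_target"] <= n
            assert per["sort"] <= math.comb(n - ell, 2)
            assert len(cert) <= total_bound


class TestConnectAny:
    def test_same_tier_reduces(self, tier1_3):
        assert len(connect_any(tier1_3, tier1_3)) == 0

    def test_tree_to_tier1_within_cross_tier_bound(self, spaces):
        trees = list(spaces(4, 0).networks.values())
        nets1 = list(spaces(4, 1).networks.values())
        bound = cross_tier_upper(4, 0, 1)
        for T in trees[:2]:
            for N in nets1[:4]:
                cert = connect_any(T, N)
                cert.replay()
                assert len(cert) <= bound

    def test_descending_tiers_by_reversal(self, tree4):
        blown = triangle_blowup(tree4, 5)
        cert = connect_any(blown, tree4)
        cert.replay()
        assert cert.source.tier() == 1 and cert.target.tier() == 0

    def test_two_blowups_at_most_two_apart_in_full_space(self, tree4):
        N1 = triangle_blowup(tree4, 5)
        N2 = triangle_blowup(tree4, 6)
        assert bfs_distance(N1, N2, op="full", tier_band=(0, 2)) == 2
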