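"""Shared fixtures: small reference networks and independent oracles."""

from __future__ import annotations

import itertools

import pytest

from phylospace import PhyloNetwork
from phylospace.echidna import build_echidna, parse_sequence
from phylospace.explore import TierSpace, enumerate_tier

LABELS4 = {"1": 1, "2": 2, "3": 3, "4": 4}


@pytest.fixture(scope="session")
def tree3() -> PhyloNetwork:
    """The unique 3-leaf tree: one hub joined to three labelled leaves."""
    return PhyloNetwork([(0, 3), (1, 3), (2, 3)], {"1": 0, "2": 1, "3": 2})


@pytest.fixture(scope="session")
def tier1_3() -> PhyloNetwork:
    """The unique tier-1 network on 3 leaves: a triangle with pendant leaves."""
    return PhyloNetwork([(10, 11), (11, 12), (12, 10), (0, 10), (1, 11), (2, 12)],
                        {"1": 0, "2": 1, "3": 2})


@pytest.fixture(scope="session")
def tree4() -> PhyloNetwork:
    """A quartet tree with cherries {1,2} and {3,4}."""
    return PhyloNetwork([(1, 5), (2, 5), (5, 6), (6, 3), (6, 4)], LABELS4)


@pytest.fixture(scope="session")
def two_blob() -> PhyloNetwork:
    """Two triangle blobs joined by one non-trivial cut-edge, leaves attached."""
    edges = [(10, 11), (11, 12), (12, 10), (20, 21), (21, 22), (22, 20),
             (12, 20), (1, 10), (2, 11), (3, 21), (4, 22)]
    return PhyloNetwork(edges, LABELS4)


@pytest.fixture(scope="session")
def big_echidna():
    """The 6-leaf, tier-5 echidna G(S, id) with S = (a1,a5,0,a2,0,0,a4,a3,0,a6)."""
    spec = parse_sequence("a1,a5,0,a2,0,0,a4,a3,0,a6")
    return build_echidna(spec)


@pytest.fixture(scope="session")
def spaces():
    """Memoized exhaustive tier-space enumerations."""
    cache: dict[tuple[int, int], TierSpace] = {}

    def get(ell: int, i: int) -> TierSpace:
        if (ell, i) not in cache:
            cache[(ell, i)] = enumerate_tier(ell, i)
        return cache[(ell, i)]

    return get


def brute_force_isomorphic(N: PhyloNetwork, M: PhyloNetwork) -> bool:
    """Isomorphism oracle: try every label-fixing vertex bijection.

    Independent of the package's canonical form (and of networkx VF2); only
    usable for small internal vertex counts.
    """
    if N.taxa != M.taxa or N.n != M.n or N.num_edges != M.num_edges:
        return False
    base = {N.leaf_labels[x]: M.leaf_labels[x] for x in N.leaf_labels}
    int_n = sorted(N.internal_vertices(), key=str)
    int_m = sorted(M.internal_vertices(), key=str)
    edges_m = {frozenset(e) for e in M.graph.edges()}
    for perm in itertools.permutations(int_m):
        phi = dict(base)
        phi.update(zip(int_n, perm))
        if all(frozenset((phi[u], phi[v])) in edges_m for u, v in N.graph.edges()):
            return True
    return False
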