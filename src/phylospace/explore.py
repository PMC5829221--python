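"""Exhaustive enumeration of small tier spaces and exact move-graph distances.

The enumerator builds every network with a given leaf set and tier directly,
by degree-constrained graph generation (leaves of degree 1, internal vertices
of degree 3), independently of the rearrangement operations -- so checking
that the NNI/SPR/TBR closure of one network recovers the whole tier is a
non-circular verification of tier connectivity.

Distances and diameters are exact breadth-first-search values on the move
graph, with networks identified by canonical key.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import networkx as nx

from .core_network import (
    PhyloNetwork,
    blob_decomposition,
    is_pseudo_hamiltonian,
    is_simple,
)
from . import bounds as _bounds
from .echidna import echidna_family, sequence_count
from .operations import (
    nni_moves,
    spr_moves,
    tbr_moves,
    triangle_blowup,
    triangle_collapse,
    triangles,
    spr_raw_move_count,
    IllegalMoveError,
)

DEFAULT_VERTEX_CAP = 12

_MOVE_FUNCS: dict[str, Callable] = {
    "nni": nni_moves,
    "spr": spr_moves,
    "tbr": tbr_moves,
}


# ---------------------------------------------------------------------------
# Direct enumeration
# ---------------------------------------------------------------------------

def _degree_graphs(degrees: list[int], first_internal: int):
    """Yield edge lists of all simple graphs with the given degree sequence.

    Vertices ``>= first_internal`` are interchangeable (unlabelled internal
    vertices); the generator only emits labelings in first-touch normal form
    for them, which covers every isomorphism class at least once.
    """
    n = len(degrees)
    rem = list(degrees)
    adj: list[set[int]] = [set() for _ in range(n)]
    edges: list[tuple[int, int]] = []

    def rec():
        v = next((k for k in range(n) if rem[k] > 0), None)
        if v is None:
            yield list(edges)
            return
        untouched = [u for u in range(first_internal, n)
                     if rem[u] == degrees[u] and u != v]
        cands = [u for u in range(v + 1, n)
                 if rem[u] > 0 and u not in adj[v]]
        need = rem[v]
        if len(cands) < need:
            return
        for combo in itertools.combinations(cands, need):
            # first-touch normal form: the untouched internal vertices used in
            # this step must be the lowest-numbered untouched ones
            fresh = [u for u in combo if u in untouched]
            if fresh != untouched[:len(fresh)]:
                continue
            for u in combo:
                rem[u] -= 1
                adj[v].add(u)
                adj[u].add(v)
                edges.append((v, u))
            rem[v] = 0
            yield from rec()
            rem[v] = need
            for u in combo:
                rem[u] += 1
                adj[v].discard(u)
                adj[u].discard(v)
                edges.pop()

    yield from rec()


@dataclass
class TierSpace:
    """All tier-``i`` networks on a taxon set, with move-graph adjacency."""

    taxa: tuple[str, ...]
    i: int
    networks: dict[tuple, PhyloNetwork]
    _adjacency: dict[str, nx.Graph] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.networks)

    def __contains__(self, N: PhyloNetwork) -> bool:
        return N.canonical_key() in self.networks

    def move_graph(self, op: str = "nni") -> nx.Graph:
        """Graph on canonical keys with one edge per ``op``-move pair."""
        if op not in self._adjacency:
            g = nx.Graph()
            g.add_nodes_from(self.networks)
            move_func = _MOVE_FUNCS[op]
            for key, N in self.networks.items():
                for _, M in move_func(N):
                    mk = M.canonical_key()
                    if mk != key:
                        if mk not in self.networks:
                            raise AssertionError(
                                f"{op} move left the enumerated tier space")
                        g.add_edge(key, mk)
            self._adjacency[op] = g
        return self._adjacency[op]

    def distance(self, N: PhyloNetwork, M: PhyloNetwork, op: str = "nni") -> int:
        return nx.shortest_path_length(self.move_graph(op),
                                       N.canonical_key(), M.canonical_key())

    def diameter(self, op: str = "nni") -> int:
        g = self.move_graph(op)
        if g.number_of_nodes() == 1:
            return 0
        return nx.diameter(g)

    def is_connected(self, op: str = "nni") -> bool:
        return nx.is_connected(self.move_graph(op))


def enumerate_tier(taxa: Iterable[str] | int, i: int,
                   cap: int = DEFAULT_VERTEX_CAP) -> TierSpace:
    """All tier-``i`` networks on ``taxa`` up to label-fixing isomorphism.

    ``taxa`` may be an iterable of labels or an integer ``l`` (labels
    ``"1".."l"``).  Networks are generated by direct degree-constrained
    construction, not by move closure.
    """
    if isinstance(taxa, int):
        taxa = tuple(str(k) for k in range(1, taxa + 1))
    else:
        taxa = tuple(taxa)
    ell = len(taxa)
    if ell < 3 or i < 0:
        raise ValueError("need at least 3 taxa and i >= 0")
    n = 2 * (ell + i - 1)
    if n > cap:
        raise ValueError(f"n = {n} exceeds enumeration cap {cap}")
    degrees = [1] * ell + [3] * (n - ell)
    labels = {taxa[k]: k for k in range(ell)}
    out: dict[tuple, PhyloNetwork] = {}
    for edges in _degree_graphs(degrees, first_internal=ell):
        g = nx.Graph(edges)
        if g.number_of_nodes() != n or not nx.is_connected(g):
            continue
        N = PhyloNetwork(edges, labels)
        out.setdefault(N.canonical_key(), N)
    return TierSpace(taxa=taxa, i=i, networks=out)


# ---------------------------------------------------------------------------
# Lazy BFS over move graphs (within a tier or across tiers)
# ---------------------------------------------------------------------------

def _neighbors(N: PhyloNetwork, op: str,
               tier_band: Optional[tuple[int, int]]) -> Iterable[PhyloNetwork]:
    if op in _MOVE_FUNCS:
        for _, M in _MOVE_FUNCS[op](N):
            yield M
        return
    if op != "full":
        raise ValueError(f"unknown operation set {op!r}")
    lo, hi = tier_band if tier_band else (0, None)
    t = N.tier()
    for _, M in nni_moves(N):
        yield M
    if hi is None or t + 1 <= hi:
        for v in N.internal_vertices():
            yield triangle_blowup(N, v)
    if t - 1 >= lo:
        for c in triangles(N):
            try:
                yield triangle_collapse(N, c)
            except IllegalMoveError:
                continue


def bfs_distance(N: PhyloNetwork, target: PhyloNetwork, op: str = "nni",
                 tier_band: Optional[tuple[int, int]] = None,
                 max_depth: Optional[int] = None) -> int:
    """Exact geodesic length from ``N`` to ``target`` in the ``op`` move graph.

    ``op`` is one of ``"nni"``, ``"spr"``, ``"tbr"`` (within-tier) or
    ``"full"`` (NNI plus triangle operations; restricted to ``tier_band =
    (lo, hi)`` when given, to keep the search finite).

    Raises ``ValueError`` if the target is not reached within ``max_depth``.
    """
    start, goal = N.canonical_key(), target.canonical_key()
    if start == goal:
        return 0
    seen = {start}
    frontier = deque([(N, 0)])
    while frontier:
        cur, d = frontier.popleft()
        if max_depth is not None and d >= max_depth:
            continue
        for M in _neighbors(cur, op, tier_band):
            k = M.canonical_key()
            if k in seen:
                continue
            if k == goal:
                return d + 1
            seen.add(k)
            frontier.append((M, d + 1))
    raise ValueError(f"target not reachable under {op!r}"
                     + (f" within depth {max_depth}" if max_depth else ""))


def bfs_path_moves(N: PhyloNetwork, target: PhyloNetwork, op: str = "nni"):
    """Shortest move sequence from ``N`` to ``target`` (anchors included).

    Returns a list of ``(anchor, network)`` steps; used as the exact fallback
    when a constructive path phase cannot legally proceed.
    """
    start, goal = N.canonical_key(), target.canonical_key()
    if start == goal:
        return []
    move_func = _MOVE_FUNCS[op]
    seen = {start}
    frontier = deque([(N, [])])
    while frontier:
        cur, steps = frontier.popleft()
        for anchor, M in move_func(cur):
            k = M.canonical_key()
            if k in seen:
                continue
            new_steps = steps + [(anchor, M)]
            if k == goal:
                return new_steps
            seen.add(k)
            frontier.append((M, new_steps))
    raise ValueError(f"target not reachable under {op!r}")


def ball_size(N: PhyloNetwork, m: int, op: str = "nni") -> int:
    """Number of networks within ``m`` ``op``-moves of ``N`` (including it)."""
    seen = {N.canonical_key()}
    frontier = deque([(N, 0)])
    while frontier:
        cur, d = frontier.popleft()
        if d >= m:
            continue
        for M in _neighbors(cur, op, None):
            k = M.canonical_key()
            if k not in seen:
                seen.add(k)
                frontier.append((M, d + 1))
    return len(seen)


def exact_diameter(space: TierSpace, op: str = "nni") -> int:
    """Maximum pairwise BFS distance over an enumerated tier space."""
    return space.diameter(op)


# ---------------------------------------------------------------------------
# Two-triangle (non-isometric subspace) worked example
# ---------------------------------------------------------------------------

def two_triangle_example(tree: Optional[PhyloNetwork] = None):
    """Blow up each internal vertex of a 4-leaf tree; measure both distances.

    Returns ``(d_full, d_tier)``: the distance between the two blown-up
    networks under NNI+triangle moves (tiers limited to 0..2), and under NNI
    only within tier 1.  The full-space distance is 2 (collapse one triangle,
    blow up the other vertex) while the within-tier distance is strictly
    larger -- tier subspaces are not isometric in the full space.
    """
    if tree is None:
        labels = {"1": 1, "2": 2, "3": 3, "4": 4}
        tree = PhyloNetwork([(1, 5), (2, 5), (5, 6), (6, 3), (6, 4)], labels)
    if tree.tier() != 0 or tree.num_leaves != 4:
        raise ValueError("need a 4-leaf tree")
    u, v = tree.internal_vertices()
    N1 = triangle_blowup(tree, u)
    N2 = triangle_blowup(tree, v)
    d_full = bfs_distance(N1, N2, op="full", tier_band=(0, 2))
    d_tier = bfs_distance(N1, N2, op="nni")
    return d_full, d_tier


def nonisometry_witness():
    """A pair witnessing that a tier subspace is not isometric in full space.

    Blows up the two *non-adjacent* internal vertices of a 5-leaf caterpillar
    tree: the full-space distance (two triangle operations) is 2, while the
    within-tier-1 NNI distance is strictly larger.  Non-adjacency matters --
    for adjacent blow-up vertices (as on the 4-leaf tree, where the two hubs
    are necessarily adjacent) the triangle can migrate in two legal NNIs and
    the within-tier distance is also 2.

    Returns ``(d_full, d_tier)``.
    """
    labels = {str(k): k for k in range(1, 6)}
    tree = PhyloNetwork([(1, 6), (2, 6), (6, 7), (3, 7), (7, 8), (4, 8), (5, 8)],
                        labels)
    N1 = triangle_blowup(tree, 6)
    N2 = triangle_blowup(tree, 8)
    d_full = bfs_distance(N1, N2, op="full", tier_band=(0, 2))
    d_tier = bfs_distance(N1, N2, op="nni")
    return d_full, d_tier


# ---------------------------------------------------------------------------
# Verification harness
# ---------------------------------------------------------------------------

DESK_SPACES = [(3, 0), (4, 0), (5, 0), (3, 1), (4, 1), (3, 2)]
DESK_ECHIDNAS = [(3, 1), (3, 2), (4, 1), (4, 2), (5, 1), (4, 3)]


def verify_suite(spaces: Optional[list[tuple[int, int]]] = None,
                 echidnas: Optional[list[tuple[int, int]]] = None,
                 ball_radius: int = 2) -> dict:
    """Verify the structural and metric claims on exhaustively enumerated
    spaces; returns a pass/fail report with counterexamples on failure.

    Checks: tier = cyclomatic number and the edge-count identity; the
    non-trivial cut-edge bound; pseudo-Hamiltonian implies simple; tier
    connectivity under NNI, SPR and TBR; pairwise non-isomorphism and size of
    the echidna families; the counting sandwich (exact tier-0/1 counts and
    the echidna lower bound); the NNI/SPR/TBR diameter sandwiches; operation
    containment and the SPR-vs-TBR distance inequality; the grammar ball
    bound; the SPR one-step bound; and the two-triangle non-isometry example.
    """
    from .fileio import network_to_text

    spaces = DESK_SPACES if spaces is None else spaces
    echidnas = DESK_ECHIDNAS if echidnas is None else echidnas
    report: dict[str, dict] = {}
    enum: dict[tuple[int, int], TierSpace] = {}
    for ell, i in spaces:
        enum[(ell, i)] = enumerate_tier(ell, i)

    def record(name: str, passed: bool, **details):
        report[name] = {"passed": bool(passed), **details}

    # tier identity, edge count, cut-edge bound, pH => simple
    bad = []
    for (ell, i), sp in enum.items():
        for N in sp.networks.values():
            ok = (N.tier() == i == N.reticulation_number()
                  and N.num_edges == 2 * ell - 3 + 3 * i
                  and len(blob_decomposition(N).nontrivial_cut_edges) <= ell + i - 3
                  and (not is_pseudo_hamiltonian(N) or is_simple(N)))
            if not ok:
                bad.append(network_to_text(N))
    record("structure_invariants", not bad, counterexamples=bad[:3])

    # connectivity of each tier under each within-tier operation
    disconnected = []
    for (ell, i), sp in enum.items():
        for op in ("nni", "spr", "tbr"):
            if not sp.is_connected(op):
                disconnected.append((ell, i, op))
    record("tier_connectivity", not disconnected, failures=disconnected)

    # echidna families: size and pairwise non-isomorphism
    fails = []
    for ell, i in echidnas:
        nets = list(echidna_family(ell, i))
        keys = {N.canonical_key() for _, N in nets}
        expected = sequence_count(ell, i - 1)
        if not (len(nets) == expected == len(keys)):
            fails.append((ell, i, len(nets), len(keys), expected))
        for _, N in nets:
            if not (N.tier() == i and is_simple(N) and is_pseudo_hamiltonian(N)):
                fails.append((ell, i, "structure"))
    record("echidna_family", not fails, failures=fails)

    # counting sandwich
    count_fail = []
    for (ell, i), sp in enum.items():
        if i == 0 and len(sp) != _bounds.tier0_count_exact(ell):
            count_fail.append((ell, i, len(sp), _bounds.tier0_count_exact(ell)))
        if i == 1 and len(sp) != _bounds.tier1_count_exact(ell):
            count_fail.append((ell, i, len(sp), _bounds.tier1_count_exact(ell)))
        if i >= 1 and _bounds.count_lower(ell, i) > len(sp):
            count_fail.append((ell, i, "lower_bound_exceeds", len(sp)))
    record("counting_sandwich", not count_fail, failures=count_fail)

    # diameter sandwiches
    diam_fail = []
    for (ell, i), sp in enum.items():
        if i < 1:
            continue
        n = 2 * (ell + i - 1)
        d_nni = sp.diameter("nni")
        lo = max(0.0, _bounds.nni_diameter_lower(n, i))
        hi = _bounds.nni_diameter_upper(n, i)
        if not (lo <= d_nni <= hi):
            diam_fail.append((ell, i, "nni", d_nni, lo, hi))
        d_spr = sp.diameter("spr")
        d_tbr = sp.diameter("tbr")
        if not (d_tbr <= d_spr <= d_nni):
            diam_fail.append((ell, i, "ordering", d_tbr, d_spr, d_nni))
        up = _bounds.spr_tbr_diameter_upper(n, i)
        lo_spr = max(0.0, _bounds.spr_diameter_lower(n, i))
        lo_tbr = max(0.0, _bounds.tbr_diameter_lower(n, i))
        if not (lo_spr <= d_spr <= up and lo_tbr <= d_tbr <= up):
            diam_fail.append((ell, i, "spr_tbr", d_spr, d_tbr, lo_spr, lo_tbr, up))
    record("diameter_sandwich", not diam_fail, failures=diam_fail)

    # neighborhood containment and pairwise distance inequality
    op_fail = []
    for (ell, i), sp in enum.items():
        if i < 1 and (ell, i) not in [(4, 0), (5, 0)]:
            continue
        for N in sp.networks.values():
            from .operations import nni_neighbors, spr_neighbors, tbr_neighbors
            nk = {M.canonical_key() for M in nni_neighbors(N)}
            sk = {M.canonical_key() for M in spr_neighbors(N)}
            tk = {M.canonical_key() for M in tbr_neighbors(N)}
            if not (nk <= sk <= tk):
                op_fail.append((ell, i, "containment", network_to_text(N)))
            n = N.n
            if spr_raw_move_count(N) > _bounds.spr_one_step_bound(n, i):
                op_fail.append((ell, i, "spr_count", network_to_text(N)))
        g_spr = sp.move_graph("spr")
        g_tbr = sp.move_graph("tbr")
        d_spr = dict(nx.all_pairs_shortest_path_length(g_spr))
        d_tbr = dict(nx.all_pairs_shortest_path_length(g_tbr))
        for a in sp.networks:
            for b in sp.networks:
                if d_spr[a][b] > 2 * d_tbr[a][b]:
                    op_fail.append((ell, i, "lemma_spr_le_2tbr", a, b))
    record("operation_laws", not op_fail, failures=op_fail[:5])

    # grammar ball bound
    ball_fail = []
    for (ell, i), sp in enum.items():
        if i < 1:
            continue
        n = 2 * (ell + i - 1)
        for N in list(sp.networks.values())[:5]:
            for m in range(ball_radius + 1):
                if ball_size(N, m, "nni") > _bounds.grammar_ball_bound(ell, i, m):
                    ball_fail.append((ell, i, m))
    record("grammar_ball", not ball_fail, failures=ball_fail)

    # two-triangle non-isometry: the subspace claim is verified on the
    # non-adjacent-blow-up witness; the adjacent (4-leaf) instance is also
    # reported (there the triangle migrates in two NNIs, so both distances
    # are 2)
    d_full, d_tier = nonisometry_witness()
    d_full4, d_tier4 = two_triangle_example()
    record("tier_not_isometric", d_full == 2 and d_tier > 2,
           d_full=d_full, d_tier=d_tier,
           four_leaf_instance={"d_full": d_full4, "d_tier": d_tier4})

    report["all_passed"] = all(v["passed"] for k, v in report.items()
                               if isinstance(v, dict))
    return report
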