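"""The four rearrangement operations: NNI, triangle blow-up/collapse, SPR, TBR.

All operations return a *new* validated :class:`PhyloNetwork`; illegal moves
raise :class:`IllegalMoveError`.  NNI, SPR and TBR preserve the tier; the
triangle operations shift it by exactly +-1.  Moves that would create a loop
or a parallel edge are rejected as illegal rather than silently repaired.

Anchors reference concrete vertex ids of the network a move is applied to;
fresh vertices (triangle blow-up, SPR/TBR subdivision points) are allocated
deterministically so recorded move sequences replay bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import networkx as nx

from .core_network import PhyloNetwork, NetworkError, Vertex

NNI = "NNI"
TRIANGLE_BLOWUP = "TRIANGLE_BLOWUP"
TRIANGLE_COLLAPSE = "TRIANGLE_COLLAPSE"
SPR = "SPR"
TBR = "TBR"


class IllegalMoveError(NetworkError):
    """The requested move violates its preconditions on this network."""


@dataclass(frozen=True)
class Move:
    """One rearrangement event, with enough detail to apply and serialize it.

    anchor semantics by kind:

    - ``NNI``: ordered path ``(v1, v2, v3, v4)``
    - ``TRIANGLE_BLOWUP``: ``(v,)`` -- the degree-3 vertex to blow up
    - ``TRIANGLE_COLLAPSE``: ``(a, b, c)`` -- the 3-cycle to collapse
    - ``SPR``: ``((v, w), (x, y))`` -- edge with detached end ``v``, target edge
    - ``TBR``: ``((v, w), (a, b), (c, d))`` -- deleted edge and the two target
      edges of the suppressed graph
    """

    kind: str
    anchor: tuple
    phase: str = ""

    def serialize(self) -> str:
        flat = []
        for part in self.anchor:
            if isinstance(part, tuple):
                flat.append(",".join(str(p) for p in part))
            else:
                flat.append(str(part))
        return " ".join([self.kind] + flat)

    @staticmethod
    def deserialize(line: str) -> "Move":
        toks = line.split()

        def part(tok: str):
            if "," in tok:
                return tuple(int(t) for t in tok.split(","))
            return int(tok)

        if toks[0] == NNI:
            # NNI anchors are flat paths, not nested pairs
            return Move(NNI, tuple(int(t) for t in toks[1:]))
        return Move(toks[0], tuple(part(t) for t in toks[1:]))


# ---------------------------------------------------------------------------
# NNI
# ---------------------------------------------------------------------------

def nni_apply(N: PhyloNetwork, path: tuple[Vertex, Vertex, Vertex, Vertex]) -> PhyloNetwork:
    """NNI on the path ``v1, v2, v3, v4``: replace it with ``v1, v3, v2, v4``.

    The central edge ``{v2, v3}`` is retained; ``{v1, v2}`` becomes
    ``{v1, v3}`` and ``{v3, v4}`` becomes ``{v2, v4}``.  Requires that
    ``v1..v4`` is a path and that neither ``{v1, v3}`` nor ``{v2, v4}`` is
    already an edge.
    """
    v1, v2, v3, v4 = path
    g = N.graph
    if len({v1, v2, v3, v4}) != 4:
        raise IllegalMoveError(f"NNI anchor {path} is not a path of 4 distinct vertices")
    for a, b in ((v1, v2), (v2, v3), (v3, v4)):
        if not g.has_edge(a, b):
            raise IllegalMoveError(f"NNI anchor {path}: missing edge {{{a}, {b}}}")
    if g.has_edge(v1, v3):
        raise IllegalMoveError(f"NNI on {path}: {{{v1}, {v3}}} is already an edge")
    if g.has_edge(v2, v4):
        raise IllegalMoveError(f"NNI on {path}: {{{v2}, {v4}}} is already an edge")
    return N.copy_with(remove_edges=[(v1, v2), (v3, v4)],
                       add_edges=[(v1, v3), (v2, v4)])


def nni_inverse(move: Move) -> Move:
    """The NNI undoing ``move`` (to be applied to the move's *result*)."""
    v1, v2, v3, v4 = move.anchor
    return Move(NNI, (v1, v3, v2, v4), phase=move.phase)


def nni_anchors(N: PhyloNetwork) -> list[tuple]:
    """All legal NNI anchors, deduplicated over path reversal."""
    g = N.graph
    seen: set[tuple] = set()
    out: list[tuple] = []
    for ev, ew in g.edges():
        for a, b in ((ev, ew), (ew, ev)):
            if g.degree(a) != 3 or g.degree(b) != 3:
                continue
            for v1 in g.neighbors(a):
                if v1 == b:
                    continue
                for v4 in g.neighbors(b):
                    if v4 == a or v4 == v1:
                        continue
                    if g.has_edge(v1, b) or g.has_edge(a, v4):
                        continue
                    anchor = (v1, a, b, v4)
                    fwd = tuple(str(x) for x in anchor)
                    rev = tuple(reversed(fwd))
                    dedup = min(fwd, rev)
                    if dedup in seen:
                        continue
                    seen.add(dedup)
                    out.append(anchor)
    return out


def nni_moves(N: PhyloNetwork) -> Iterator[tuple[tuple, PhyloNetwork]]:
    """All legal NNI moves as ``(anchor, result)`` pairs."""
    for anchor in nni_anchors(N):
        yield anchor, nni_apply(N, anchor)


def _distinct_neighbors(moves: Iterator[tuple[tuple, PhyloNetwork]],
                        self_key: tuple) -> list[PhyloNetwork]:
    out: dict[tuple, PhyloNetwork] = {}
    for _, M in moves:
        k = M.canonical_key()
        if k != self_key and k not in out:
            out[k] = M
    return list(out.values())


def nni_neighbors(N: PhyloNetwork) -> list[PhyloNetwork]:
    """Distinct NNI neighbors of ``N`` up to isomorphism, excluding ``N`` itself."""
    return _distinct_neighbors(nni_moves(N), N.canonical_key())


# ---------------------------------------------------------------------------
# Triangle operations
# ---------------------------------------------------------------------------

def triangle_blowup(N: PhyloNetwork, v: Vertex) -> PhyloNetwork:
    """Replace the degree-3 vertex ``v`` by a 3-cycle (tier + 1).

    Each new cycle vertex inherits one former neighbor of ``v`` (in sorted
    neighbor order, for determinism).
    """
    if v not in N.graph or N.graph.degree(v) != 3:
        raise IllegalMoveError(f"blow-up target {v!r} is not a degree-3 vertex")
    nbrs = sorted(N.graph.neighbors(v), key=str)
    a, b, c = N.fresh_ids(3)
    return N.copy_with(
        remove_vertices=[v],
        add_edges=[(a, b), (b, c), (c, a),
                   (a, nbrs[0]), (b, nbrs[1]), (c, nbrs[2])],
    )


def triangle_collapse(N: PhyloNetwork, cycle: tuple[Vertex, Vertex, Vertex]) -> PhyloNetwork:
    """Collapse the 3-cycle ``cycle`` into a single degree-3 vertex (tier - 1).

    Illegal if the three outside neighbors are not pairwise distinct (the
    collapse would create a parallel edge).
    """
    a, b, c = cycle
    g = N.graph
    if len({a, b, c}) != 3 or not all(x in g for x in (a, b, c)) or not (
            g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(c, a)):
        raise IllegalMoveError(f"{cycle} is not a 3-cycle")
    outside = []
    for t in (a, b, c):
        others = [u for u in g.neighbors(t) if u not in {a, b, c}]
        if len(others) != 1:
            raise IllegalMoveError(f"3-cycle vertex {t!r} lacks a unique outside neighbor")
        outside.append(others[0])
    if len(set(outside)) != 3:
        raise IllegalMoveError(
            f"collapsing {cycle} would create a parallel edge "
            f"(shared outside neighbor among {outside})")
    (v,) = N.fresh_ids(1)
    return N.copy_with(remove_vertices=[a, b, c],
                       add_edges=[(v, u) for u in outside])


def triangles(N: PhyloNetwork) -> list[tuple[Vertex, Vertex, Vertex]]:
    """All 3-cycles of the network, each as a str-sorted vertex triple."""
    g = N.graph
    out = []
    for u in sorted(g.nodes, key=str):
        for v in g.neighbors(u):
            if str(v) <= str(u):
                continue
            for w in g.neighbors(v):
                if str(w) <= str(v):
                    continue
                if g.has_edge(w, u):
                    out.append((u, v, w))
    return out


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------

def spr_apply(N: PhyloNetwork, e: tuple[Vertex, Vertex],
              target: tuple[Vertex, Vertex]) -> PhyloNetwork:
    """SPR on edge ``e = {v, w}`` detaching ``v`` and regrafting onto ``target``.

    Removes ``e``, suppresses ``v`` (merging its two remaining edges into
    ``{v1, v2}``), subdivides the target edge by a fresh vertex ``u`` and adds
    ``{w, u}``.  The target must not share a vertex with ``e``; if ``e`` is a
    cut-edge the target must lie in the component not containing ``w``.
    """
    v, w = e
    g = N.graph
    if not g.has_edge(v, w):
        raise IllegalMoveError(f"SPR: {{{v}, {w}}} is not an edge")
    if g.degree(v) != 3:
        raise IllegalMoveError(f"SPR: detached end {v!r} must have degree 3")
    v1, v2 = [u for u in g.neighbors(v) if u != w]
    if g.has_edge(v1, v2):
        raise IllegalMoveError(f"SPR on {{{v}, {w}}}: {{{v1}, {v2}}} is already an edge")
    x, y = target
    if not g.has_edge(x, y):
        raise IllegalMoveError(f"SPR: target {{{x}, {y}}} is not an edge")
    if {x, y} & {v, w}:
        raise IllegalMoveError(f"SPR: target {{{x}, {y}}} is adjacent to {{{v}, {w}}}")
    h = g.copy()
    h.remove_edge(v, w)
    if not nx.has_path(h, v, w):
        comp = nx.node_connected_component(h, v)
        if x not in comp or y not in comp:
            raise IllegalMoveError(
                f"SPR on cut-edge {{{v}, {w}}}: target must avoid the component of {w!r}")
    (u,) = N.fresh_ids(1)
    return N.copy_with(
        remove_vertices=[v],
        remove_edges=[(x, y)],
        add_edges=[(v1, v2), (x, u), (u, y), (w, u)],
    )


def spr_moves(N: PhyloNetwork) -> Iterator[tuple[tuple, PhyloNetwork]]:
    """All legal SPR moves as ``(anchor, result)`` with anchor ``(e, target)``."""
    edges = N.edges()
    for ev, ew in edges:
        for v, w in ((ev, ew), (ew, ev)):
            if N.graph.degree(v) != 3:
                continue
            v1, v2 = [u for u in N.graph.neighbors(v) if u != w]
            if N.graph.has_edge(v1, v2):
                continue
            for x, y in edges:
                if {x, y} & {v, w}:
                    continue
                try:
                    M = spr_apply(N, (v, w), (x, y))
                except NetworkError:
                    continue
                yield ((v, w), (x, y)), M


def spr_neighbors(N: PhyloNetwork) -> list[PhyloNetwork]:
    """Distinct SPR neighbors up to isomorphism, excluding ``N`` itself."""
    return _distinct_neighbors(spr_moves(N), N.canonical_key())


def spr_raw_move_count(N: PhyloNetwork) -> int:
    """Number of legal (edge, detached end, target) SPR triples.

    Bounded above by ``2(n + i - 1)(n + i - 4)`` (the unconstrained count of
    such triples).
    """
    return sum(1 for _ in spr_moves(N))


# ---------------------------------------------------------------------------
# TBR
# ---------------------------------------------------------------------------

def _tbr_suppressed(N: PhyloNetwork, e: tuple[Vertex, Vertex]):
    """Multigraph after deleting ``e`` and suppressing both (degree-3) ends.

    Returns ``(multigraph, was_cut_edge)``.  The merged edges ``{v1, v2}``
    and ``{w1, w2}`` may duplicate existing edges; such parallel pairs are
    admissible in the intermediate and must be resolved by the reconnection
    step subdividing one copy (the final network is always a simple graph).
    """
    v, w = e
    g = N.graph
    if not g.has_edge(v, w):
        raise IllegalMoveError(f"TBR: {{{v}, {w}}} is not an edge")
    if g.degree(v) != 3 or g.degree(w) != 3:
        raise IllegalMoveError(f"TBR: both ends of {{{v}, {w}}} must have degree 3")
    v1, v2 = [u for u in g.neighbors(v) if u != w]
    w1, w2 = [u for u in g.neighbors(w) if u != v]
    h = nx.MultiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(g.edges())
    h.remove_edge(v, w)
    was_cut = not nx.has_path(h, v, w)
    h.remove_nodes_from([v, w])
    h.add_edge(v1, v2)
    h.add_edge(w1, w2)
    return h, was_cut


def _multi_edge_key(h: nx.MultiGraph, spec: tuple) -> tuple:
    """Normalize an edge spec ``(a, b)`` or ``(a, b, key)`` to ``(a, b, key)``."""
    if len(spec) == 3:
        a, b, k = spec
    else:
        a, b = spec
        k = min(h[a][b]) if h.has_edge(a, b) else 0
    if not h.has_edge(a, b, k):
        raise IllegalMoveError(f"TBR: {{{a}, {b}}} is not an edge after suppression")
    return a, b, k


def tbr_apply(N: PhyloNetwork, e: tuple[Vertex, Vertex],
              e1: tuple[Vertex, Vertex], e2: tuple[Vertex, Vertex]) -> PhyloNetwork:
    """TBR: delete ``e``, suppress both ends, reconnect via subdivisions.

    ``e1`` and ``e2`` are distinct edges of the suppressed graph (which
    includes the two merged edges); fresh subdivision vertices ``u1``, ``u2``
    are joined by a new edge.  If ``e`` was a cut-edge, ``e1`` and ``e2`` must
    lie in distinct components of the suppressed graph.

    Degenerate pendant case: if one end of ``e`` is a leaf, bisection
    isolates that leaf (a one-vertex component that cannot be suppressed);
    the leaf is then reattached directly to the subdivision vertex of the
    single target edge ``e1``, with ``e2 = (leaf,)`` marking the case.  This
    keeps TBR the generalization of its tree-space namesake, where bisecting
    a pendant edge moves one leaf (and coincides with the SPR doing so).
    """
    if len(e2) == 1:
        (w,) = e2
        v = e[0] if e[1] == w else e[1]
        if N.graph.degree(w) != 1 or not N.graph.has_edge(v, w):
            raise IllegalMoveError(f"TBR pendant case needs a pendant edge at {w!r}")
        return spr_apply(N, (v, w), e1)
    h, was_cut = _tbr_suppressed(N, e)
    a1, b1, k1 = _multi_edge_key(h, e1)
    a2, b2, k2 = _multi_edge_key(h, e2)
    if (frozenset((a1, b1)), k1) == (frozenset((a2, b2)), k2):
        raise IllegalMoveError("TBR: the two target edges must be distinct")
    if was_cut:
        comp = nx.node_connected_component(h, a1)
        if a2 in comp:
            raise IllegalMoveError(
                f"TBR on cut-edge {{{e[0]}, {e[1]}}}: targets must lie in distinct components")
    u1, u2 = N.fresh_ids(2)
    h.remove_edge(a1, b1, k1)
    h.remove_edge(a2, b2, k2)
    h.add_edges_from([(a1, u1), (u1, b1),
                      (a2, u2), (u2, b2),
                      (u1, u2)])
    try:
        return PhyloNetwork(list(h.edges()), N.leaf_labels)
    except NetworkError as exc:
        raise IllegalMoveError(f"TBR would leave an invalid network: {exc}") from exc


def tbr_moves(N: PhyloNetwork) -> Iterator[tuple[tuple, PhyloNetwork]]:
    """All legal TBR moves as ``(anchor, result)``, pendant bisections included."""
    for ev, ew in N.edges():
        for v, w in ((ev, ew), (ew, ev)):
            if N.graph.degree(w) != 1 or N.graph.degree(v) != 3:
                continue
            for x, y in N.edges():
                if {x, y} & {v, w}:
                    continue
                try:
                    M = spr_apply(N, (v, w), (x, y))
                except NetworkError:
                    continue
                yield ((v, w), (x, y), (w,)), M
    for v, w in N.edges():
        try:
            h, was_cut = _tbr_suppressed(N, (v, w))
        except IllegalMoveError:
            continue
        hedges = sorted(((*sorted((a, b), key=str), k)
                         for a, b, k in h.edges(keys=True)), key=str)
        if was_cut:
            comp = nx.node_connected_component(h, hedges[0][0])
            side1 = [e for e in hedges if e[0] in comp]
            side2 = [e for e in hedges if e[0] not in comp]
            pairs = [(a, b) for a in side1 for b in side2]
        else:
            pairs = [(hedges[i], hedges[j])
                     for i in range(len(hedges)) for j in range(i + 1, len(hedges))]
        for e1, e2 in pairs:
            try:
                M = tbr_apply(N, (v, w), e1, e2)
            except NetworkError:
                continue
            yield ((v, w), e1, e2), M


def tbr_neighbors(N: PhyloNetwork) -> list[PhyloNetwork]:
    """Distinct TBR neighbors up to isomorphism, excluding ``N`` itself."""
    return _distinct_neighbors(tbr_moves(N), N.canonical_key())


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

def apply_move(N: PhyloNetwork, move: Move) -> PhyloNetwork:
    """Apply a recorded move to ``N``."""
    if move.kind == NNI:
        return nni_apply(N, move.anchor)
    if move.kind == TRIANGLE_BLOWUP:
        return triangle_blowup(N, move.anchor[0])
    if move.kind == TRIANGLE_COLLAPSE:
        return triangle_collapse(N, move.anchor)
    if move.kind == SPR:
        return spr_apply(N, move.anchor[0], move.anchor[1])
    if move.kind == TBR:
        return tbr_apply(N, move.anchor[0], move.anchor[1], move.anchor[2])
    raise ValueError(f"unknown move kind {move.kind!r}")
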