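"""Data model and structural predicates for unrooted binary phylogenetic networks.

A phylogenetic network on a taxon set ``X`` (with ``|X| >= 3``) is a connected
simple graph in which every vertex has degree 1 or 3 and whose degree-1
vertices are bijectively labelled by ``X``.  Writing ``n`` for the number of
vertices, ``l = |X|`` for the number of leaves and ``i`` for the *tier*, these
satisfy ``n = 2(l + i - 1)``; the tier equals the cyclomatic (reticulation)
number ``|E| - |V| + 1``, and the edge count is ``2l - 3 + 3i``.

This module provides the :class:`PhyloNetwork` container (a thin validated
wrapper around a :class:`networkx.Graph`), blob/cut-edge decomposition,
simplicity and pseudo-Hamiltonicity predicates, and a leaf-label-respecting
canonical form used as the sole notion of identity across networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional

import networkx as nx

Vertex = Hashable


class NetworkError(ValueError):
    """Base class for invalid-network conditions."""


class DegreeError(NetworkError):
    """A vertex has degree other than 1 or 3."""


class DisconnectedError(NetworkError):
    """The graph is not connected."""


class LoopError(NetworkError):
    """An edge joins a vertex to itself."""


class ParallelEdgeError(NetworkError):
    """Two edges share the same pair of endpoints."""


class LabelError(NetworkError):
    """The leaf labelling is not a bijection X -> degree-1 vertices, or |X| < 3."""


class PhyloNetwork:
    """An unrooted binary phylogenetic network on a labelled leaf set.

    Parameters
    ----------
    edges
        Iterable of unordered vertex pairs.  Vertex ids are opaque hashables;
        they carry no meaning across networks (canonical keys are the only
        notion of identity).
    leaf_labels
        Mapping from taxon name to the degree-1 vertex carrying it.  Must be a
        bijection onto the degree-1 vertices, with at least 3 taxa.

    Raises
    ------
    LoopError, ParallelEdgeError, DegreeError, DisconnectedError, LabelError
        One distinct error kind per violated invariant.
    """

    __slots__ = ("graph", "leaf_labels", "_label_of", "_canon")

    def __init__(self, edges: Iterable[tuple[Vertex, Vertex]],
                 leaf_labels: Mapping[str, Vertex]):
        g = nx.Graph()
        for u, v in edges:
            if u == v:
                raise LoopError(f"loop at vertex {u!r}")
            if g.has_edge(u, v):
                raise ParallelEdgeError(f"parallel edge {{{u!r}, {v!r}}}")
            g.add_edge(u, v)
        if g.number_of_nodes() == 0:
            raise LabelError("empty network")
        for v, d in g.degree():
            if d not in (1, 3):
                raise DegreeError(f"vertex {v!r} has degree {d}")
        if not nx.is_connected(g):
            raise DisconnectedError("network is not connected")
        leaves = {v for v, d in g.degree() if d == 1}
        labels = dict(leaf_labels)
        if len(labels) < 3:
            raise LabelError(f"need at least 3 taxa, got {len(labels)}")
        if set(labels.values()) != leaves or len(set(labels.values())) != len(labels):
            raise LabelError(
                "leaf labels must biject taxa onto the degree-1 vertices: "
                f"labelled {sorted(map(repr, labels.values()))}, "
                f"leaves {sorted(map(repr, leaves))}"
            )
        self.graph = g
        self.leaf_labels = labels
        self._label_of = {v: x for x, v in labels.items()}
        self._canon: Optional[tuple] = None

    # -- basic counts -----------------------------------------------------

    @property
    def n(self) -> int:
        """Number of vertices ``|V(N)|``."""
        return self.graph.number_of_nodes()

    @property
    def num_leaves(self) -> int:
        """Number of leaves ``l = |X|``."""
        return len(self.leaf_labels)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaf_labels)

    @property
    def num_edges(self) -> int:
        return self.graph.number_of_edges()

    def tier(self) -> int:
        """Tier index ``i`` with ``n = 2(l + i - 1)``.

        Equals the reticulation number; both identities follow from the
        degree constraints, so no separate bookkeeping is needed.
        """
        return self.n // 2 - self.num_leaves + 1

    def reticulation_number(self) -> int:
        """Cyclomatic number ``r(N) = |E| - |V| + 1``."""
        return self.num_edges - self.n + 1

    # -- conveniences ------------------------------------------------------

    @property
    def leaves(self) -> set[Vertex]:
        return set(self.leaf_labels.values())

    def label_of(self, v: Vertex) -> Optional[str]:
        """Taxon carried by leaf vertex ``v``, or ``None`` for internal vertices."""
        return self._label_of.get(v)

    def internal_vertices(self) -> list[Vertex]:
        return [v for v, d in self.graph.degree() if d == 3]

    def edges(self) -> list[tuple[Vertex, Vertex]]:
        return list(self.graph.edges())

    def fresh_ids(self, k: int) -> list[int]:
        """``k`` integer vertex ids not present in the network.

        Deterministic (max int id + 1 upward) so that move sequences are
        replayable.
        """
        ints = [v for v in self.graph.nodes if isinstance(v, int)]
        start = max(ints, default=-1) + 1
        return list(range(start, start + k))

    def copy_with(self, remove_vertices=(), remove_edges=(), add_edges=(),
                  leaf_labels: Optional[Mapping[str, Vertex]] = None) -> "PhyloNetwork":
        """New validated network derived by the given edits."""
        g = self.graph.copy()
        g.remove_edges_from(remove_edges)
        g.remove_nodes_from(remove_vertices)
        edges = list(g.edges()) + list(add_edges)
        return PhyloNetwork(edges, leaf_labels if leaf_labels is not None
                            else self.leaf_labels)

    def __repr__(self) -> str:
        return (f"PhyloNetwork(l={self.num_leaves}, tier={self.tier()}, "
                f"n={self.n}, m={self.num_edges})")

    # -- canonical form ----------------------------------------------------

    def canonical_key(self) -> tuple:
        """Hashable key equal across two networks iff they are isomorphic by a
        graph isomorphism fixing every leaf label.  Cached."""
        if self._canon is None:
            self._canon = _canonical(self)[0]
        return self._canon

    def canonical_labeling(self) -> dict[Vertex, int]:
        """A vertex -> 0..n-1 relabelling realizing :meth:`canonical_key`.

        Composing one network's labelling with the inverse of another's yields
        an explicit label-fixing isomorphism whenever the keys agree.
        """
        key, lab = _canonical(self)
        if self._canon is None:
            self._canon = key
        return lab


def validate(edges: Iterable[tuple[Vertex, Vertex]],
             leaf_labels: Mapping[str, Vertex]) -> PhyloNetwork:
    """Check a candidate vertex/edge/label collection and return a network.

    Raises a distinct :class:`NetworkError` subclass per violated invariant.
    """
    return PhyloNetwork(edges, leaf_labels)


# ---------------------------------------------------------------------------
# Canonical form: colour leaves by taxon, internal vertices one colour, then
# canonical labelling by iterative partition refinement with individualization
# backtracking.  Leaf labels break most symmetry, so refinement is cheap at
# the scales this package targets (n <= ~20).
# ---------------------------------------------------------------------------

def _refine(adj: dict, parts: list[list]) -> list[list]:
    """Equitable refinement of an ordered partition (1-dim WL with cell order)."""
    parts = [list(p) for p in parts]
    changed = True
    while changed:
        changed = False
        index = {}
        for j, p in enumerate(parts):
            for v in p:
                index[v] = j
        for j, cell in enumerate(parts):
            if len(cell) <= 1:
                continue
            sig: dict[tuple, list] = {}
            for v in cell:
                s = tuple(sorted(index[u] for u in adj[v]))
                sig.setdefault(s, []).append(v)
            if len(sig) > 1:
                parts[j:j + 1] = [sig[s] for s in sorted(sig)]
                changed = True
                break
    return parts


def _canonical(N: PhyloNetwork) -> tuple[tuple, dict[Vertex, int]]:
    g = N.graph
    adj = {v: list(g.neighbors(v)) for v in g.nodes}
    taxa = sorted(N.leaf_labels)
    # ordered initial partition: one singleton cell per taxon, then internals
    parts: list[list] = [[N.leaf_labels[x]] for x in taxa]
    internal = [v for v, d in g.degree() if d == 3]
    if internal:
        parts.append(internal)

    best: list = [None, None]  # best (key, labeling)

    def visit(parts: list[list]) -> None:
        parts = _refine(adj, parts)
        target = None
        for j, cell in enumerate(parts):
            if len(cell) > 1:
                target = j
                break
        if target is None:
            lab = {}
            for pos, cell in enumerate(parts):
                lab[cell[0]] = pos
            key = tuple(sorted(tuple(sorted((lab[u], lab[v]))) for u, v in g.edges()))
            if best[0] is None or key < best[0]:
                best[0], best[1] = key, lab
            return
        cell = parts[target]
        for v in cell:
            rest = [u for u in cell if u is not v]
            visit(parts[:target] + [[v], rest] + parts[target + 1:])

    visit(parts)
    full_key = (N.n, tuple(taxa), best[0])
    return full_key, best[1]


def canonical_key(N: PhyloNetwork) -> tuple:
    """Module-level alias for :meth:`PhyloNetwork.canonical_key`."""
    return N.canonical_key()


def is_isomorphic(N: PhyloNetwork, M: PhyloNetwork) -> bool:
    """True iff a graph isomorphism fixing each leaf label exists.

    Raises
    ------
    LabelError
        If the two networks are on different taxon sets.
    """
    if N.taxa != M.taxa:
        raise LabelError(f"different taxon sets: {sorted(N.taxa)} vs {sorted(M.taxa)}")
    if N.n != M.n or N.num_edges != M.num_edges:
        return False
    return N.canonical_key() == M.canonical_key()


# ---------------------------------------------------------------------------
# Blobs and cut-edges
# ---------------------------------------------------------------------------

@dataclass
class BlobDecomposition:
    """Blobs (maximal 2-edge-connected non-vertex subgraphs) and cut-edges."""

    blobs: list[frozenset]
    cut_edges: set[frozenset]
    trivial_cut_edges: set[frozenset] = field(default_factory=set)

    @property
    def nontrivial_cut_edges(self) -> set[frozenset]:
        return self.cut_edges - self.trivial_cut_edges


def blob_decomposition(N: PhyloNetwork) -> BlobDecomposition:
    """Cut-edges with trivial/non-trivial flags, plus the blobs.

    A cut-edge is *trivial* if one of the two components created by its
    removal is a single vertex; a blob is a connected component of the graph
    minus its cut-edges that is not a single vertex.
    """
    g = N.graph
    bridges = {frozenset(e) for e in nx.bridges(g)}
    trivial = set()
    for e in bridges:
        u, v = tuple(e)
        # with all degrees in {1,3}, a one-vertex side is exactly a leaf side,
        # but we decide from actual component sizes to stay definitional
        h = g.copy()
        h.remove_edge(u, v)
        comp_u = nx.node_connected_component(h, u)
        comp_v = nx.node_connected_component(h, v)
        if len(comp_u) == 1 or len(comp_v) == 1:
            trivial.add(e)
    h = g.copy()
    h.remove_edges_from(tuple(e) for e in bridges)
    blobs = [frozenset(c) for c in nx.connected_components(h) if len(c) > 1]
    return BlobDecomposition(blobs=sorted(blobs, key=lambda b: sorted(map(str, b))),
                             cut_edges=bridges, trivial_cut_edges=trivial)


def is_simple(N: PhyloNetwork) -> bool:
    """True iff every cut-edge is trivial.

    Trees on 3 or more leaves are never simple: their internal edges are
    non-trivial cut-edges.
    """
    return not blob_decomposition(N).nontrivial_cut_edges


def shrink_blobs(N: PhyloNetwork) -> nx.Graph:
    """Shrink each blob to a single vertex, returning the resulting tree.

    The result is a leaf-labelled :class:`networkx.Graph` tree on X (node
    attribute ``taxon`` on leaves).  It is diagnostic: degree-2 vertices
    created by shrinking are retained, so it is generally not a valid
    PhyloNetwork.  Its vertex count is at most ``2l + i - 2``.
    """
    dec = blob_decomposition(N)
    rep: dict[Vertex, Vertex] = {}
    for blob in dec.blobs:
        r = sorted(blob, key=str)[0]
        for v in blob:
            rep[v] = r
    t = nx.Graph()
    for v in N.graph.nodes:
        t.add_node(rep.get(v, v))
    for u, v in N.graph.edges():
        ru, rv = rep.get(u, u), rep.get(v, v)
        if ru != rv:
            t.add_edge(ru, rv)
    for x, v in N.leaf_labels.items():
        t.nodes[rep.get(v, v)]["taxon"] = x
    return t


# ---------------------------------------------------------------------------
# Pseudo-Hamiltonicity
# ---------------------------------------------------------------------------

PSEUDO_HAMILTONIAN_WARN_THRESHOLD = 40


def _hamiltonian_cycle(h: nx.Graph) -> Optional[list]:
    """Exact backtracking Hamiltonian-cycle search on a small graph."""
    nodes = sorted(h.nodes, key=str)
    k = len(nodes)
    if k < 3:
        return None
    start = nodes[0]
    path = [start]
    used = {start}

    def extend() -> Optional[list]:
        if len(path) == k:
            return list(path) if h.has_edge(path[-1], start) else None
        for u in sorted(h.neighbors(path[-1]), key=str):
            if u not in used:
                path.append(u)
                used.add(u)
                got = extend()
                if got is not None:
                    return got
                used.discard(u)
                path.pop()
        return None

    return extend()


def longest_cycle(h: nx.Graph) -> Optional[list]:
    """A maximum-length cycle of ``h`` by exhaustive backtracking, or None.

    Exponential in general; intended for the internal (leafless) part of a
    network at desk scale.
    """
    nodes = sorted(h.nodes, key=str)
    best: list = [None]

    def search(start, path, used):
        if len(path) >= 3 and h.has_edge(path[-1], start):
            if best[0] is None or len(path) > len(best[0]):
                best[0] = list(path)
        for u in h.neighbors(path[-1]):
            # only extend with vertices >= start to avoid re-finding each
            # cycle from every basepoint
            if u not in used and str(u) > str(start):
                path.append(u)
                used.add(u)
                search(start, path, used)
                used.discard(u)
                path.pop()

    for start in nodes:
        search(start, [start], {start})
    return best[0]


def is_pseudo_hamiltonian(N: PhyloNetwork, return_witness: bool = False):
    """Whether ``N`` contains a cycle through every non-leaf vertex.

    Decided by exact backtracking over the internal (degree-3) subgraph; the
    leaf vertices cannot lie on a cycle, so the question is exactly whether
    that cubic subgraph is Hamiltonian.  Emits a warning above
    ``PSEUDO_HAMILTONIAN_WARN_THRESHOLD`` vertices, where the exact search may
    be slow.  Every pseudo-Hamiltonian network is simple.

    Returns ``bool``, or ``(bool, cycle-or-None)`` if ``return_witness``.
    """
    if N.n > PSEUDO_HAMILTONIAN_WARN_THRESHOLD:
        warnings.warn(
            f"exact pseudo-Hamiltonicity search on n={N.n} vertices may be slow",
            stacklevel=2,
        )
    internal = N.internal_vertices()
    if N.tier() == 0 or len(internal) < 3:
        return (False, None) if return_witness else False
    h = N.graph.subgraph(internal)
    cyc = _hamiltonian_cycle(h)
    if return_witness:
        return (cyc is not None), cyc
    return cyc is not None
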