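"""Network file formats and seeded fixture generation.

The native format is a plain-text edge list:

.. code-block:: text

    # optional comments
    4 1          <- header: leaf count, tier
    0 4          <- exactly 2l - 3 + 3i edge lines "u v" (integer vertex ids)
    ...
    1 0          <- exactly l label lines "taxon vertex"
    ...

GraphML and DOT are provided for interchange and visualization.  Unrooted
networks have no standard serialization (extended Newick is rooted-centric),
so the edge-list format is primary.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx

from .core_network import PhyloNetwork, NetworkError
from .echidna import EchidnaSpec, build_echidna
from .operations import nni_anchors, nni_apply


class ParseError(ValueError):
    """Malformed network file; message includes the offending line number."""


def network_to_text(N: PhyloNetwork) -> str:
    """Serialize to the native edge-list format (vertices renamed 0..n-1)."""
    order = {v: k for k, v in enumerate(sorted(N.graph.nodes, key=str))}
    lines = [f"{N.num_leaves} {N.tier()}"]
    for u, v in sorted((tuple(sorted((order[a], order[b]))) for a, b in N.graph.edges())):
        lines.append(f"{u} {v}")
    for x in sorted(N.leaf_labels):
        lines.append(f"{x} {order[N.leaf_labels[x]]}")
    return "\n".join(lines) + "\n"


def network_from_text(text: str) -> PhyloNetwork:
    """Parse the native edge-list format."""
    rows = [(k + 1, ln.strip()) for k, ln in enumerate(text.splitlines())]
    rows = [(k, ln) for k, ln in rows if ln and not ln.startswith("#")]
    if not rows:
        raise ParseError("line 1: empty file")
    k, header = rows[0]
    try:
        ell, i = map(int, header.split())
    except ValueError:
        raise ParseError(f"line {k}: header must be '<leaves> <tier>'") from None
    n_edges = 2 * ell - 3 + 3 * i
    body = rows[1:]
    if len(body) != n_edges + ell:
        raise ParseError(
            f"line {k}: expected {n_edges} edge lines and {ell} label lines, "
            f"got {len(body)} lines")
    edges = []
    for k, ln in body[:n_edges]:
        try:
            u, v = map(int, ln.split())
        except ValueError:
            raise ParseError(f"line {k}: edge line must be '<u> <v>'") from None
        edges.append((u, v))
    labels = {}
    for k, ln in body[n_edges:]:
        parts = ln.split()
        if len(parts) != 2:
            raise ParseError(f"line {k}: label line must be '<taxon> <vertex>'")
        try:
            labels[parts[0]] = int(parts[1])
        except ValueError:
            raise ParseError(f"line {k}: vertex id must be an integer") from None
    try:
        N = PhyloNetwork(edges, labels)
    except NetworkError as exc:
        raise ParseError(f"invalid network in file: {exc}") from exc
    if N.num_leaves != ell or N.tier() != i:
        raise ParseError(
            f"header says l={ell} i={i} but file describes "
            f"l={N.num_leaves} i={N.tier()}")
    return N


def _to_nx(N: PhyloNetwork) -> nx.Graph:
    g = nx.Graph()
    order = {v: k for k, v in enumerate(sorted(N.graph.nodes, key=str))}
    for v in N.graph.nodes:
        taxon = N.label_of(v)
        g.add_node(order[v], taxon=taxon if taxon else "")
    g.add_edges_from((order[u], order[v]) for u, v in N.graph.edges())
    return g


def network_to_dot(N: PhyloNetwork) -> str:
    """Graphviz DOT text; leaves shown with their taxon labels."""
    order = {v: k for k, v in enumerate(sorted(N.graph.nodes, key=str))}
    lines = ["graph phylonetwork {", "  node [shape=point];"]
    for x in sorted(N.leaf_labels):
        lines.append(f'  {order[N.leaf_labels[x]]} [shape=circle, label="{x}"];')
    for u, v in sorted((tuple(sorted((order[a], order[b]))) for a, b in N.graph.edges())):
        lines.append(f"  {u} -- {v};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_network(N: PhyloNetwork, path: Union[str, Path],
                  fmt: str = "native") -> None:
    """Write in ``native``, ``graphml`` or ``dot`` format."""
    path = Path(path)
    if fmt == "native":
        path.write_text(network_to_text(N))
    elif fmt == "graphml":
        nx.write_graphml(_to_nx(N), path)
    elif fmt == "dot":
        path.write_text(network_to_dot(N))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path: Union[str, Path], fmt: str = "native") -> PhyloNetwork:
    """Read a network; round-trips are lossless up to vertex renaming."""
    path = Path(path)
    if fmt == "native":
        return network_from_text(path.read_text())
    if fmt == "graphml":
        g = nx.read_graphml(path)
        labels = {}
        edges = []
        mapping = {v: k for k, v in enumerate(g.nodes)}
        for v, data in g.nodes(data=True):
            if data.get("taxon"):
                labels[data["taxon"]] = mapping[v]
        edges = [(mapping[u], mapping[v]) for u, v in g.edges()]
        return PhyloNetwork(edges, labels)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Seeded random fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible random network of given size and tier."""

    ell: int
    i: int
    method: str = "random-walk"  # or "echidna-random"
    walk_length: int = 10
    seed: int = 0


def random_echidna_spec(ell: int, i: int, rng: random.Random) -> EchidnaSpec:
    """Uniform random sequence in S(ell, i-1), identity chord permutation."""
    interior = list(range(2, ell)) + [0] * (i - 1)
    rng.shuffle(interior)
    return EchidnaSpec((1, *interior, ell))


def random_network(spec: FixtureSpec) -> PhyloNetwork:
    """Deterministic pseudorandom network with the requested leaves and tier.

    ``echidna-random`` draws a random echidna; ``random-walk`` additionally
    applies ``walk_length`` uniformly random legal NNI moves (tier
    connectivity means long walks mix within the tier).  Requires ``i >= 1``.
    """
    if spec.i < 1:
        raise ValueError("random fixtures need tier >= 1")
    rng = random.Random(spec.seed)
    N, _ = build_echidna(random_echidna_spec(spec.ell, spec.i, rng))
    if spec.method == "echidna-random":
        return N
    if spec.method != "random-walk":
        raise ValueError(f"unknown method {spec.method!r}")
    for _ in range(spec.walk_length):
        anchors = nni_anchors(N)
        if not anchors:
            break
        N = nni_apply(N, rng.choice(anchors))
    return N
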