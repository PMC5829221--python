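"""Constructive rearrangement paths between networks, with certified moves.

A within-tier NNI path between two tier-``i`` networks (``i >= 1``) is built
in three phases, mirroring the constructive diameter argument:

1. *simplify*: eliminate non-trivial cut-edges one NNI each
   (at most ``l + i - 3`` moves per side);
2. *hamiltonize*: grow a maximum-length cycle of the internal graph by one
   vertex per NNI until it spans all internal vertices
   (at most ``n`` moves per side);
3. *sort*: with both networks pseudo-Hamiltonian, realize the remaining
   difference as adjacent transpositions along the witness cycle, one NNI
   per swap (at most ``C(n - l, 2)`` moves).

The total is at most ``3n + C(n/2 + i - 1, 2) - 2``.  An adjacent swap along
the cycle can occasionally be blocked by a chord (the NNI preconditions
forbid it); such cases fall back to an exact BFS in the tier move graph,
tagged ``bfs-fallback`` and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .core_network import (
    PhyloNetwork,
    blob_decomposition,
    is_pseudo_hamiltonian,
    is_simple,
    longest_cycle,
)
from .operations import (
    Move,
    NNI,
    TRIANGLE_BLOWUP,
    TRIANGLE_COLLAPSE,
    IllegalMoveError,
    apply_move,
    nni_apply,
    nni_inverse,
    triangle_blowup,
)

logger = logging.getLogger(__name__)

PHASE_SIMPLIFY = "simplify"
PHASE_HAMILTONIZE = "hamiltonize"
PHASE_SORT = "sort"
PHASE_TIER_SHIFT = "tier-shift"
PHASE_BFS = "bfs-fallback"


@dataclass
class PathCertificate:
    """An ordered, replayable move list transforming ``source`` into ``target``.

    Every move carries a phase tag; :meth:`replay` re-applies the moves from
    the source and checks the endpoint is isomorphic to the target.
    """

    source: PhyloNetwork
    target: PhyloNetwork
    moves: list[Move] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.moves)

    def phase_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.moves:
            out[m.phase] = out.get(m.phase, 0) + 1
        return out

    def replay(self, verify: bool = True) -> PhyloNetwork:
        cur = self.source
        for m in self.moves:
            cur = apply_move(cur, m)
        if verify and cur.canonical_key() != self.target.canonical_key():
            raise AssertionError("certificate replay did not reach the target")
        return cur

    def extend(self, other: "PathCertificate") -> "PathCertificate":
        """Concatenate with a certificate starting at this one's target."""
        return PathCertificate(self.source, other.target,
                               self.moves + other.moves,
                               {**self.meta, **other.meta})

    def serialize(self) -> str:
        lines = [f"# {len(self.moves)} moves"]
        for m in self.moves:
            lines.append(f"{m.serialize()}  # {m.phase}" if m.phase else m.serialize())
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Phase 1: simplify
# ---------------------------------------------------------------------------

def make_simple(N: PhyloNetwork) -> PathCertificate:
    """NNI path from ``N`` to a simple network (no non-trivial cut-edges).

    Each move acts on a path ``u, a, b, w`` across a non-trivial cut-edge
    ``{a, b}``, which merges that edge into the adjacent blob; the endpoints
    are chosen (deterministically) to minimize the remaining count, which
    drops by at least one per move, so at most ``l + i - 3`` moves are used.
    Unsupported for trees (tier 0 networks cannot be made simple).
    """
    if N.tier() < 1:
        raise ValueError("trees cannot be made simple; need tier >= 1")
    cur = N
    moves: list[Move] = []
    while True:
        nontrivial = blob_decomposition(cur).nontrivial_cut_edges
        if not nontrivial:
            break
        count = len(nontrivial)
        best = None
        for e in sorted(nontrivial, key=lambda s: sorted(map(str, s))):
            a, b = sorted(e, key=str)
            for x, y in ((a, b), (b, a)):
                us = sorted((z for z in cur.graph.neighbors(x) if z != y), key=str)
                ws = sorted((z for z in cur.graph.neighbors(y) if z != x), key=str)
                for u in us:
                    for w in ws:
                        try:
                            M = nni_apply(cur, (u, x, y, w))
                        except IllegalMoveError:
                            continue
                        c = len(blob_decomposition(M).nontrivial_cut_edges)
                        if best is None or c < best[0]:
                            best = (c, (u, x, y, w), M)
            if best is not None and best[0] < count:
                break
        if best is None or best[0] >= count:
            raise AssertionError("no cut-edge-reducing NNI found")
        moves.append(Move(NNI, best[1], phase=PHASE_SIMPLIFY))
        cur = best[2]
    return PathCertificate(N, cur, moves)


# ---------------------------------------------------------------------------
# Phase 2: hamiltonize
# ---------------------------------------------------------------------------

def make_pseudo_hamiltonian(N: PhyloNetwork) -> PathCertificate:
    """NNI path from a simple network to a pseudo-Hamiltonian one.

    Repeatedly recomputes a maximum-length cycle ``C`` of the internal graph
    and, while some internal vertex ``v`` lies outside ``C`` adjacent to a
    cycle vertex ``w``, applies the NNI on ``w1, w, v, v1`` (``w1`` a cycle
    neighbor of ``w``, ``v1`` any other neighbor of ``v``), which splices
    ``v`` into the cycle.  Maximality of ``C`` guarantees the move is legal,
    and simplicity is preserved; at most ``n`` moves are needed.  The final
    witness cycle is stored under ``meta["witness"]``.
    """
    if N.tier() < 1:
        raise ValueError("need tier >= 1")
    if not is_simple(N):
        raise ValueError("input must be simple")
    cur = N
    moves: list[Move] = []
    lengths: list[int] = []
    while True:
        internal = set(cur.internal_vertices())
        h = cur.graph.subgraph(internal)
        cycle = longest_cycle(h)
        lengths.append(len(cycle))
        if len(cycle) == len(internal):
            break
        in_cycle = set(cycle)
        pick = None
        for w in sorted(cycle, key=str):
            outs = sorted((v for v in h.neighbors(w) if v not in in_cycle), key=str)
            if outs:
                pick = (w, outs[0])
                break
        if pick is None:
            raise AssertionError("cycle not spanning yet no adjacent outside vertex")
        w, v = pick
        pos = cycle.index(w)
        w1 = cycle[(pos - 1) % len(cycle)]
        v1 = sorted((z for z in cur.graph.neighbors(v) if z != w), key=str)[0]
        moves.append(Move(NNI, (w1, w, v, v1), phase=PHASE_HAMILTONIZE))
        cur = nni_apply(cur, (w1, w, v, v1))
        if not is_simple(cur):  # the splice preserves simplicity
            raise AssertionError("hamiltonize step broke simplicity")
    cert = PathCertificate(N, cur, moves)
    cert.meta["witness"] = longest_cycle(cur.graph.subgraph(cur.internal_vertices()))
    cert.meta["cycle_lengths"] = lengths
    return cert


# ---------------------------------------------------------------------------
# Phase 3: sort along the witness cycle
# ---------------------------------------------------------------------------

def _cycle_symbols(N: PhyloNetwork, cycle: list) -> list:
    """Symbol per cycle position: taxon for leaf-adjacent vertices, and
    ``("chord", k, end)`` for chord endpoints, chords numbered by first
    appearance along the traversal."""
    in_cycle = set(cycle)
    consec = set()
    m = len(cycle)
    for p in range(m):
        consec.add(frozenset((cycle[p], cycle[(p + 1) % m])))
    symbols = []
    chord_id: dict[frozenset, int] = {}
    for v in cycle:
        others = [u for u in N.graph.neighbors(v)
                  if frozenset((u, v)) not in consec]
        if len(others) != 1:
            raise ValueError("vertex off the witness cycle structure")
        u = others[0]
        if u not in in_cycle:  # pendant leaf
            symbols.append(("leaf", N.label_of(u)))
        else:
            key = frozenset((u, v))
            if key not in chord_id:
                chord_id[key] = len(chord_id) + 1
                symbols.append(("chord", chord_id[key], 0))
            else:
                symbols.append(("chord", chord_id[key], 1))
    return symbols


def _inversions(seq: list, rank: dict) -> int:
    r = [rank[s] for s in seq]
    return sum(1 for a in range(len(r)) for b in range(a + 1, len(r)) if r[a] > r[b])


def _target_arrangements(Np: PhyloNetwork, cycle: list, n_chords: int):
    """All candidate target symbol sequences over rotations, reflections,
    chord renumberings and per-chord end swaps."""
    import itertools
    m = len(cycle)
    for direction in (1, -1):
        ordered = cycle if direction == 1 else list(reversed(cycle))
        for rot in range(m):
            arrangement = ordered[rot:] + ordered[:rot]
            base = _cycle_symbols(Np, arrangement)
            for perm in itertools.permutations(range(1, n_chords + 1)):
                for mask in range(1 << n_chords):
                    seq = []
                    for s in base:
                        if s[0] == "chord":
                            k = perm[s[1] - 1]
                            e = s[2] ^ ((mask >> (s[1] - 1)) & 1)
                            seq.append(("chord", k, e))
                        else:
                            seq.append(s)
                    yield seq


def sort_cycle(N: PhyloNetwork, Np: PhyloNetwork,
               witness: list | None = None,
               witness_target: list | None = None) -> PathCertificate:
    """NNI path between two pseudo-Hamiltonian tier-``i`` networks.

    Labels the witness-cycle vertices of both networks (taxa at leaf
    positions, paired labels at chord endpoints), picks the target reading --
    over rotations, reflections, chord renumberings and per-chord end swaps
    -- minimizing the adjacent-transposition distance, and realizes each
    swap as an NNI on the corresponding length-3 subpath.  At most
    ``C(n - l, 2)`` swaps are needed (the symmetric-group diameter).  A swap
    blocked by a chord triggers an exact BFS fallback (logged).
    """
    if N.taxa != Np.taxa or N.tier() != Np.tier():
        raise ValueError("need two networks on the same taxa in the same tier")
    if N.canonical_key() == Np.canonical_key():
        return PathCertificate(N, Np, [], {"sorted_endpoint": N})
    for name, G, wit in (("source", N, witness), ("target", Np, witness_target)):
        if wit is None:
            ok, wit = is_pseudo_hamiltonian(G, return_witness=True)
            if not ok:
                raise ValueError(f"{name} network is not pseudo-Hamiltonian")
        if name == "source":
            witness = wit
        else:
            witness_target = wit

    n_chords = N.tier() - 1
    src_symbols = _cycle_symbols(N, witness)
    best = None
    for seq in _target_arrangements(Np, witness_target, n_chords):
        rank = {s: p for p, s in enumerate(seq)}
        if set(rank) != set(src_symbols):
            continue
        inv = _inversions(src_symbols, rank)
        if best is None or inv < best[0]:
            best = (inv, rank)
    if best is None:
        raise AssertionError("no consistent target cycle labelling found")
    _, rank = best

    cur = N
    order = list(witness)
    symbol_of = dict(zip(witness, src_symbols))
    moves: list[Move] = []
    m = len(order)

    def ranks():
        return [rank[symbol_of[v]] for v in order]

    while True:
        r = ranks()
        if all(r[p] < r[p + 1] for p in range(m - 1)):
            break
        done_swap = False
        for p in range(m - 1):
            if r[p] > r[p + 1]:
                x, y = order[p], order[p + 1]
                prev = order[(p - 1) % m]
                nxt = order[(p + 2) % m]
                try:
                    nxt_cur = nni_apply(cur, (prev, x, y, nxt))
                except IllegalMoveError:
                    continue
                cur = nxt_cur
                moves.append(Move(NNI, (prev, x, y, nxt), phase=PHASE_SORT))
                order[p], order[p + 1] = y, x
                done_swap = True
                break
        if not done_swap:
            logger.warning("sort_cycle: all useful swaps blocked; BFS fallback")
            return _bfs_fallback(N, Np, moves_so_far=moves, reached=cur)

    if cur.canonical_key() != Np.canonical_key():
        logger.warning("sort_cycle: sorted arrangement mismatch; BFS fallback")
        return _bfs_fallback(N, Np, moves_so_far=moves, reached=cur)
    cert = PathCertificate(N, Np, moves)
    cert.meta["sorted_endpoint"] = cur
    return cert


def _bfs_fallback(N: PhyloNetwork, Np: PhyloNetwork,
                  moves_so_far: list[Move], reached: PhyloNetwork) -> PathCertificate:
    from .explore import bfs_path_moves
    steps = bfs_path_moves(reached, Np, op="nni")
    moves = list(moves_so_far)
    cur = reached
    for anchor, M in steps:
        moves.append(Move(NNI, anchor, phase=PHASE_BFS))
        cur = M
    cert = PathCertificate(N, Np, moves)
    cert.meta["sorted_endpoint"] = cur
    cert.meta["bfs_fallback"] = True
    return cert


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _isomorphism_map(A: PhyloNetwork, B: PhyloNetwork) -> dict:
    """An explicit label-fixing isomorphism ``V(A) -> V(B)`` (keys must agree)."""
    la = A.canonical_labeling()
    lb = B.canonical_labeling()
    inv_b = {pos: v for v, pos in lb.items()}
    return {v: inv_b[pos] for v, pos in la.items()}


def _map_anchor(anchor, phi):
    return tuple(_map_anchor(a, phi) if isinstance(a, tuple) else phi[a]
                 for a in anchor)


def connect_same_tier(N: PhyloNetwork, Np: PhyloNetwork) -> PathCertificate:
    """Certified NNI path between two networks of the same tier on one taxon set.

    For tier ``i >= 1`` composes simplify + hamiltonize on both sides with the
    cycle sort, reversing the target-side moves; total length is at most
    ``3n + C(n/2 + i - 1, 2) - 2``.  Tier 0 (tree space) is handled by exact
    BFS, tagged ``bfs-fallback``.
    """
    if N.taxa != Np.taxa:
        raise ValueError("networks must share the taxon set")
    if N.tier() != Np.tier():
        raise ValueError("networks must be in the same tier")
    empty_budget = dict.fromkeys(
        ("simplify_source", "hamiltonize_source",
         "simplify_target", "hamiltonize_target", "sort"), 0)
    if N.canonical_key() == Np.canonical_key():
        return PathCertificate(N, Np, [], {"bfs_fallback": False,
                                           "per_side": empty_budget})
    if N.tier() == 0:
        cert = _bfs_fallback(N, Np, [], N)
        cert.meta["per_side"] = empty_budget
        return cert

    simp_s = make_simple(N)
    ham_s = make_pseudo_hamiltonian(simp_s.target)
    simp_t = make_simple(Np)
    ham_t = make_pseudo_hamiltonian(simp_t.target)

    sort = sort_cycle(ham_s.target, ham_t.target,
                      witness=ham_s.meta["witness"],
                      witness_target=ham_t.meta["witness"])
    endpoint = sort.meta["sorted_endpoint"]

    # reverse the target-side moves, transported through an explicit
    # isomorphism from the target's pseudo-Hamiltonian form to the sort
    # endpoint (all target-side moves are NNIs, so vertex ids persist)
    phi = _isomorphism_map(ham_t.target, endpoint)
    moves = list(simp_s.moves) + list(ham_s.moves) + list(sort.moves)
    cur = endpoint
    for mv in reversed(simp_t.moves + ham_t.moves):
        inv = nni_inverse(mv)
        mapped = Move(NNI, _map_anchor(inv.anchor, phi), phase=inv.phase)
        cur = nni_apply(cur, mapped.anchor)
        moves.append(mapped)
    cert = PathCertificate(N, Np, moves)
    cert.meta["bfs_fallback"] = sort.meta.get("bfs_fallback", False)
    cert.meta["per_side"] = {
        "simplify_source": len(simp_s.moves),
        "hamiltonize_source": len(ham_s.moves),
        "simplify_target": len(simp_t.moves),
        "hamiltonize_target": len(ham_t.moves),
        "sort": len(sort.moves),
    }
    if cur.canonical_key() != Np.canonical_key():
        raise AssertionError("composed certificate does not reach the target")
    bound = 3 * N.n + math.comb(N.n // 2 + N.tier() - 1, 2) - 2
    if len(moves) > bound and not cert.meta["bfs_fallback"]:
        raise AssertionError(f"certificate length {len(moves)} exceeds bound {bound}")
    return cert


def connect_any(N: PhyloNetwork, Np: PhyloNetwork) -> PathCertificate:
    """Certified NNI+triangle path between networks in any tiers ``i <= j``.

    Performs ``j - i`` triangle blow-ups on the lower-tier network, then a
    same-tier path; total length at most
    ``6l + 7j - i - 8 + C(l + 2j - 2, 2)``.
    """
    if N.taxa != Np.taxa:
        raise ValueError("networks must share the taxon set")
    if N.tier() > Np.tier():
        return _reverse_certificate(connect_any(Np, N))
    moves: list[Move] = []
    cur = N
    while cur.tier() < Np.tier():
        v = sorted(cur.internal_vertices(), key=str)[0]
        moves.append(Move(TRIANGLE_BLOWUP, (v,), phase=PHASE_TIER_SHIFT))
        cur = triangle_blowup(cur, v)
    inner = connect_same_tier(cur, Np)
    cert = PathCertificate(N, Np, moves + inner.moves, dict(inner.meta))
    return cert


def _reverse_certificate(cert: PathCertificate) -> PathCertificate:
    """Reverse a certificate whose moves are NNIs and triangle blow-ups.

    Replays the forward moves to recover every intermediate network, then
    inverts them back-to-front; each inverted anchor is transported through a
    freshly computed isomorphism between the forward intermediate and the
    network reached so far (triangle moves change the vertex set, so a single
    fixed map would not stay valid).
    """
    states = [cert.source]
    for mv in cert.moves:
        states.append(apply_move(states[-1], mv))
    moves: list[Move] = []
    cur = cert.target
    for idx in range(len(cert.moves) - 1, -1, -1):
        mv, before, after = cert.moves[idx], states[idx], states[idx + 1]
        psi = _isomorphism_map(after, cur)
        if mv.kind == NNI:
            inv = nni_inverse(mv)
            mapped = Move(NNI, _map_anchor(inv.anchor, psi), phase=inv.phase)
        elif mv.kind == TRIANGLE_BLOWUP:
            created = tuple(before.fresh_ids(3))
            mapped = Move(TRIANGLE_COLLAPSE, _map_anchor(created, psi),
                          phase=PHASE_TIER_SHIFT)
        else:
            raise ValueError(f"cannot reverse move kind {mv.kind!r}")
        cur = apply_move(cur, mapped)
        moves.append(mapped)
    out = PathCertificate(cert.target, cert.source, moves, dict(cert.meta))
    if cur.canonical_key() != cert.source.canonical_key():
        raise AssertionError("reversed certificate does not reach the source")
    return out
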