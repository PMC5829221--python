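"""The echidna family of pseudo-Hamiltonian networks.

An echidna graph ``G(S, pi)`` is built from a sequence ``S`` of length
``p + q`` over the symbols ``a1..ap`` plus ``q`` zeros (beginning with ``a1``
and ending with ``ap``) and a permutation ``pi`` of ``{1..q}``:

1. draw a circle with ``p + q`` vertices labelled clockwise by the entries of
   ``S`` (these are the "top" vertices);
2. attach leaf ``j`` to the vertex labelled ``a_j``;
3. subdivide the closing edge ``{S[1], S[p+q]}`` by ``q`` "bottom" vertices,
   numbered anticlockwise from ``S[1]``;
4. draw a chord from the m-th zero vertex (in sequence order) to bottom
   vertex ``pi(m)``.

For a network with ``l`` leaves in tier ``i`` this uses ``p = l`` and
``q = i - 1``.  Distinct sequences with the identity permutation yield
pairwise non-isomorphic networks, so the family size ``(p + q - 2)!/q!``
is a lower bound on the number of tier-``i`` networks on ``l`` leaves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .core_network import PhyloNetwork


@dataclass(frozen=True)
class EchidnaSpec:
    """Blueprint for an echidna graph: a sequence plus a chord permutation.

    ``sequence`` uses integers: ``j > 0`` stands for the symbol ``a_j`` and
    ``0`` for a zero (chord) position.  ``pi`` maps chord index ``m`` (1-based,
    in sequence order of the zeros) to the bottom vertex index (1-based,
    anticlockwise from ``S[1]``); it defaults to the identity.
    """

    sequence: tuple[int, ...]
    pi: tuple[int, ...] = ()

    def __post_init__(self):
        seq = self.sequence
        p = sum(1 for s in seq if s != 0)
        q = len(seq) - p
        if p < 3:
            raise ValueError(f"need at least 3 leaf symbols, got {p}")
        if sorted(s for s in seq if s != 0) != list(range(1, p + 1)):
            raise ValueError("sequence must contain each of a1..ap exactly once")
        if seq[0] != 1 or seq[-1] != p:
            raise ValueError("sequence must begin with a1 and end with ap")
        pi = self.pi if self.pi else tuple(range(1, q + 1))
        if sorted(pi) != list(range(1, q + 1)):
            raise ValueError(f"pi must be a permutation of 1..{q}")
        object.__setattr__(self, "pi", pi)

    @property
    def p(self) -> int:
        """Number of leaf symbols (= number of leaves)."""
        return sum(1 for s in self.sequence if s != 0)

    @property
    def q(self) -> int:
        """Number of zeros (= tier - 1 = number of chords)."""
        return len(self.sequence) - self.p

    @property
    def tier(self) -> int:
        return self.q + 1


def sequence_count(p: int, q: int) -> int:
    """``|S(p, q)| = (p + q - 2)! / q!`` (with the 0! = 1 convention)."""
    if p < 1 or q < 0:
        raise ValueError("need p >= 1, q >= 0")
    return math.factorial(p + q - 2) // math.factorial(q) if p + q >= 2 else 1


def enumerate_sequences(p: int, q: int) -> list[EchidnaSpec]:
    """All sequences in ``S(p, q)``, as identity-permutation specs.

    The count equals ``(p + q - 2)!/q!``: the interior of the sequence is any
    arrangement of ``a2..a_{p-1}`` and ``q`` indistinct zeros.
    """
    if p < 3:
        raise ValueError(f"building specs needs p >= 3, got {p}")
    interior = list(range(2, p)) + [0] * q
    seen = set()
    out = []
    for perm in itertools.permutations(interior):
        if perm in seen:
            continue
        seen.add(perm)
        out.append(EchidnaSpec((1,) + perm + (p,)))
    return out


def build_echidna(spec: EchidnaSpec) -> tuple[PhyloNetwork, list]:
    """Construct ``G(S, pi)`` and return it with its construction-circle witness.

    The witness is the cycle through all internal vertices (top vertices
    clockwise, then bottom vertices back), certifying pseudo-Hamiltonicity.
    """
    seq = spec.sequence
    p, q = spec.p, spec.q
    top = list(range(len(seq)))          # top vertex k holds S[k+1]
    bottom = list(range(len(seq), len(seq) + q))
    leaf_start = len(seq) + q
    edges = []
    # the circle: top vertices clockwise ...
    for k in range(len(top) - 1):
        edges.append((top[k], top[k + 1]))
    # ... closed through the bottom subdivision vertices, anticlockwise from
    # S[1]: bottom[0] is adjacent to top[0]
    arc = [top[0]] + bottom + [top[-1]]
    for k in range(len(arc) - 1):
        edges.append((arc[k], arc[k + 1]))
    # pendant leaves
    labels = {}
    leaf_id = leaf_start
    for k, s in enumerate(seq):
        if s != 0:
            edges.append((top[k], leaf_id))
            labels[str(s)] = leaf_id
            leaf_id += 1
    # chords: m-th zero (sequence order) to bottom vertex pi(m)
    zero_positions = [k for k, s in enumerate(seq) if s == 0]
    for m, k in enumerate(zero_positions, start=1):
        edges.append((top[k], bottom[spec.pi[m - 1] - 1]))
    net = PhyloNetwork(edges, labels)
    witness = top + list(reversed(bottom))
    return net, witness


def echidna_family(ell: int, i: int):
    """Iterate ``G(S, pi0)`` over all ``S`` in ``S(ell, i - 1)``.

    Yields ``(spec, network)`` pairs; the ``(ell + i - 3)!/(i - 1)!`` networks
    are pairwise non-isomorphic.
    """
    if ell < 3 or i < 1:
        raise ValueError("need ell >= 3 and i >= 1")
    for spec in enumerate_sequences(ell, i - 1):
        net, _ = build_echidna(spec)
        yield spec, net


def parse_sequence(text: str) -> EchidnaSpec:
    """Parse a textual sequence like ``"a1,a5,0,a2,0,0,a4,a3,0,a6"``."""
    items = []
    for tok in text.split(","):
        tok = tok.strip()
        if tok == "0":
            items.append(0)
        elif tok.startswith("a"):
            items.append(int(tok[1:]))
        else:
            raise ValueError(f"bad sequence token {tok!r}")
    return EchidnaSpec(tuple(items))
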