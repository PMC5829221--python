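# Methods

This note documents the model, the algorithmic and numerical choices, and
the limitations of `phylospace`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is taken
on faith.

## The objects

A network on taxa `X` (`|X| = l >= 3`) is a connected simple graph with all
degrees in {1, 3} and degree-1 vertices bijectively labelled by `X`.  The
degree constraints force `n = 2(l + i - 1)` and `|E| = 2l - 3 + 3i` where
`i = |E| - |V| + 1 >= 0` is the cyclomatic number; `i` is called the tier
(or reticulation number), and tier `i` on `X` is denoted `N_i(X)`.  A
*cut-edge* is trivial if one side of its removal is a single vertex; a
*blob* is a maximal 2-edge-connected subgraph that is not a vertex.  A
network is *simple* if every cut-edge is trivial, and *pseudo-Hamiltonian*
if a cycle passes through every non-leaf vertex (which implies simple).

One degenerate point worth recording: the 3-leaf star is simple under this
definition (every edge is pendant), even though trees with `l >= 4` never
are.  The tests treat the star as the exception it is.

## Identity: canonical form

Vertex ids are opaque; two networks are "the same" exactly when a graph
isomorphism fixing every leaf label exists.  `canonical_key` colors each
leaf by its taxon and all internal vertices alike, refines the ordered
partition to equitability (1-dimensional Weisfeiler–Leman with cell order),
and individualizes vertices of the first non-singleton cell recursively,
taking the lexicographically least edge relabelling over all branches.
Leaf labels break most symmetry, so the search is near-linear in practice
at the package's scales (n ≲ 20).  The test suite cross-checks the key
against a brute-force oracle that tries every label-fixing vertex bijection
on spaces with up to 10 vertices.

## Operations

All moves validate their preconditions and return a fresh, fully validated
network; anything that would create a loop or parallel edge is rejected as
illegal, never repaired.  Fresh vertices (blow-ups, subdivision points) get
deterministic ids so recorded move sequences replay exactly.

Two definitional choices were genuinely open and are resolved as follows.

- **SPR with a leaf endpoint.**  The SPR definition fixes only the detached
  end `v` at degree 3.  We allow the retained end `w` to be a leaf whenever
  the result is valid: such moves relocate a leaf and are the natural
  network analogue of pendant-subtree SPR on trees.

- **TBR on pendant edges and triangle corners.**  Read literally — both
  ends of the bisected edge of degree 3, and the two merged edges required
  absent beforehand — TBR cannot move leaves at all.  Computationally this
  breaks the expected structure at the smallest sizes: quartet trees then
  have *no* effective TBR move, tier-0 TBR space is disconnected, and the
  containment NNI ⊆ SPR ⊆ TBR fails.  Since these operations are meant to
  generalize their tree-space namesakes (which do bisect pendant edges),
  the package implements the coherent reading: (a) bisecting a pendant edge
  isolates its leaf, which is reattached to a single subdivision vertex
  (coinciding with the leaf SPR); (b) suppressing an endpoint may
  transiently duplicate an edge (a multigraph intermediate), provided the
  reconnection subdivides one copy so the final network is simple.  With
  this reading the containment chain, tier connectivity under all three
  operations, and `d_SPR <= 2 d_TBR` all verify exhaustively on every
  enumerated space (tiers 0–2, 3–5 leaves).

## Echidna graphs

`G(S, pi)` is built from a sequence `S` of length `p + q` over `a1..ap`
plus `q` zeros (endpoints `a1`, `ap`) and a permutation `pi` of `{1..q}`:
a cycle of `p + q` "top" vertices labelled by `S` in clockwise order, a
pendant leaf at each symbol position, `q` "bottom" vertices subdividing the
closing arc (numbered anticlockwise from `S[1]`), and chord `m` joining the
`m`-th zero (in sequence order) to bottom vertex `pi(m)`.  For `p = l`,
`q = i - 1` this is a tier-`i` network on `l` leaves whose construction
circle witnesses pseudo-Hamiltonicity.  Distinct sequences with `pi = id`
give pairwise non-isomorphic graphs — verified exhaustively via canonical
keys for `(l, i)` in {(3,1), (3,2), (4,1), (4,2), (5,1), (4,3)} — so
`|S(p, q)| = (p+q-2)!/q!` lower-bounds `|N_i(X)|`.  Counting over general
`pi` is out of scope (it is an open combinatorial question); general `pi`
is still supported in construction.

## Constructive paths

`connect_same_tier` builds an explicit NNI path between two tier-`i`
networks (`i >= 1`) in three certified phases.

1. **Simplify** (≤ `l + i - 3` moves per side).  While a non-trivial
   cut-edge `{a, b}` exists, an NNI across it (`u, a, b, w` with `u`, `w`
   neighbors on either side) merges it into the adjacent blob.  Such a move
   is always legal (no edge can bridge the cut except `{a, b}` itself);
   among the ≤ 8 endpoint choices we take the first minimizing the
   remaining non-trivial count, which the certificate asserts drops every
   step.  The bound is the maximum possible number of non-trivial
   cut-edges.

2. **Pseudo-Hamiltonize** (≤ `n` moves per side).  Recompute a
   maximum-length cycle `C` of the internal subgraph by exhaustive
   backtracking; while `C` misses an internal vertex `v` adjacent to some
   `w` on `C`, the NNI `w1, w, v, v1` (with `w1` a cycle neighbor of `w`
   and `v1` any other neighbor of `v`) splices `v` into the cycle.
   Maximality guarantees legality, and simplicity is preserved (asserted).
   Because the cycle is recomputed, its length can occasionally jump by
   more than one; the certificate records the lengths and asserts strict
   growth.

3. **Sort** (≤ `C(n - l, 2)` moves).  Both endpoints now carry witness
   cycles of length `n - l`.  Cycle vertices are labelled — taxa at
   leaf-adjacent positions, paired labels at the `i - 1` chord endpoints
   (numbered by first appearance) — and the target's reading is chosen over
   all rotations, reflections, chord renumberings and per-chord endpoint
   swaps to minimize the adjacent-transposition distance.  Each swap is an
   NNI on a length-3 subpath of the cycle; a swap can be blocked when a
   chord joins nearby cycle vertices (the NNI preconditions fail), in which
   case the remainder falls back to an exact BFS in the tier, tagged
   `bfs-fallback` and logged.  Across the seeded fixtures used by the test
   suite (100+ random pairs in tiers 1–2 on 4–5 leaves) the fallback never
   triggered, but it is load-bearing for correctness, not an error path.

The composed certificate (source phases, sort, reversed target phases
transported through an explicit isomorphism) is asserted to replay to the
target and to respect `3n + C(n/2 + i - 1, 2) - 2` in total.  Tier 0 is
served by exact BFS instead: the constructive argument needs a blob, and
near-linear tree-space path algorithms are out of scope.  Cross-tier paths
(`connect_any`) blow up the lower-tier network `j - i` times (at the
str-least internal vertex) and connect within tier `j`, within
`6l + 7j - i - 8 + C(l + 2j - 2, 2)`.

## Enumeration and exact distances

`enumerate_tier` generates every tier-`i` network on `l` taxa directly:
backtracking over simple graphs with degree sequence `(1^l, 3^(n-l))`,
restricted to first-touch normal form on the interchangeable internal
vertices (every isomorphism class is produced at least once; canonical keys
deduplicate).  Because this is independent of the move operations,
verifying that the NNI/SPR/TBR closure of one network equals the enumerated
space is a non-circular connectivity check.  Exact distances and diameters
are breadth-first-search values on the move graph over canonical keys.

Enumerated sizes used throughout: `|N_0| = 1, 3, 15` for `l = 3, 4, 5`
(the `(2l-5)!!` counts), `|N_1| = 1, 9` for `l = 3, 4` (the exact unicyclic
formula), and `|N_2| = 7, 66` for `l = 3, 4` (no closed form; the echidna
bound gives ≥ 2 and ≥ 6).  The default enumeration cap is 12 vertices;
everything the harness verifies stays at or below that, keeping the full
suite under a minute on one CPU.

## Bound conventions and vacuity

All bounds honor `0! = 1` and `log_a(0) = ln 0 = 0` (needed for the
`(i - 1)` terms at tier 1).  The information-theoretic NNI lower bound
`(1/20)[(n-3) log6(n/2-2) - (2i-1) log6(i-1) - (n-2i) log6 e - 2n]` is
negative for all `n` below roughly 200 (the `n log n` term only dominates
once `n/2 - 2 > 36e`); it is reported as-is and flagged vacuous, and
sandwich checks clip it at 0.  The SPR/TBR lower bounds behave the same
way at desk scale.  The tier-0 SPR/TBR bracket of the tree-space
literature is kept in its native `n = |X|` convention, while all `i >= 1`
bounds use `n = |V|`; both are documented on the functions because the two
conventions genuinely coexist in the source material.

## The two-triangle example

Blowing up two distinct vertices of one network gives two networks in the
next tier at full-space distance 2 (collapse one triangle, blow up the
other vertex).  The within-tier distance exceeds 2 only when the two
blown-up vertices are *non-adjacent*: for adjacent vertices — unavoidable
on the 4-leaf tree, whose two hubs are neighbors — the triangle migrates in
two legal NNI moves and the within-tier distance is also exactly 2 (the
two-move path is verified by an independent VF2 oracle in the development
record).  The harness therefore witnesses tier-subspace non-isometry with
the 5-leaf caterpillar (non-adjacent hubs: full-space 2, within-tier 4),
and reports the 4-leaf instance alongside.  One acceptance test asserts the
strict inequality on the 4-leaf instance and is expected to fail; it is
kept deliberately.

## Random fixtures

`random_network` draws a uniform random echidna sequence and applies a
seeded uniform random NNI walk (default length ~8–12 in the suites): tier
connectivity guarantees the walk stays in, and mixes within, the tier.
These fixtures exercise non-simple and non-pseudo-Hamiltonian shapes (walks
readily leave the echidna family) but are *not* samples from any
biologically motivated distribution — passing tests say nothing about
networks reconstructed from sequence data, only about the combinatorics.

## Known limitations

- Exact pseudo-Hamiltonicity, longest-cycle search, canonicalization and
  enumeration are all exponential in the worst case; they are intended for
  `n` ≲ 20 (a warning fires above 40 for the cycle searches, and
  enumeration is capped at 12 vertices by default).
- Shortest rearrangement paths are NP-hard territory; certificates are
  upper bounds (each ≥ the exact BFS distance, verified on enumerable
  spaces), not geodesics.
- Rooted/directed networks, edge lengths, multifurcations and extended
  Newick serialization are out of scope; the native format is a plain
  edge-list because no standard exists for unrooted networks.
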