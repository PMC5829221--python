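# phylospace

Rearrangement operations, echidna graphs and diameter bounds for the space of
unrooted binary phylogenetic networks.

## The problem

Phylogenetic networks generalize phylogenetic trees to represent reticulate
evolution (hybridization, lateral gene transfer) in organisms such as plants
and bacteria.  An *unrooted binary phylogenetic network* on a taxon set `X`
is a connected graph in which every vertex has degree 1 or 3 and whose
degree-1 vertices are bijectively labelled by `X`.  Writing `n = |V|`,
`l = |X|` and `i` for the *tier*, these satisfy `n = 2(l + i - 1)`; the tier
equals the cyclomatic (reticulation) number `|E| - |V| + 1`, so tier 0 is
classical tree space and tier 1 the unicyclic networks.

Network search algorithms walk this space using local rearrangements.  This
package implements the four operations that structure it and everything
needed to study the induced metrics at desk scale:

- **NNI** — replace a path `v1, v2, v3, v4` by `v1, v3, v2, v4`, keeping the
  central edge (legal when neither `{v1,v3}` nor `{v2,v4}` is an edge);
- **triangle operations** — blow up a degree-3 vertex into a 3-cycle
  (tier +1) or collapse a 3-cycle (tier −1);
- **SPR** — detach one end of an edge, suppress the degree-2 vertex, regraft
  onto a subdivision of another edge;
- **TBR** — bisect an edge, suppress both ends, reconnect via subdivisions
  of two edges (bisecting a pendant edge moves its leaf).

Each tier is connected under NNI (and hence under SPR and TBR), giving
metrics `d_NNI >= d_SPR >= d_TBR` with `d_SPR <= 2 d_TBR`.  The package
provides:

- `core_network` — the validated `PhyloNetwork` container, blob/cut-edge
  decomposition, simplicity and pseudo-Hamiltonicity predicates, and a
  leaf-label-respecting canonical form (partition refinement with
  individualization) as the sole notion of network identity;
- `operations` — the four moves with full legality checking, invertibility
  and neighborhood enumeration;
- `echidna` — the echidna family `G(S, pi)`: cycle-with-chords networks built
  from sequences `S` in `S(p, q)`; distinct sequences give pairwise
  non-isomorphic networks, so `|S(l, i-1)| = (l+i-3)!/(i-1)!` lower-bounds
  the tier size;
- `paths` — certified NNI paths between networks of one tier (simplify,
  pseudo-Hamiltonize, sort the witness cycle by adjacent transpositions),
  realizing the diameter upper bound `3n + C(n/2 + i - 1, 2) - 2`, and
  cross-tier paths via triangle operations;
- `bounds` — every closed-form counting/diameter bound (tier counts
  `(2l-5)!!` and the exact unicyclic count, echidna lower bounds, the
  `6^(n+10m)` graph-grammar ball bound, NNI/SPR/TBR diameter brackets);
- `explore` — exhaustive, move-independent enumeration of small tier spaces,
  exact BFS distances/diameters, and a verification harness tying every
  claim to computation;
- `fileio`/`cli` — a plain-text edge-list format (plus GraphML/DOT export),
  seeded random fixtures, and the `phylospace` command-line tool.

## Worked example

```python
>>> from phylospace import enumerate_tier, bounds
>>> sp = enumerate_tier(4, 1)          # all unicyclic networks on 4 taxa
>>> len(sp)
9
>>> sp.diameter("nni"), sp.diameter("spr"), sp.diameter("tbr")
(2, 1, 1)
>>> bounds.nni_diameter_upper(8, 1)    # constructive bound, n = 8
28
```

The enumeration finds exactly 9 networks — matching the closed-form
unicyclic count `(l-1)! 2^(l-2) - (2l-2)!/((l-1)! 2^(l-1)) = 9` for
`l = 4` — and the exact NNI diameter 2 sits inside the `[0, 28]` bracket
(the information-theoretic lower bound is vacuous at this size).  Stronger
operations shrink the diameter to 1.

A certified path between two seeded random tier-2 networks on 5 taxa:

```python
>>> from phylospace.fileio import FixtureSpec, random_network
>>> from phylospace.paths import connect_same_tier
>>> A = random_network(FixtureSpec(5, 2, "random-walk", 8, seed=1))
>>> B = random_network(FixtureSpec(5, 2, "random-walk", 8, seed=2))
>>> cert = connect_same_tier(A, B)
>>> len(cert), cert.phase_counts()
(5, {'simplify': 2, 'sort': 3})
>>> cert.replay().canonical_key() == B.canonical_key()
True
```

Five NNI moves (two eliminating non-trivial cut-edges, three sorting the
witness cycle) transform `A` into `B`, well under the `3n + C(n/2+i-1, 2)
- 2 = 49` bound for `n = 12`.

The same functionality is available from the shell:

```sh
phylospace enumerate --leaves 4 --tier 1      # count: 9
phylospace diameter --leaves 4 --tier 1       # diameter: 2
phylospace bounds --leaves 4 --tier 1 --json
phylospace verify                              # the full desk-scale harness
```

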