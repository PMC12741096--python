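# Methods

## The pedigree graph

Trio records (individual, father, mother, optional sex and attributes) are
validated on ingest: IDs are coerced to strings, any ID matching a
configurable missing code (default `NA`, empty, `0`) becomes a missing
parent, duplicate individual IDs, self-parentage and identical
father/mother are rejected. Parents referenced without a row of their own
are legal and become founder nodes — registers routinely truncate
ascending lineages.

The graph is mixed. Parental edges are directed parent → child and tagged
`father`/`mother`. Full-sibling edges are undirected, stored once per
unordered pair, and exist exactly between individuals who share the same
non-missing father **and** mother, so each full sibship forms a clique
(`k·(k−1)/2` edges). Individuals with no parents, children or siblings are
kept as isolated nodes. All neighbourhood and distance computations ignore
edge direction — descendants must be found as readily as ancestors — and
count a sibling edge as one step. Cyclic parentage is a hard error (one
cycle is reported), because every downstream algorithm assumes
ancestor relations are well-founded. Monozygotic twins get no special
treatment: zygosity is not modelled.

The graph container, cycle detection and breadth-first searches are
delegated to networkx; tables to pandas; the sparse kinship storage to
scipy.

## Family extraction

The degree-*n* family of a proband is the set of nodes within shortest-path
distance *n* in the mixed graph. With the sibling shortcut this distance
coincides with the classical degree of relatedness for blood relatives on
loop-free pedigrees (parent 1, grandparent/half-sib/avuncular 2, first
cousin/great-grandparent 3, …). Neighbourhood membership is purely
distance-based, so affines (a child's co-parent, at undirected distance 2)
are included; they receive kinship 0 and the label `Unrelated`, and a
`blood_only` option drops them. Only the minimal distance is kept; no path
enumeration is stored.

## Kinship by path counting

`k(i,j) = C · 0.5^d` with `d` the length of the shortest genealogically
valid path: ascend, cross at most one full-sibling edge at the apex,
descend (`up* [sib] down*`). Equivalently

```
d = min(  min over common ancestors a of  u_i(a) + u_j(a),
          min over sibling edges {s,t}, s anc-or-self of i,
                                  t anc-or-self of j  of  u_i(s) + 1 + u_j(t) )
```

where `u_x(·)` is the child→parent step count. The raw undirected distance
is *not* used: it would assign spurious kinship 0.25 to co-parents via the
descend-then-ascend path through their child. Per individual an
ancestor-distance map is built by upward BFS; pair distances come from an
inverted ancestor→descendants index plus sibling-edge bridging, so fully
unrelated pairs cost nothing and the output is independent of traversal
order. `NO_PATH` is encoded as infinity (so `0.5**d` is arithmetically 0)
and as a structural zero in sparse output.

Properties, both tested: on loop-free pedigrees (no pair related through
two distinct ancestral couples) `0.5^d = 2φ` exactly, with `φ` the
classical recursive kinship coefficient; under loops the estimator is a
lower bound (double first cousins: path 0.125 vs `2φ` 0.25). No inbreeding
adjustment is applied anywhere — the diagonal is always `C`. `C` is a
scalar broadcast (default 1, e.g. a heritability); per-pair constants are
out of scope. For a family subgraph, distances are computed within the
subgraph as provided: if the subgraph truncates the only connecting
ancestor of a pair, that pair is unrelated in the subgraph's matrix.

## Relation labelling

Every MRCA configuration between proband and member is enumerated: one per
common ancestor (`(u, v)`, half when collateral) and one per full-sibling
bridge (`(u_s+1, v_t+1)`, full). A configuration via a single common
ancestor with both `u, v ≥ 1` is a *half* relation except when the pair
shares both parents at the apex. The implied degree is `up + down − 1` for
full collateral relations (the sibling bridge saves a step) and
`up + down` otherwise. The configuration with minimal degree is selected;
ties are broken toward the more horizontal relation (larger
`min(up, down)`), then deterministically by smaller `up` and full before
half. The horizontal tie-break is the simplest formalisation of favouring
collateral over lineal readings; it is a design choice of this package.

Codes: lineal chains `Pa/GPa/G^k GPa` and `Ch/GCh/G^k GCh`; `(1,1)`
`Sib`/`HSib`; pibling chain `(u,1)` `Pib/GPib/G^k GPib`; nibling chain
`(1,v)` `Nib/GNib/G^k GNib`; cousins `(u,v≥2)` `{order}C[{removal}R]` with
order `min(u,v)−1`, removal `|u−v|`; `H` prefix for half collateral
relations. Cousin codes are symmetric in up/down by construction (`1C2R`
covers both once-directions of the removal). Labelling is bounded: ascent
on the proband side is capped at 6 generations (up to the
great-great-great-great-grandparents) and no relation past degree 9 is
labelled; configurations beyond either bound fall into a `Distant` bucket,
and members with no configuration are `Unrelated`. The code set beyond the
conventional anchors is this package's own documented taxonomy. Sexed
prose (father/aunt/grandson…) appears only in the description field when a
sex attribute is present; codes stay sex-neutral.

## Trio reconstruction

`graph_to_trio` assigns father/mother from the `sex` attribute of each
parent node (`male`/`female`), so reconstructed tables work with external
pedigree tools that require sexed trios. An unsexed parent is an error by
default — silent data loss is worse than a loud failure — or is dropped
with `on_ambiguity="set_missing"`; two same-sex parents of one child are
always an error. Sibling edges are ignored (derivable). On tables whose
parents all carry sex, `graph_to_trio(prepare_graph(T))` is the identity
up to row order.

## Synthetic pedigrees

The generator is a generation-structured branching process: founder
couples; sibship sizes drawn from a zero-truncated Poisson (default mean
2.5); with probability `half_sib_rate` (default 0.1) one parent re-partners
once with a new unrelated immigrant, producing a half sibship. Mating is
either fully exogamous (`loop_free=True`: every child pairs with a fresh
immigrant, which guarantees no pair is related through two distinct
ancestral couples — the precondition of the classical-oracle equivalence)
or endogamous within a generation (random male–female pairing across
sibships, leftovers matched to immigrants), which can create loops.
Everything is driven by one seed; identical configurations yield identical
tables, and IDs encode generation and origin (`g2i7`, `g1f3`) for
debuggability.

The generator emulates the *structure* of register trio data — truncated
lineages, variable sibships, half-sibs, isolated immigrants — and none of
its demography: no ages, no mortality, no assortative mating, no
sex-ratio or fertility trends. Passing tests therefore establish graph
correctness and estimator algebra, not calibration to any human
population.

The canonical fixtures (nuclear, half-sib, a 16-person four-generation
family, double first cousins, isolated individuals) ship with sidecar
tables of hand-verified (pair, distance, kinship, label) expectations used
across the test suites.

## Problem sizes and numerics

The register-scale run in `scripts/acceptance.py` and the corresponding
test uses 2000 founder couples, 3 generations, sibship mean 2.2, half-sib
rate 0.1 and endogamous mating, giving roughly 28,000 individuals — the
scale of a mid-sized register extract — from which 500 random probands get
degree-3 families and per-family sparse kinship matrices; the whole run
takes seconds on one CPU. Oracle-equivalence tests use 50 seeded loop-free
pedigrees of up to ~170 individuals and assert agreement to 1e-12 (the
quantities are dyadic rationals, so the only tolerance needed is for
float summation order). Summary means are rounded to 3 decimals in
rendered output only. SVG figures are rendered with a fixed hash salt and
no date metadata, so identical summaries produce byte-identical files.

## Known limitations

- Not inbreeding-aware: kinship under loops is a lower bound; the diagonal
  ignores inbreeding. Convert families back to trios and use an
  inbreeding-aware calculator when consanguinity matters.
- Twin zygosity is not modelled.
- No affinal or step-relation labels; no composite labels (e.g. "double
  first cousin" is labelled `1C`).
- Label codes beyond the conventional anchors are this package's own
  taxonomy; other tools may spell them differently.
- Family-subgraph kinship uses subgraph-internal distances (see above);
  compute on the population graph when truncation is a concern.
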