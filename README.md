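# pedigraph

Family-based genetic studies — family-history indicators, family liability
models, mixed models with relatedness structure — need the relatives of each
study individual up to some degree *n*, together with the kinship among them.
In biobanks and population registers, pedigree information arrives as **trio
data**: one row per individual with their own ID and the IDs of their father
and mother. `pedigraph` turns population-level trio tables into a mixed
pedigree graph and answers the downstream questions directly:

- **build** a graph with directed, role-tagged parental edges
  (parent → child) plus one undirected shortcut edge per full-sibling pair,
  keeping individuals without relatives as isolated nodes and attaching
  arbitrary per-individual attributes;
- **extract**, for any list of probands, every family member within degree
  *n* (ancestors *and* descendants, in one call);
- compute the **kinship-by-path-counting** matrix over any (sub)graph;
- **reconstruct trio tables** from graphs, so identified families can be fed
  to other pedigree software;
- **label** every family member with a standard consanguinity code
  (`Pa`, `HSib`, `Pib`, `1C2R`, …) and **summarise** label totals and
  per-proband means, with an optional chart-style grid figure;
- **simulate** seeded synthetic pedigrees for testing and benchmarking.

## The kinship estimator

For individuals *i*, *j* the estimator is

```
k(i, j) = C · 0.5^d(i,j)
```

where `d(i,j)` is the length of the shortest *genealogically valid* path
between them: ascend parental edges, cross at most one full-sibling edge at
the apex, then descend (shape `up* [sib] down*`), i.e. a path through a most
recent common ancestor configuration. Pairs with no such path (e.g.
co-parents) get 0, and the scale constant `C` (default 1) can represent a
heritability. With the full-sibling shortcut, `d` equals the classical degree
of relatedness: parent–child 1, half-sibling/grandparent/avuncular 2, first
cousin 3, and `0.5^d` equals twice the classical kinship coefficient
`2·φ(i,j)` on loop-free pedigrees. The estimator is deliberately **not
inbreeding-aware**: under pedigree loops (e.g. double first cousins,
`0.5^3 = 0.125` vs `2φ = 0.25`) it is a lower bound, and monozygotic twins
are treated as ordinary full siblings.

Relationship labels classify each member by generations up/down to the MRCA:
`(1,0)` parent `Pa`, `(1,1)` sibling `Sib`/`HSib`, `(u,1)` piblings
(parent's siblings) `Pib`, `GPib`, …, `(1,v)` niblings `Nib`, `GNib`, …, and
cousins `{order}C[{removal}R]` with order `min(u,v)−1` and removal `|u−v|`.
Labelling ascends at most 6 generations and stops at degree 9; anything
beyond is bucketed as `Distant`, and neighbours without any MRCA
configuration as `Unrelated`.

## Worked example

```python
import pedigraph as pg

fixtures = pg.canonical_fixtures()
table = fixtures["four_generation"].table       # 16-person family
graph = pg.prepare_graph(table)
print(f"graph: {len(graph)} nodes, {graph.n_parental_edges} parental edges, "
      f"{graph.n_sibling_edges} sibling edges")

fam = pg.get_family_graphs(graph, ["prb"], degree=3)["prb"]
print(f"degree-3 family of prb: {len(fam)} members")

km = pg.get_kinship(fam.graph)
print("kinship(prb, cousin) =", km.value("prb", "cousin"))

rel = pg.get_relations(fam)
print(rel[["member_id", "up", "down", "code", "degree", "description"]]
      .to_string(index=False))
```

prints

```
graph: 16 nodes, 18 parental edges, 3 sibling edges
degree-3 family of prb: 13 members
kinship(prb, cousin) = 0.125
member_id   up down      code degree                    description
      prb    0    0      Self      0                           self
      dad    1    0        Pa      1                         father
      mom    1    0        Pa      1                         mother
      sib    1    1       Sib      1                        brother
     aunt    2    1       Pib      2                           aunt
      gpa    2    0       GPa      2                    grandfather
      gpw    2    0       GPa      2                    grandmother
  halfsib    1    1      HSib      2                    half-sister
   cousin    2    2        1C      3                   first cousin
     gdau    3    1      GPib      3                      grandaunt
      ggf    3    0      GGPa      3              great-grandfather
      ggm    3    0      GGPa      3              great-grandmother
  stepmom <NA> <NA> Unrelated   <NA> unrelated (no common ancestor)
```

Reading the output: the proband's half-sister sits at degree 2 (kinship
0.25), the first cousin at degree 3 (0.125), and `dad`'s stepmother-in-law
— reachable in 3 undirected steps but sharing no ancestor with `prb` — is
flagged `Unrelated` (kinship 0). The first cousin once removed (`cous1r`,
degree 4) is correctly outside this degree-3 family.

The same pipeline is available from the shell:

```
pedigraph simulate --couples 5 --generations 3 --seed 1 --out trios.tsv
pedigraph extract  --trios trios.tsv --probands g3i1,g3i2 --degree 3 --out fam
pedigraph kinship  --trios trios.tsv --family-of g3i1 --degree 3 --out kin.tsv
pedigraph relations --trios trios.tsv --probands g3i1 --degree 3 --out rel.tsv
pedigraph summarize --relations rel.tsv --out summary.tsv --figure grid.svg
```

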