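"""Kinship by path counting: ``0.5 ** d * C``.

``d`` is the length of the shortest *genealogically valid* path between
two individuals: ascend zero or more parental edges, optionally cross one
full-sibling edge at the apex, then descend zero or more parental edges
(shape ``up* [sib] down*``). A path must pass through a most recent common
ancestor configuration; the raw undirected graph distance is NOT used,
because it would assign spurious kinship to affines (e.g. co-parents at
undirected distance 2 via their shared child descend-then-ascend, which is
not a genealogical shape).

On loop-free pedigrees ``0.5**d`` equals twice the classical kinship
coefficient. The estimator is not inbreeding-aware: under pedigree loops
(e.g. double first cousins) it is a lower bound on ``2*phi``, and the
diagonal is always ``C`` regardless of inbreeding.

The constant ``C`` defaults to 1 and may represent, e.g., the heritability
of a phenotype; it rescales the whole matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import UnknownIDError
from .pedigree_graph import PedigreeGraph

#: Sentinel for "no genealogically valid path". Using infinity makes
#: ``0.5 ** NO_PATH == 0.0`` hold arithmetically.
NO_PATH = float("inf")


def ancestor_distances(graph: PedigreeGraph, individual_id: str) -> dict[str, int]:
    """Map ancestor-or-self -> number of child->parent steps (self at 0),
    by upward breadth-first search over the parental edges."""
    if individual_id not in graph:
        raise UnknownIDError(individual_id)
    dist = {individual_id: 0}
    frontier = [individual_id]
    while frontier:
        nxt = []
        for node in frontier:
            for parent in graph.parent_ids(node):
                if parent not in dist:
                    dist[parent] = dist[node] + 1
                    nxt.append(parent)
        frontier = nxt
    return dist


def genealogical_distance(graph: PedigreeGraph, i: str, j: str) -> float:
    """Shortest valid-path length between ``i`` and ``j``; ``NO_PATH`` if
    no common-ancestor or sibling-bridged configuration exists.

    ``d = min( min_a u_i(a) + u_j(a),
               min_{sib {s,t}} u_i(s) + 1 + u_j(t) )``
    over common ancestors ``a`` and full-sibling edges with ``s``
    ancestor-or-self of ``i`` and ``t`` ancestor-or-self of ``j``.
    """
    if i == j:
        if i not in graph:
            raise UnknownIDError(i)
        return 0
    anc_i = ancestor_distances(graph, i)
    anc_j = ancestor_distances(graph, j)
    best = NO_PATH
    for a, ui in anc_i.items():
        uj = anc_j.get(a)
        if uj is not None:
            best = min(best, ui + uj)
    for pair in graph.sibling_edges:
        s, t = tuple(pair)
        for s_, t_ in ((s, t), (t, s)):
            ui, uj = anc_i.get(s_), anc_j.get(t_)
            if ui is not None and uj is not None:
                best = min(best, ui + 1 + uj)
    return best


@dataclass
class KinshipMatrix:
    """Symmetric matrix of ``C * 0.5**d`` over a graph's individuals.

    ``values`` is either a dense ``numpy.ndarray`` or a ``scipy.sparse``
    matrix; pairs with no genealogical path are structural zeros.
    """

    ids: list[str]
    values: np.ndarray | sp.spmatrix
    C: float = 1.0

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def value(self, i: str, j: str) -> float:
        a, b = self.ids.index(i), self.ids.index(j)
        return float(self.values[a, b])

    def to_dense(self) -> pd.DataFrame:
        values = self.values.toarray() if self.is_sparse else self.values
        return pd.DataFrame(values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        """Nonzero upper-triangle entries plus the diagonal as
        (id_1, id_2, kinship) rows."""
        coo = sp.coo_matrix(self.values)
        rows = [
            (self.ids[r], self.ids[c], v)
            for r, c, v in zip(coo.row, coo.col, coo.data)
            if r <= c
        ]
        return pd.DataFrame(rows, columns=["id_1", "id_2", "kinship"])

    def write_dense_csv(self, path: str | Path) -> None:
        self.to_dense().to_csv(path, index_label="id")

    def write_long_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _pair_distances(graph: PedigreeGraph) -> Iterator[tuple[int, int, float]]:
    """Yield (row, col, d) for every related pair (row < col), using an
    inverted ancestor index so unrelated pairs are never touched."""
    ids = graph.nodes
    index = {ind: k for k, ind in enumerate(ids)}
    anc = {ind: ancestor_distances(graph, ind) for ind in ids}

    # invert: ancestor -> [(descendant index, distance)]
    descendants: dict[str, list[tuple[int, int]]] = {}
    for ind, dists in anc.items():
        for a, d in dists.items():
            descendants.setdefault(a, []).append((index[ind], d))

    best: dict[tuple[int, int], float] = {}

    def offer(i: int, j: int, d: float) -> None:
        if i == j:
            return
        key = (i, j) if i < j else (j, i)
        if d < best.get(key, NO_PATH):
            best[key] = d

    for a, descs in descendants.items():
        for x in range(len(descs)):
            i, di = descs[x]
            for y in range(x + 1, len(descs)):
                j, dj = descs[y]
                offer(i, j, di + dj)
    for pair in graph.sibling_edges:
        s, t = tuple(pair)
        for s_, t_ in ((s, t), (t, s)):
            for i, di in descendants.get(s_, ()):
                for j, dj in descendants.get(t_, ()):
                    offer(i, j, di + 1 + dj)
    yield from ((i, j, d) for (i, j), d in best.items())


def get_kinship(
    graph: PedigreeGraph,
    C: float = 1.0,
    output: str = "dense",
) -> KinshipMatrix:
    """Kinship matrix for all individuals present in a (neighbourhood) graph.

    Distances are computed within the provided graph: when a family
    subgraph truncates a connecting ancestor, the corresponding pair is
    unrelated *in that subgraph*.

    Parameters
    ----------
    graph
        Pedigree graph (typically a :class:`~pedigraph.relatives.FamilyGraph`
        subgraph, or any population graph).
    C
        Positive scale constant; diagonal entries equal ``C``.
    output
        ``"dense"`` (ndarray) or ``"sparse_triplets"`` (COO matrix where
        unrelated pairs are structural zeros).
    """
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if output not in ("dense", "sparse_triplets"):
        raise ValueError(f"output must be 'dense' or 'sparse_triplets', got {output!r}")

    ids = graph.nodes
    n = len(ids)
    rows, cols, data = [], [], []
    for k in range(n):
        rows.append(k)
        cols.append(k)
        data.append(C)
    for i, j, d in _pair_distances(graph):
        v = C * 0.5**d
        rows += [i, j]
        cols += [j, i]
        data += [v, v]
    mat = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    if output == "dense":
        return KinshipMatrix(ids, mat.toarray(), C)
    return KinshipMatrix(ids, mat, C)
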