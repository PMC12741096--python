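"""Proband-centred extraction of all relatives within degree *n*.

The degree of a member is its shortest-path distance to the proband in the
mixed pedigree graph, ignoring edge direction and counting full-sibling
edges as one step. With the sibling shortcut in place this distance equals
the classical degree of relatedness for blood relatives on loop-free
pedigrees. Non-blood neighbours reachable within *n* undirected steps
(e.g. the co-parent of a proband's child at distance 2) are included by
default; pass ``blood_only=True`` to drop members that have no
genealogically valid connecting path (kinship zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import UnknownIDError
from .pedigree_graph import PedigreeGraph


@dataclass
class FamilyGraph:
    """A proband-anchored neighbourhood: members with degrees and the
    node-induced subgraph over them (attributes preserved)."""

    proband_id: str
    degrees: dict[str, int]
    graph: PedigreeGraph

    @property
    def members(self) -> set[str]:
        return set(self.degrees)

    def __len__(self) -> int:
        return len(self.degrees)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.degrees


def get_family_graphs(
    graph: PedigreeGraph,
    proband_ids: Iterable[str],
    degree: int,
    blood_only: bool = False,
) -> dict[str, FamilyGraph]:
    """Extract one :class:`FamilyGraph` per proband.

    Probands may appear as members of each other's families. Membership is
    symmetric (``b in family(a, n)`` iff ``a in family(b, n)``) because the
    mixed-graph distance is symmetric.

    Parameters
    ----------
    graph
        Population pedigree graph.
    proband_ids
        Node IDs to centre neighbourhoods on; unknown IDs raise.
    degree
        Maximum distance *n* (positive integer).
    blood_only
        Drop members with no genealogical path to the proband.
    """
    proband_ids = list(proband_ids)
    if degree < 1:
        raise ValueError(f"degree must be a positive integer, got {degree}")
    unknown = [p for p in proband_ids if p not in graph]
    if unknown:
        raise UnknownIDError(unknown)

    undirected = graph.undirected_view()
    families: dict[str, FamilyGraph] = {}
    for proband in proband_ids:
        degrees = dict(
            nx.single_source_shortest_path_length(undirected, proband, cutoff=degree)
        )
        sub = graph.subgraph(degrees)
        if blood_only:
            from .kinship import NO_PATH, genealogical_distance

            degrees = {
                m: d
                for m, d in degrees.items()
                if genealogical_distance(sub, proband, m) is not NO_PATH
            }
            sub = graph.subgraph(degrees)
        families[proband] = FamilyGraph(proband, degrees, sub)
    return families


def membership_table(families: Mapping[str, FamilyGraph]) -> pd.DataFrame:
    """Long-form table of (proband_id, member_id, degree), one row per
    member including the proband itself at degree 0."""
    rows = [
        (fam.proband_id, member, deg)
        for fam in families.values()
        for member, deg in sorted(fam.degrees.items(), key=lambda kv: (kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["proband_id", "member_id", "degree"])
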