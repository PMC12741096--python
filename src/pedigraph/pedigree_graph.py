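"""Population-level pedigree graph: directed parental edges plus
full-sibling shortcut edges.

The graph is "mixed": parent->child edges are directed and role-tagged
(father/mother), while full-sibling edges are undirected and stored once
per unordered pair. Sibling edges exist exactly between individuals who
share the same non-missing father AND mother, so within a full sibship
they form a clique. Distance/neighbourhood computations traverse every
edge in both directions; the full-sibling shortcut is what makes plain
graph distance coincide with the classical degree of relatedness
(parent 1, grandparent/half-sib/avuncular 2, first cousin 3, ...).

Monozygotic twins receive no special treatment: they are full siblings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import CyclicParentageError, UnknownIDError
from .trio_io import MISSING, TrioTable

FATHER = "father"
MOTHER = "mother"

PARENTAL = "parental"
SIBLING = "sibling"


class PedigreeGraph:
    """Mixed pedigree graph over individual IDs.

    Internally two networkx structures share one node set: a ``DiGraph``
    of parental edges (attribute ``role``) and an undirected ``Graph`` of
    full-sibling edges. Node attributes live on the parental graph.
    """

    def __init__(self) -> None:
        self._parental = nx.DiGraph()
        self._siblings = nx.Graph()

    # -- construction ---------------------------------------------------

    def add_individual(self, individual_id: str, **attributes) -> None:
        self._parental.add_node(individual_id, **attributes)
        self._siblings.add_node(individual_id)

    def add_parental_edge(self, parent: str, child: str, role: str | None = None) -> None:
        if role is not None and role not in (FATHER, MOTHER):
            raise ValueError(f"role must be {FATHER!r} or {MOTHER!r}, got {role!r}")
        for node in (parent, child):
            if node not in self._parental:
                self.add_individual(node)
        self._parental.add_edge(parent, child, role=role)

    def add_sibling_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("sibling edge endpoints must differ")
        for node in (a, b):
            if node not in self._parental:
                self.add_individual(node)
        self._siblings.add_edge(a, b)

    def set_attributes(self, individual_id: str, **attributes) -> None:
        if individual_id not in self._parental:
            raise UnknownIDError(individual_id)
        self._parental.nodes[individual_id].update(attributes)

    # -- queries --------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._parental.nodes)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._parental

    def __len__(self) -> int:
        return self._parental.number_of_nodes()

    @property
    def n_parental_edges(self) -> int:
        return self._parental.number_of_edges()

    @property
    def n_sibling_edges(self) -> int:
        return self._siblings.number_of_edges()

    @property
    def n_edges(self) -> int:
        """Total familial edges, counting each sibling pair once."""
        return self.n_parental_edges + self.n_sibling_edges

    def node_attributes(self, individual_id: str) -> Mapping:
        if individual_id not in self._parental:
            raise UnknownIDError(individual_id)
        return self._parental.nodes[individual_id]

    def parent_ids(self, child: str) -> list[str]:
        if child not in self._parental:
            raise UnknownIDError(child)
        return list(self._parental.predecessors(child))

    def parents_of(self, child: str) -> dict[str, str | None]:
        """Role -> parent mapping; roles may be ``None`` on hand-built graphs."""
        return {
            (self._parental.edges[p, child].get("role") or p): p
            for p in self.parent_ids(child)
        }

    def father_of(self, child: str) -> str | None:
        return self._role_parent(child, FATHER)

    def mother_of(self, child: str) -> str | None:
        return self._role_parent(child, MOTHER)

    def _role_parent(self, child: str, role: str) -> str | None:
        for p in self.parent_ids(child):
            if self._parental.edges[p, child].get("role") == role:
                return p
        return None

    def children_of(self, parent: str) -> list[str]:
        if parent not in self._parental:
            raise UnknownIDError(parent)
        return list(self._parental.successors(parent))

    def siblings_of(self, individual_id: str) -> list[str]:
        if individual_id not in self._siblings:
            raise UnknownIDError(individual_id)
        return list(self._siblings.neighbors(individual_id))

    @property
    def parental_edges(self) -> Iterator[tuple[str, str, str | None]]:
        for p, c, data in self._parental.edges(data=True):
            yield p, c, data.get("role")

    @property
    def sibling_edges(self) -> Iterator[frozenset]:
        for a, b in self._siblings.edges:
            yield frozenset((a, b))

    def isolated_nodes(self) -> list[str]:
        return [
            n
            for n in self._parental.nodes
            if self._parental.degree(n) == 0 and self._siblings.degree(n) == 0
        ]

    def undirected_view(self) -> nx.Graph:
        """Flat undirected graph over all edges, for neighbourhood/BFS use.

        Edges carry ``edge_type`` (parental edges additionally keep their
        role); node attributes are shared by reference.
        """
        g = nx.Graph()
        g.add_nodes_from(self._parental.nodes(data=True))
        for p, c, data in self._parental.edges(data=True):
            g.add_edge(p, c, edge_type=PARENTAL, role=data.get("role"))
        for a, b in self._siblings.edges:
            g.add_edge(a, b, edge_type=SIBLING)
        return g

    def subgraph(self, individual_ids: Iterable[str]) -> "PedigreeGraph":
        """Node-induced subgraph; attributes are copied."""
        keep_order = list(individual_ids)
        keep = set(keep_order)
        unknown = keep - set(self._parental.nodes)
        if unknown:
            raise UnknownIDError(unknown)
        sub = PedigreeGraph()
        for node in keep_order:
            sub.add_individual(node, **dict(self._parental.nodes[node]))
        for child in keep_order:
            for p in self._parental.predecessors(child):
                if p in keep:
                    sub.add_parental_edge(p, child, self._parental.edges[p, child].get("role"))
        for a in keep_order:
            for b in self._siblings.neighbors(a):
                if b in keep and a < b:
                    sub.add_sibling_edge(a, b)
        return sub

    def __eq__(self, other) -> bool:
        if not isinstance(other, PedigreeGraph):
            return NotImplemented
        return (
            dict(self._parental.nodes(data=True)) == dict(other._parental.nodes(data=True))
            and set(self.parental_edges) == set(other.parental_edges)
            and set(self.sibling_edges) == set(other.sibling_edges)
        )


def prepare_graph(
    table: TrioTable,
    attributes: Mapping[str, Mapping] | None = None,
) -> PedigreeGraph:
    """Build the population pedigree graph from a trio table.

    Steps: coerce/validate records (done by :class:`TrioTable` ingest), add
    one node per individual plus one per referenced-but-unlisted parent, add
    a role-tagged parental edge per non-missing parent reference, connect
    every full sibship into a clique of sibling edges, keep individuals
    with no relatives as isolated nodes, and attach any extra per-individual
    attributes.

    Parameters
    ----------
    table
        Validated trio records.
    attributes
        Optional mapping ``individual_id -> {name: value}`` merged onto the
        named nodes; IDs not present in the graph produce a warning and are
        skipped.

    Raises
    ------
    CyclicParentageError
        If an individual is their own ancestor.
    """
    graph = PedigreeGraph()
    for rec in table:
        graph.add_individual(rec.individual_id, **rec.attributes)
        if rec.sex is not None:
            graph.set_attributes(rec.individual_id, sex=rec.sex)
    for rec in table:
        if rec.father_id is not MISSING:
            graph.add_parental_edge(rec.father_id, rec.individual_id, FATHER)
        if rec.mother_id is not MISSING:
            graph.add_parental_edge(rec.mother_id, rec.individual_id, MOTHER)

    # full-sibling cliques: identical non-missing father AND mother
    sibships: dict[tuple[str, str], list[str]] = {}
    for rec in table:
        if rec.father_id is not MISSING and rec.mother_id is not MISSING:
            sibships.setdefault((rec.father_id, rec.mother_id), []).append(
                rec.individual_id
            )
    for sibs in sibships.values():
        for a, b in combinations(sibs, 2):
            graph.add_sibling_edge(a, b)

    if not nx.is_directed_acyclic_graph(graph._parental):
        cycle = [edge[0] for edge in nx.find_cycle(graph._parental)]
        raise CyclicParentageError(cycle)

    if attributes:
        unknown = [i for i in attributes if i not in graph]
        if unknown:
            warnings.warn(
                f"attributes provided for {len(unknown)} unknown ID(s), skipped: "
                f"{', '.join(sorted(unknown)[:10])}",
                stacklevel=2,
            )
        for individual_id, attrs in attributes.items():
            if individual_id in graph:
                graph.set_attributes(individual_id, **dict(attrs))
    return graph


@dataclass
class ValidationReport:
    """Result of :func:`validate_graph`; empty iff every invariant holds."""

    cycles: list[list[str]] = field(default_factory=list)
    excess_parents: list[str] = field(default_factory=list)
    spurious_sibling_edges: list[frozenset] = field(default_factory=list)
    missing_sibling_edges: list[frozenset] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not (
            self.cycles
            or self.excess_parents
            or self.spurious_sibling_edges
            or self.missing_sibling_edges
        )

    def __str__(self) -> str:
        if self.is_valid:
            return "graph is valid"
        parts = []
        if self.cycles:
            parts.append(f"{len(self.cycles)} parental cycle(s)")
        if self.excess_parents:
            parts.append(
                f"{len(self.excess_parents)} individual(s) with conflicting parents"
            )
        if self.spurious_sibling_edges:
            parts.append(
                f"{len(self.spurious_sibling_edges)} sibling edge(s) between non-full-siblings"
            )
        if self.missing_sibling_edges:
            parts.append(
                f"{len(self.missing_sibling_edges)} missing full-sibling edge(s)"
            )
        return "invalid graph: " + ", ".join(parts)


def _expected_sibling_pairs(graph: PedigreeGraph) -> set[frozenset]:
    """Recompute the full-sibling relation from the parental edges."""
    sibships: dict[tuple, list[str]] = {}
    for child in graph.nodes:
        father, mother = graph.father_of(child), graph.mother_of(child)
        if father is not None and mother is not None:
            key: tuple = (father, mother)
        else:
            # untagged roles: fall back to the unordered pair when exactly 2
            parents = graph.parent_ids(child)
            if len(parents) != 2:
                continue
            key = (frozenset(parents),)
        sibships.setdefault(key, []).append(child)
    return {
        frozenset((a, b))
        for sibs in sibships.values()
        for a, b in combinations(sibs, 2)
    }


def validate_graph(graph: PedigreeGraph) -> ValidationReport:
    """Check every structural invariant and report violations.

    Reported: directed parental cycles; children with more than one
    father-role or mother-role parent (or more than two parents in all);
    sibling edges that do not correspond to a shared non-missing parent
    pair; full-sibling pairs lacking their edge.
    """
    report = ValidationReport()
    if not nx.is_directed_acyclic_graph(graph._parental):
        report.cycles = [list(c) for c in nx.simple_cycles(graph._parental)]

    for child in graph.nodes:
        parents = graph.parent_ids(child)
        roles = [graph._parental.edges[p, child].get("role") for p in parents]
        if (
            len(parents) > 2
            or roles.count(FATHER) > 1
            or roles.count(MOTHER) > 1
        ):
            report.excess_parents.append(child)

    expected = _expected_sibling_pairs(graph)
    actual = set(graph.sibling_edges)
    report.spurious_sibling_edges = sorted(actual - expected, key=sorted)
    report.missing_sibling_edges = sorted(expected - actual, key=sorted)
    return report


# -- serialization ------------------------------------------------------


def save_graph(graph: PedigreeGraph, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Write edge-list and node-attribute TSVs (lossless with :func:`load_graph`).

    Attribute values are JSON-encoded per cell so that types survive the
    round trip; empty cells mean "attribute absent".
    """
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\tedge_type\trole\n")
        for p, c, role in graph.parental_edges:
            fh.write(f"{p}\t{c}\t{PARENTAL}\t{role or ''}\n")
        for pair in graph.sibling_edges:
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\t{SIBLING}\t\n")

    attr_names: dict[str, None] = {}
    for node in graph.nodes:
        for key in graph.node_attributes(node):
            attr_names.setdefault(key)
    names = list(attr_names)
    with open(nodes_path, "w") as fh:
        fh.write("\t".join(["id"] + names) + "\n")
        for node in graph.nodes:
            attrs = graph.node_attributes(node)
            cells = [json.dumps(attrs[n]) if n in attrs else "" for n in names]
            fh.write("\t".join([node] + cells) + "\n")


def load_graph(edges_path: str | Path, nodes_path: str | Path) -> PedigreeGraph:
    """Inverse of :func:`save_graph`."""
    graph = PedigreeGraph()
    with open(nodes_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[1:]
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            node = cells[0]
            attrs = {
                name: json.loads(cell)
                for name, cell in zip(names, cells[1:])
                if cell != ""
            }
            graph.add_individual(node, **attrs)
    with open(edges_path) as fh:
        fh.readline()
        for line in fh:
            source, target, edge_type, role = line.rstrip("\n").split("\t")
            if edge_type == PARENTAL:
                graph.add_parental_edge(source, target, role or None)
            elif edge_type == SIBLING:
                graph.add_sibling_edge(source, target)
            else:
                raise ValueError(f"unknown edge_type {edge_type!r}")
    return graph
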