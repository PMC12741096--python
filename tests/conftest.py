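"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library's graph machinery: the
classical kinship coefficient is computed by the textbook recursion over
the raw trio records, and neighbourhood membership by a hand-rolled
breadth-first search over an adjacency map built directly from the table.
"""

from __future__ import annotations

from collections import defaultdict, deque
from itertools import combinations

import pytest

from pedigraph import (
    PedigreeSimConfig,
    TrioTable,
    canonical_fixtures,
    make_random_pedigree,
    prepare_graph,
)

# -- oracle 1: classical kinship recursion ------------------------------


def classical_kinship(table: TrioTable):
    """Return phi(a, b), the classical kinship coefficient.

    phi(x, x) = (1 + f_x) / 2 with f_x = phi(father, mother);
    phi(a, b) = (phi(father_a, b) + phi(mother_a, b)) / 2 expanding the
    individual farther from the founders; founders (including parents
    referenced without a record) are mutually unrelated.
    """
    parents = {r.individual_id: (r.father_id, r.mother_id) for r in table}

    depth_memo: dict[str | None, int] = {}

    def depth(x):
        if x is None or x not in parents:
            return 0
        if x not in depth_memo:
            f, m = parents[x]
            depth_memo[x] = (
                0 if f is None and m is None else 1 + max(depth(f), depth(m))
            )
        return depth_memo[x]

    memo: dict[tuple, float] = {}

    def phi(a, b) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            f, m = parents.get(a, (None, None))
            value = 0.5 * (1 + phi(f, m))
        else:
            if depth(a) < depth(b):
                a, b = b, a
            f, m = parents.get(a, (None, None))
            value = 0.5 * (phi(f, b) + phi(m, b))
        memo[key] = value
        return value

    return phi


# -- oracle 2: brute-force neighbourhood BFS ----------------------------


def bfs_degrees(table: TrioTable, source: str, max_degree: int) -> dict[str, int]:
    """Shortest-path degrees from ``source`` in the mixed family graph,
    built directly from the trio records (parent links traversable both
    ways, one step per full-sibling pair)."""
    adj: dict[str, set[str]] = defaultdict(set)
    ids = set(table.ids())
    for rec in table:
        adj.setdefault(rec.individual_id, set())
        for p in (rec.father_id, rec.mother_id):
            if p is not None:
                adj[rec.individual_id].add(p)
                adj[p].add(rec.individual_id)
    sibships: dict[tuple[str, str], list[str]] = defaultdict(list)
    for rec in table:
        if rec.father_id is not None and rec.mother_id is not None:
            sibships[(rec.father_id, rec.mother_id)].append(rec.individual_id)
    for sibs in sibships.values():
        for a, b in combinations(sibs, 2):
            adj[a].add(b)
            adj[b].add(a)

    assert source in adj or source in ids
    degrees = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        if degrees[node] == max_degree:
            continue
        for other in adj[node]:
            if other not in degrees:
                degrees[other] = degrees[node] + 1
                queue.append(other)
    return degrees


# -- shared fixtures ----------------------------------------------------


@pytest.fixture(scope="session")
def fixtures():
    return canonical_fixtures()


@pytest.fixture(scope="session")
def nuclear_table(fixtures):
    return fixtures["nuclear"].table


@pytest.fixture(scope="session")
def nuclear_graph(nuclear_table):
    return prepare_graph(nuclear_table)


@pytest.fixture(scope="session")
def four_generation_graph(fixtures):
    return prepare_graph(fixtures["four_generation"].table)


def loop_free_pedigrees(n: int, start_seed: int = 0):
    """A varied batch of loop-free random pedigrees (each well under 200
    individuals)."""
    tables = []
    for i in range(n):
        deep = i % 4 == 0  # a quarter of the batch gets a third generation
        config = PedigreeSimConfig(
            n_founder_couples=2 + i % 3,
            n_generations=3 if deep else 2,
            sibship_mean=1.5 if deep else 1.5 + 0.5 * (i % 3),
            half_sib_rate=0.25,
            loop_free=True,
            seed=start_seed + i,
        )
        tables.append(make_random_pedigree(config))
    return tables


@pytest.fixture(scope="session")
def small_loop_free_tables():
    return loop_free_pedigrees(10, start_seed=500)
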