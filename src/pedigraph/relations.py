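"""Labelling relatives by generations up/down to the most recent common
ancestor.

Every genealogically valid connection between a proband and a relative is
summarised by a configuration ``(up, down, fullness)``: ``up`` generations
from the proband to the MRCA, ``down`` generations from the relative to
the MRCA, and whether the collateral link is through full or half
siblings. The configuration determines a compact code in the conventional
consanguinity taxonomy:

======== =========================================== =================
(up,down) code                                        description
======== =========================================== =================
(0,0)     Self
(1,0)     Pa                                          parent
(2,0)     GPa                                         grandparent
(u,0)     G…GPa (u-2 G's)                             great-…-grandparent
(0,v)     Ch / GCh / G…GCh                            child, grandchild, …
(1,1)     Sib / HSib                                  sibling / half-sibling
(u,1)     Pib / GPib / G…GPib (H-prefixed when half)  pibling = parent's sibling
(1,v)     Nib / GNib / G…GNib                         nibling = sibling's child
(u,v)≥2   {order}C[{removal}R], order=min(u,v)-1,     cousins, e.g. 1C2R =
          removal=|u-v|, H-prefixed when half         first cousin twice removed
======== =========================================== =================

The implied degree of relatedness is ``up + down - 1`` for full collateral
relations (the sibling bridge saves a step) and ``up + down`` otherwise.

Codes past the three anchored in common usage are this package's own
taxonomy; labelling is bounded: configurations ascending more than 6
generations on the proband side, or implying a degree above 9, fall into
a "Distant" bucket, and members with no MRCA configuration at all (e.g.
in-laws picked up by the neighbourhood) are "Unrelated".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .kinship import ancestor_distances
from .pedigree_graph import PedigreeGraph
from .relatives import FamilyGraph

FULL = "full"
HALF = "half"
NOT_APPLICABLE = "not_applicable"

SELF_CODE = "Self"
UNRELATED_CODE = "Unrelated"
DISTANT_CODE = "Distant"

#: Hard labelling bounds: maximum proband-side ascent and maximum implied degree.
MAX_UP = 6
MAX_DEGREE = 9

_ORDINALS = [
    "zeroth", "first", "second", "third", "fourth", "fifth",
    "sixth", "seventh", "eighth", "ninth", "tenth",
]


def _ordinal(n: int) -> str:
    return _ORDINALS[n] if n < len(_ORDINALS) else f"{n}th"


def _removal_words(n: int) -> str:
    if n == 1:
        return "once removed"
    if n == 2:
        return "twice removed"
    return f"{n} times removed"


@dataclass(frozen=True)
class RelationLabel:
    """A classified relationship: generation counts, code, prose and the
    implied degree of relatedness."""

    up: int
    down: int
    fullness: str
    code: str
    description: str
    degree: int


def classify_pair(up: int, down: int, fullness: str = NOT_APPLICABLE) -> RelationLabel:
    """Map a (generations-up, generations-down, fullness) configuration to
    its relationship label. Total on all non-negative ``up``/``down``."""
    if up < 0 or down < 0:
        raise ValueError(f"up and down must be non-negative, got ({up}, {down})")
    if fullness not in (FULL, HALF, NOT_APPLICABLE):
        raise ValueError(f"unknown fullness {fullness!r}")

    collateral = up >= 1 and down >= 1
    if not collateral:
        fullness = NOT_APPLICABLE
    elif fullness == NOT_APPLICABLE:
        fullness = FULL  # collateral codes always carry a fullness; default full
    half = fullness == HALF
    degree = up + down - (1 if collateral and not half else 0)

    if up == 0 and down == 0:
        return RelationLabel(0, 0, NOT_APPLICABLE, SELF_CODE, "self", 0)
    if down == 0:  # lineal ancestor
        code = "Pa" if up == 1 else "G" * (up - 2) + "GPa"
        desc = "parent" if up == 1 else "great-" * (up - 2) + "grandparent"
    elif up == 0:  # lineal descendant
        code = "Ch" if down == 1 else "G" * (down - 2) + "GCh"
        desc = "child" if down == 1 else "great-" * (down - 2) + "grandchild"
    elif up == 1 and down == 1:
        code, desc = ("HSib", "half-sibling") if half else ("Sib", "sibling")
    elif down == 1:  # pibling chain
        code = "Pib" if up == 2 else "G" * (up - 3) + "GPib"
        desc = (
            "pibling (parent's sibling)"
            if up == 2
            else "great-" * (up - 3) + "grandpibling"
        )
        if half:
            code, desc = "H" + code, "half-" + desc
    elif up == 1:  # nibling chain
        code = "Nib" if down == 2 else "G" * (down - 3) + "GNib"
        desc = (
            "nibling (sibling's child)"
            if down == 2
            else "great-" * (down - 3) + "grandnibling"
        )
        if half:
            code, desc = "H" + code, "half-" + desc
    else:  # cousins
        order = min(up, down) - 1
        removal = abs(up - down)
        code = f"{order}C" + (f"{removal}R" if removal else "")
        desc = f"{_ordinal(order)} cousin"
        if removal:
            desc += f" {_removal_words(removal)}"
        if half:
            code, desc = "H" + code, "half " + desc
    return RelationLabel(up, down, fullness, code, desc, degree)


_MALE_HEADS = {
    "parent": "father", "child": "son", "sibling": "brother",
    "pibling": "uncle", "nibling": "nephew",
}
_FEMALE_HEADS = {
    "parent": "mother", "child": "daughter", "sibling": "sister",
    "pibling": "aunt", "nibling": "niece",
}


def sexed_description(label: RelationLabel, sex: str | None) -> str:
    """Sex-specialised prose ("father", "granddaughter", "half-uncle", …);
    the code itself stays sex-neutral. Cousins are not specialised."""
    heads = {"male": _MALE_HEADS, "female": _FEMALE_HEADS}.get(sex or "")
    if not heads:
        return label.description
    head, _, rest = label.description.partition(" (")
    for suffix, replacement in heads.items():
        if head.endswith(suffix):
            head = head[: -len(suffix)] + replacement
            break
    return head


@dataclass(frozen=True)
class _Config:
    up: int
    down: int
    fullness: str
    bridged: bool  # crossed a full-sibling edge at the apex

    @property
    def degree(self) -> int:
        collateral = self.up >= 1 and self.down >= 1
        return self.up + self.down - (1 if collateral and self.fullness == FULL else 0)


def mrca_configurations(graph: PedigreeGraph, i: str, j: str) -> list[_Config]:
    """Enumerate all MRCA configurations connecting ``i`` to ``j``:
    one per common ancestor, plus one per full-sibling bridge between an
    ancestor-or-self of each."""
    if i == j:
        return [_Config(0, 0, NOT_APPLICABLE, False)]
    anc_i = ancestor_distances(graph, i)
    anc_j = ancestor_distances(graph, j)
    configs: set[_Config] = set()
    for a, u in anc_i.items():
        v = anc_j.get(a)
        if v is None:
            continue
        if u >= 1 and v >= 1:
            full = (
                u == 1
                and v == 1
                and len(set(graph.parent_ids(i))) == 2
                and set(graph.parent_ids(i)) == set(graph.parent_ids(j))
            )
            configs.add(_Config(u, v, FULL if full else HALF, False))
        else:
            configs.add(_Config(u, v, NOT_APPLICABLE, False))
    for pair in graph.sibling_edges:
        s, t = tuple(pair)
        for s_, t_ in ((s, t), (t, s)):
            u, v = anc_i.get(s_), anc_j.get(t_)
            if u is not None and v is not None:
                configs.add(_Config(u + 1, v + 1, FULL, True))
    return sorted(
        configs,
        key=lambda c: (c.degree, -min(c.up, c.down), c.up, c.fullness != FULL),
    )


def best_configuration(graph: PedigreeGraph, i: str, j: str) -> _Config | None:
    """Minimal-degree configuration; ties broken toward the more
    horizontal relation (larger ``min(up, down)``). ``None`` if unrelated."""
    configs = mrca_configurations(graph, i, j)
    return configs[0] if configs else None


def get_relations(family: FamilyGraph) -> pd.DataFrame:
    """Label every member of a family graph relative to its proband.

    Returns one row per member with columns ``proband_id, member_id, up,
    down, fullness, code, degree, description``. Generation counts are
    those of the selected MRCA configuration, evaluated within the family
    subgraph; members without any configuration are "Unrelated" and
    configurations beyond the labelling bounds are "Distant" (both carry
    missing generation counts in the ``code``-determining sense but keep
    their numbers for inspection where available).
    """
    graph = family.graph
    proband = family.proband_id
    rows = []
    for member in sorted(family.members, key=lambda m: (family.degrees[m], m)):
        config = best_configuration(graph, proband, member)
        if config is None:
            rows.append((proband, member, pd.NA, pd.NA, NOT_APPLICABLE,
                         UNRELATED_CODE, pd.NA, "unrelated (no common ancestor)"))
            continue
        if config.up > MAX_UP or config.degree > MAX_DEGREE:
            rows.append((proband, member, config.up, config.down, config.fullness,
                         DISTANT_CODE, config.degree, "distant relative (unlabelled)"))
            continue
        label = classify_pair(config.up, config.down, config.fullness)
        sex = graph.node_attributes(member).get("sex")
        rows.append((proband, member, label.up, label.down, label.fullness,
                     label.code, label.degree, sexed_description(label, sex)))
    return pd.DataFrame(
        rows,
        columns=["proband_id", "member_id", "up", "down", "fullness",
                 "code", "degree", "description"],
    )


def get_relations_for_families(families: dict[str, FamilyGraph]) -> pd.DataFrame:
    """Concatenate :func:`get_relations` over many probands."""
    if not families:
        return pd.DataFrame(
            columns=["proband_id", "member_id", "up", "down", "fullness",
                     "code", "degree", "description"]
        )
    return pd.concat(
        [get_relations(f) for f in families.values()], ignore_index=True
    )
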