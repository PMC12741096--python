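"""Seeded synthetic pedigrees and canonical hand-built fixture families.

The generator produces generation-structured populations: founder couples,
zero-truncated-Poisson sibship sizes, optional re-partnering (half
sibships) and either fully exogamous mating (``loop_free=True``, every
child pairs with an unrelated immigrant, so no pair is related through
two distinct ancestral couples) or within-generation random mating that
can create pedigree loops. It emulates the *structure* of register trio
data — truncated ascending lineages, mixed sibship sizes, isolated
immigrants — not human demography: there is no age structure, mortality
or assortative mating.

The canonical fixtures are small families with hand-verified expected
distances, kinships and relation labels, shipped as sidecar tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trio_io import FEMALE, MALE, MISSING, TrioRecord, TrioTable


@dataclass
class PedigreeSimConfig:
    """Parameters of the random-pedigree generator.

    n_founder_couples : founding couples in generation 0.
    n_generations : reproducing generations after the founders.
    sibship_mean : lambda of the zero-truncated Poisson sibship size.
    half_sib_rate : probability a couple's parent re-partners once and
        produces a second sibship with a new unrelated partner.
    loop_free : when True every mate is a fresh unrelated immigrant.
    seed : RNG seed; identical configs produce identical tables.
    """

    n_founder_couples: int = 5
    n_generations: int = 3
    sibship_mean: float = 2.5
    half_sib_rate: float = 0.1
    loop_free: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_founder_couples < 1:
            raise ValueError("n_founder_couples must be >= 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.sibship_mean <= 0:
            raise ValueError("sibship_mean must be > 0")
        if not 0 <= self.half_sib_rate <= 1:
            raise ValueError("half_sib_rate must be in [0, 1]")


def _zt_poisson(rng: np.random.Generator, lam: float) -> int:
    k = 0
    while k == 0:
        k = int(rng.poisson(lam))
    return k


def make_random_pedigree(config: PedigreeSimConfig) -> TrioTable:
    """Generate a trio table from the configured branching process.

    IDs encode generation and origin for debuggability: ``g2i7`` is the
    7th individual born into generation 2, ``g2f3`` the 3rd immigrant
    founder joining generation 2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[TrioRecord] = []
    counters: dict[str, int] = {}

    def new_id(gen: int, kind: str) -> str:
        key = f"g{gen}{kind}"
        counters[key] = counters.get(key, 0) + 1
        return f"{key}{counters[key]}"

    def add(individual: str, father, mother, sex: str, gen: int) -> None:
        records.append(
            TrioRecord(individual, father, mother, sex,
                       attributes={"generation": str(gen)})
        )

    # generation 0: founder couples
    couples: list[tuple[str, str]] = []
    for _ in range(config.n_founder_couples):
        f, m = new_id(0, "f"), new_id(0, "f")
        add(f, MISSING, MISSING, MALE, 0)
        add(m, MISSING, MISSING, FEMALE, 0)
        couples.append((f, m))

    for gen in range(1, config.n_generations + 1):
        children: list[tuple[str, str, int]] = []  # (id, sex, sibship index)

        def bear(father: str, mother: str, sibship: int) -> None:
            for _ in range(_zt_poisson(rng, config.sibship_mean)):
                sex = MALE if rng.random() < 0.5 else FEMALE
                child = new_id(gen, "i")
                add(child, father, mother, sex, gen)
                children.append((child, sex, sibship))

        sibship = 0
        for father, mother in couples:
            bear(father, mother, sibship)
            sibship += 1
            if rng.random() < config.half_sib_rate:
                # one parent re-partners with a fresh immigrant
                if rng.random() < 0.5:
                    partner = new_id(gen - 1, "f")
                    add(partner, MISSING, MISSING, FEMALE, gen - 1)
                    bear(father, partner, sibship)
                else:
                    partner = new_id(gen - 1, "f")
                    add(partner, MISSING, MISSING, MALE, gen - 1)
                    bear(partner, mother, sibship)
                sibship += 1

        if gen == config.n_generations:
            break

        couples = []
        if config.loop_free:
            for child, sex, _ in children:
                partner = new_id(gen, "f")
                add(partner, MISSING, MISSING,
                    FEMALE if sex == MALE else MALE, gen)
                couples.append((child, partner) if sex == MALE else (partner, child))
        else:
            males = [(c, s) for c, s, sib in children if s == MALE]
            females = [(c, sib) for c, s, sib in children if s == FEMALE]
            male_ids = [c for c, _ in males]
            male_sib = {c: sib for c, s, sib in children if s == MALE}
            order = rng.permutation(len(male_ids))
            unmatched_females = []
            used: set[str] = set()
            for c, sib in females:
                mate = None
                for k in order:
                    cand = male_ids[k]
                    if cand not in used and male_sib[cand] != sib:
                        mate = cand
                        break
                if mate is None:
                    unmatched_females.append(c)
                else:
                    used.add(mate)
                    couples.append((mate, c))
            for c in unmatched_females:
                partner = new_id(gen, "f")
                add(partner, MISSING, MISSING, MALE, gen)
                couples.append((partner, c))
            for c in male_ids:
                if c not in used:
                    partner = new_id(gen, "f")
                    add(partner, MISSING, MISSING, FEMALE, gen)
                    couples.append((c, partner))

    return TrioTable(records)


# -- canonical fixtures -------------------------------------------------

SELF = "Self"
UNRELATED = "Unrelated"
INF = math.inf


@dataclass
class CanonicalFixture:
    """A hand-built family plus its sidecar of expected values.

    ``expectations`` columns: id_1 (proband side), id_2, distance
    (genealogical path length, ``inf`` when none exists), kinship
    (``0.5**distance`` at C=1) and label (relation of id_2 w.r.t. id_1).
    """

    name: str
    table: TrioTable
    expectations: pd.DataFrame


def _expect(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["id_1", "id_2", "distance", "kinship", "label"]
    )


def _rec(i, f, m, sex) -> TrioRecord:
    return TrioRecord(i, f, m, sex)


def canonical_fixtures() -> dict[str, CanonicalFixture]:
    """Named fixture families with hand-verified expectation sidecars."""
    fixtures: dict[str, CanonicalFixture] = {}

    # nuclear: two founders, two full-sibling children
    nuclear = TrioTable([
        _rec("f1", MISSING, MISSING, MALE),
        _rec("m1", MISSING, MISSING, FEMALE),
        _rec("c1", "f1", "m1", FEMALE),
        _rec("c2", "f1", "m1", MALE),
    ])
    fixtures["nuclear"] = CanonicalFixture("nuclear", nuclear, _expect([
        ("c1", "c1", 0, 1.0, SELF),
        ("c1", "f1", 1, 0.5, "Pa"),
        ("c1", "m1", 1, 0.5, "Pa"),
        ("c1", "c2", 1, 0.5, "Sib"),
        ("f1", "c1", 1, 0.5, "Ch"),
        ("f1", "m1", INF, 0.0, UNRELATED),  # co-parents share no ancestor
    ]))

    # half-sib: one mother, two fathers
    half_sib = TrioTable([
        _rec("f1", MISSING, MISSING, MALE),
        _rec("f2", MISSING, MISSING, MALE),
        _rec("m1", MISSING, MISSING, FEMALE),
        _rec("c1", "f1", "m1", MALE),
        _rec("c2", "f2", "m1", FEMALE),
    ])
    fixtures["half_sib"] = CanonicalFixture("half_sib", half_sib, _expect([
        ("c1", "m1", 1, 0.5, "Pa"),
        ("c1", "c2", 2, 0.25, "HSib"),
        ("c1", "f2", INF, 0.0, UNRELATED),
        ("f1", "f2", INF, 0.0, UNRELATED),
    ]))

    # four generations around proband "prb": great-grandparents, a
    # grandpibling with a child (prb's parent's first cousin = 1C1R),
    # a full pibling with a child (first cousin), and a paternal half-sib
    four_gen = TrioTable([
        _rec("ggf", MISSING, MISSING, MALE),
        _rec("ggm", MISSING, MISSING, FEMALE),
        _rec("gpa", "ggf", "ggm", MALE),
        _rec("gdau", "ggf", "ggm", FEMALE),
        _rec("gpw", MISSING, MISSING, FEMALE),
        _rec("gdauh", MISSING, MISSING, MALE),
        _rec("dad", "gpa", "gpw", MALE),
        _rec("aunt", "gpa", "gpw", FEMALE),
        _rec("cous1r", "gdauh", "gdau", MALE),
        _rec("mom", MISSING, MISSING, FEMALE),
        _rec("auntp", MISSING, MISSING, MALE),
        _rec("stepmom", MISSING, MISSING, FEMALE),
        _rec("prb", "dad", "mom", FEMALE),
        _rec("sib", "dad", "mom", MALE),
        _rec("cousin", "auntp", "aunt", FEMALE),
        _rec("halfsib", "dad", "stepmom", FEMALE),
    ])
    fixtures["four_generation"] = CanonicalFixture(
        "four_generation", four_gen, _expect([
            ("prb", "dad", 1, 0.5, "Pa"),
            ("prb", "mom", 1, 0.5, "Pa"),
            ("prb", "sib", 1, 0.5, "Sib"),
            ("prb", "halfsib", 2, 0.25, "HSib"),
            ("prb", "gpa", 2, 0.25, "GPa"),
            ("prb", "gpw", 2, 0.25, "GPa"),
            ("prb", "aunt", 2, 0.25, "Pib"),
            ("prb", "ggf", 3, 0.125, "GGPa"),
            ("prb", "ggm", 3, 0.125, "GGPa"),
            ("prb", "cousin", 3, 0.125, "1C"),
            ("prb", "gdau", 3, 0.125, "GPib"),
            ("prb", "cous1r", 4, 0.0625, "1C1R"),
            ("prb", "auntp", INF, 0.0, UNRELATED),
            ("prb", "stepmom", INF, 0.0, UNRELATED),
        ])
    )

    # double first cousins: two sibling pairs intermarry; the path
    # estimator sees 0.5**3 = 0.125 while classical 2*phi = 0.25
    dfc = TrioTable([
        _rec("fpa", MISSING, MISSING, MALE),
        _rec("fma", MISSING, MISSING, FEMALE),
        _rec("fpb", MISSING, MISSING, MALE),
        _rec("fmb", MISSING, MISSING, FEMALE),
        _rec("a1", "fpa", "fma", MALE),
        _rec("a2", "fpa", "fma", FEMALE),
        _rec("b1", "fpb", "fmb", FEMALE),
        _rec("b2", "fpb", "fmb", MALE),
        _rec("x", "a1", "b1", FEMALE),
        _rec("y", "b2", "a2", MALE),
    ])
    fixtures["double_first_cousins"] = CanonicalFixture(
        "double_first_cousins", dfc, _expect([
            ("x", "y", 3, 0.125, "1C"),
            ("x", "a1", 1, 0.5, "Pa"),
            ("x", "a2", 2, 0.25, "Pib"),
        ])
    )

    # isolated individuals alongside one trio
    iso = TrioTable([
        _rec("iso1", MISSING, MISSING, FEMALE),
        _rec("iso2", MISSING, MISSING, MALE),
        _rec("f1", MISSING, MISSING, MALE),
        _rec("m1", MISSING, MISSING, FEMALE),
        _rec("c1", "f1", "m1", MALE),
    ])
    fixtures["isolated_individuals"] = CanonicalFixture(
        "isolated_individuals", iso, _expect([
            ("iso1", "iso1", 0, 1.0, SELF),
            ("iso1", "iso2", INF, 0.0, UNRELATED),
            ("iso1", "c1", INF, 0.0, UNRELATED),
        ])
    )
    return fixtures
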