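"""Relationship classification: code taxonomy, totality, reciprocity and
labelling of whole family graphs."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedigraph import (
    MISSING,
    TrioRecord,
    TrioTable,
    classify_pair,
    get_family_graphs,
    get_relations,
    prepare_graph,
)
from pedigraph.relations import FULL, HALF, NOT_APPLICABLE, sexed_description


class TestClassifyPair:
    @pytest.mark.parametrize(
        "up,down,fullness,code",
        [
            (0, 0, NOT_APPLICABLE, "Self"),
            (1, 0, NOT_APPLICABLE, "Pa"),
            (2, 0, NOT_APPLICABLE, "GPa"),
            (3, 0, NOT_APPLICABLE, "GGPa"),
            (6, 0, NOT_APPLICABLE, "GGGGGPa"),
            (0, 1, NOT_APPLICABLE, "Ch"),
            (0, 2, NOT_APPLICABLE, "GCh"),
            (0, 4, NOT_APPLICABLE, "GGGCh"),
            (1, 1, FULL, "Sib"),
            (1, 1, HALF, "HSib"),
            (2, 1, FULL, "Pib"),
            (3, 1, FULL, "GPib"),
            (4, 1, FULL, "GGPib"),
            (2, 1, HALF, "HPib"),
            (1, 2, FULL, "Nib"),
            (1, 3, FULL, "GNib"),
            (2, 2, FULL, "1C"),
            (2, 2, HALF, "H1C"),
            (3, 3, FULL, "2C"),
            (2, 3, FULL, "1C1R"),
            (2, 4, FULL, "1C2R"),
            (4, 2, FULL, "1C2R"),
            (3, 5, FULL, "2C2R"),
        ],
    )
    def test_code_table(self, up, down, fullness, code):
        assert classify_pair(up, down, fullness).code == code

    @pytest.mark.parametrize(
        "up,down,fullness,degree",
        [
            (1, 0, NOT_APPLICABLE, 1),
            (1, 1, FULL, 1),  # sibling bridge saves a step
            (1, 1, HALF, 2),
            (2, 1, FULL, 2),
            (2, 2, FULL, 3),
            (3, 0, NOT_APPLICABLE, 3),
            (3, 2, FULL, 4),
            (2, 2, HALF, 4),
        ],
    )
    def test_implied_degree(self, up, down, fullness, degree):
        assert classify_pair(up, down, fullness).degree == degree

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(-1, 0)

    @given(
        up=st.integers(min_value=0, max_value=6),
        down=st.integers(min_value=0, max_value=6),
        fullness=st.sampled_from([FULL, HALF, NOT_APPLICABLE]),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_total_and_code_unique_on_grid(self, up, down, fullness):
        """classify_pair is defined on the whole 0..6 x 0..6 grid and a
        code pins down its configuration up to the deliberate up/down
        symmetry of cousin codes."""
        label = classify_pair(up, down, fullness)
        assert label.code
        seen = set()
        for u in range(7):
            for v in range(7):
                for f in (FULL, HALF, NOT_APPLICABLE):
                    other = classify_pair(u, v, f)
                    if other.code == label.code:
                        seen.add((other.up, other.down, other.fullness))
        assert seen <= {
            (label.up, label.down, label.fullness),
            (label.down, label.up, label.fullness),
        }

    @given(
        up=st.integers(min_value=0, max_value=6),
        down=st.integers(min_value=0, max_value=6),
        fullness=st.sampled_from([FULL, HALF]),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_reciprocity(self, up, down, fullness):
        """Swapping the viewpoint swaps up/down: Pib <-> Nib, ancestors
        <-> descendants, cousin codes unchanged."""
        a = classify_pair(up, down, fullness)
        b = classify_pair(down, up, fullness)
        assert a.degree == b.degree
        assert (b.up, b.down) == (a.down, a.up)
        if min(up, down) >= 2 or up == down:
            assert a.code == b.code  # cousins and symmetric cases
        else:
            assert a.code != b.code  # lineal/pibling chains mirror
            assert classify_pair(b.down, b.up, fullness).code == a.code

    def test_pib_nib_and_lineal_mirrors(self):
        pairs = [
            (("Pa",), ("Ch",)), (("GPa",), ("GCh",)), (("GGPa",), ("GGCh",)),
            (("Pib",), ("Nib",)), (("GPib",), ("GNib",)),
        ]
        mirrors = {
            classify_pair(1, 0).code: classify_pair(0, 1).code,
            classify_pair(2, 0).code: classify_pair(0, 2).code,
            classify_pair(3, 0).code: classify_pair(0, 3).code,
            classify_pair(2, 1, FULL).code: classify_pair(1, 2, FULL).code,
            classify_pair(3, 1, FULL).code: classify_pair(1, 3, FULL).code,
        }
        assert mirrors == {a[0]: d[0] for a, d in pairs}


class TestSexedDescriptions:
    def test_head_word_specialisation(self):
        assert sexed_description(classify_pair(1, 0), "male") == "father"
        assert sexed_description(classify_pair(3, 0), "female") == "great-grandmother"
        assert sexed_description(classify_pair(0, 2), "male") == "grandson"
        assert sexed_description(classify_pair(2, 1, HALF), "female") == "half-aunt"
        assert sexed_description(classify_pair(1, 1, FULL), None) == "sibling"
        # cousins stay neutral
        assert sexed_description(classify_pair(2, 2, FULL), "male") == "first cousin"


class TestGetRelations:
    def _relations(self, table, proband, degree=6):
        graph = prepare_graph(table)
        fam = get_family_graphs(graph, [proband], degree)[proband]
        df = get_relations(fam)
        return df.set_index("member_id")

    def test_nuclear_labels(self, fixtures):
        rel = self._relations(fixtures["nuclear"].table, "c1")
        assert rel.loc["f1", "code"] == "Pa"
        assert rel.loc["f1", "description"] == "father"
        assert rel.loc["m1", "description"] == "mother"
        assert rel.loc["c2", "code"] == "Sib"
        assert rel.loc["c1", "code"] == "Self"

    def test_co_parent_is_unrelated(self):
        table = TrioTable([
            TrioRecord("pa", MISSING, MISSING, "male"),
            TrioRecord("ma", MISSING, MISSING, "female"),
            TrioRecord("kid", "pa", "ma", "female"),
        ])
        rel = self._relations(table, "pa")
        assert rel.loc["ma", "code"] == "Unrelated"
        assert rel.loc["kid", "code"] == "Ch"

    def test_four_generation_labels(self, fixtures):
        rel = self._relations(fixtures["four_generation"].table, "prb")
        expected = {
            "ggf": "GGPa", "cousin": "1C", "halfsib": "HSib",
            "aunt": "Pib", "gdau": "GPib", "cous1r": "1C1R",
        }
        for member, code in expected.items():
            assert rel.loc[member, "code"] == code, member

    def test_label_degree_matches_graph_degree_on_loop_free(self, small_loop_free_tables):
        for table in small_loop_free_tables[:4]:
            graph = prepare_graph(table)
            proband = table.ids()[-1]
            fam = get_family_graphs(graph, [proband], 4)[proband]
            rel = get_relations(fam)
            labelled = rel[~rel.code.isin(["Unrelated", "Distant"])]
            for row in labelled.itertuples():
                assert row.degree == fam.degrees[row.member_id], row.member_id

    def test_distant_bucket_beyond_labelling_bounds(self):
        # an unbroken chain of 8 generations: the top ancestor implies
        # up=8 > 6, so it is Distant rather than G^6GPa
        rows = [TrioRecord("i0", MISSING, MISSING, "male"),
                TrioRecord("s0", MISSING, MISSING, "female")]
        for g in range(1, 9):
            rows.append(TrioRecord(f"i{g}", f"i{g-1}", f"s{g-1}", "male"))
            rows.append(TrioRecord(f"s{g}", MISSING, MISSING, "female"))
        rel = self._relations(TrioTable(rows), "i8", degree=8)
        assert rel.loc["i2", "code"] == "GGGGGPa"  # up=6 still labelled
        assert rel.loc["i1", "code"] == "Distant"
        assert rel.loc["i0", "code"] == "Distant"

    def test_horizontal_tie_break(self):
        """A relative reachable both as a distant ancestor and as a
        collateral of equal degree is labelled with the more horizontal
        (larger min(up, down)) configuration."""
        assert classify_pair(2, 2, FULL).degree == classify_pair(3, 0).degree == 3
        # build: proband's full pibling is ALSO their great-grandparent?
        # impossible without incest; instead check the selector directly.
        from pedigraph.relations import _Config, mrca_configurations

        configs = sorted(
            [_Config(3, 0, NOT_APPLICABLE, False), _Config(2, 2, FULL, True)],
            key=lambda c: (c.degree, -min(c.up, c.down), c.up, c.fullness != FULL),
        )
        assert (configs[0].up, configs[0].down) == (2, 2)
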