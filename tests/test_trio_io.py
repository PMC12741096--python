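"""Trio table ingest, validation, writing and graph round trips."""

import pytest

from pedigraph import (
    AmbiguousParentError,
    MISSING,
    TrioFormatError,
    TrioRecord,
    TrioTable,
    TrioValidationError,
    graph_to_trio,
    prepare_graph,
    read_trios,
    write_trios,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadTrios:
    def test_basic_ingest_with_missing_code(self, tmp_path):
        path = _write(tmp_path, "t.csv", "id,dad_id,mom_id\nc1,f1,m1\nf1,0,0\nm1,0,0\n")
        table = read_trios(path, missing_codes=("0",))
        assert len(table) == 3
        assert table.records[0].father_id == "f1"
        assert table.records[1].is_founder and table.records[2].is_founder

    def test_ids_are_strings_even_when_numeric(self, tmp_path):
        path = _write(tmp_path, "t.csv", "id,dad_id,mom_id\n101,202,303\n")
        rec = read_trios(path).records[0]
        assert rec.individual_id == "101" and rec.father_id == "202"

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write(tmp_path, "t.csv", "id,papa,mom_id\nc1,f1,m1\n")
        with pytest.raises(TrioFormatError, match="dad_id"):
            read_trios(path)

    def test_duplicate_ids_rejected_and_listed(self, tmp_path):
        path = _write(tmp_path, "t.csv", "id,dad_id,mom_id\na,NA,NA\na,NA,NA\nb,NA,NA\nb,NA,NA\n")
        with pytest.raises(TrioValidationError, match="a.*b"):
            read_trios(path)

    def test_same_father_and_mother_rejected(self, tmp_path):
        path = _write(tmp_path, "t.csv", "id,dad_id,mom_id\na,b,b\n")
        with pytest.raises(TrioValidationError, match="father_id equals mother_id"):
            read_trios(path)

    def test_self_parentage_rejected(self, tmp_path):
        path = _write(tmp_path, "t.csv", "id,dad_id,mom_id\na,a,NA\n")
        with pytest.raises(TrioValidationError, match="self-parentage"):
            read_trios(path)

    def test_extra_columns_become_attributes_verbatim(self, tmp_path):
        path = _write(
            tmp_path, "t.tsv",
            "id\tdad_id\tmom_id\tsex\tbirth_year\nc1\tf1\tm1\tF\t1990\n",
        )
        rec = read_trios(path, format="tsv").records[0]
        assert rec.sex == "female"
        assert rec.attributes == {"birth_year": "1990"}

    def test_plink_fam_dialect(self, tmp_path):
        path = _write(tmp_path, "t.fam", "FAM1 c1 f1 m1 2 -9\nFAM1 f1 0 0 1 -9\n")
        table = read_trios(path, format="plink_fam")
        c1, f1 = table.records
        assert c1.sex == "female" and f1.sex == "male"
        assert c1.father_id == "f1" and f1.is_founder
        assert c1.attributes == {"fid": "FAM1", "phenotype": "-9"}


class TestWriteTrios:
    @pytest.mark.parametrize("fmt", ["csv", "tsv"])
    def test_write_read_round_trip(self, tmp_path, fmt, fixtures):
        for fixture in fixtures.values():
            path = tmp_path / f"{fixture.name}.{fmt}"
            write_trios(fixture.table, path, format=fmt)
            back = read_trios(path, format=fmt,
                              missing_codes=fixture.table.missing_codes)
            assert back.ids() == fixture.table.ids()
            for a, b in zip(back, fixture.table):
                assert (a.father_id, a.mother_id, a.sex) == (
                    b.father_id, b.mother_id, b.sex)

    def test_plink_round_trip_and_unknown_sex_code(self, tmp_path):
        table = TrioTable([
            TrioRecord("f1", MISSING, MISSING, "male"),
            TrioRecord("m1", MISSING, MISSING, "female"),
            TrioRecord("c1", "f1", "m1", "unknown"),
        ])
        path = tmp_path / "t.fam"
        write_trios(table, path, format="plink_fam")
        assert path.read_text().splitlines()[2].split()[4] == "0"
        back = read_trios(path, format="plink_fam")
        assert [r.individual_id for r in back] == table.ids()
        assert back.records[2].sex == "unknown"

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_trios(TrioTable([]), path)
        assert path.read_text() == "id,dad_id,mom_id,sex\n"

    def test_missing_written_as_first_configured_code(self, tmp_path):
        table = TrioTable([TrioRecord("a", MISSING, MISSING)],
                          missing_codes=("*", "NA"))
        path = tmp_path / "t.csv"
        write_trios(table, path)
        assert "a,*,*,*" in path.read_text()


class TestGraphToTrio:
    def test_round_trip_identity_on_sexed_tables(self, fixtures):
        for fixture in fixtures.values():
            table = fixture.table
            back = graph_to_trio(prepare_graph(table))
            original = {r.individual_id: r for r in table}
            assert set(back.ids()) == set(table.ids())
            for rec in back:
                ref = original[rec.individual_id]
                assert rec.father_id == ref.father_id
                assert rec.mother_id == ref.mother_id
                assert rec.sex == ref.sex

    def test_referenced_parents_come_back_as_founders(self):
        # f1/m1 have no row of their own; they gain founder records
        table = TrioTable([TrioRecord("c1", "f1", "m1", "male")])
        with pytest.raises(AmbiguousParentError):  # parents carry no sex
            graph_to_trio(prepare_graph(table))
        back = graph_to_trio(prepare_graph(table), on_ambiguity="set_missing")
        by_id = {r.individual_id: r for r in back}
        assert by_id["f1"].is_founder and by_id["m1"].is_founder
        assert by_id["c1"].is_founder  # unsexed parents were dropped

    def test_unsexed_parent_error_names_the_parent(self, nuclear_table):
        from pedigraph import PedigreeGraph

        graph = PedigreeGraph()
        graph.add_individual("kid", sex="male")
        graph.add_individual("anon")
        graph.add_parental_edge("anon", "kid")
        with pytest.raises(AmbiguousParentError, match="anon"):
            graph_to_trio(graph)

    def test_two_same_sex_parents_error_names_the_child(self):
        from pedigraph import PedigreeGraph

        graph = PedigreeGraph()
        for p in ("p1", "p2"):
            graph.add_individual(p, sex="male")
            graph.add_parental_edge(p, "kid")
        with pytest.raises(AmbiguousParentError, match="kid"):
            graph_to_trio(graph)

    def test_isolated_node_becomes_single_founder_record(self):
        from pedigraph import PedigreeGraph

        graph = PedigreeGraph()
        graph.add_individual("only", sex="female")
        back = graph_to_trio(graph)
        assert len(back) == 1 and back.records[0].is_founder
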