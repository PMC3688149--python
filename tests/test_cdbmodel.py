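"""Schema extraction, the three-level model, OBO round-trips and
vocabulary loading."""

import io
import random

import pytest

from iptrans.cdbmodel import (
    ModelConflictError,
    ModelError,
    SchemaError,
    SourceColumn,
    SourceSchema,
    SourceTable,
    build_model,
    extract_schema,
    load_model,
    model_from_store,
    read_obo,
    write_obo,
)

from conftest import random_schema, write_csv


class TestExtractSchema:
    def test_csv_patient_table(self, tmp_path):
        write_csv(
            tmp_path / "patient.csv",
            ["id", "age", "height", "weight"],
            [["1", "58", "1.72", "80.0"]],
        )
        schema = extract_schema(str(tmp_path), "csv_dir", db_name="CDB")
        assert len(schema.tables) == 1
        table = schema.tables[0]
        assert table.name == "patient"
        assert table.column_names == ["id", "age", "height", "weight"]
        assert table.key_column == "id"
        assert {c.name: c.datatype for c in table.columns} == {
            "id": "integer",
            "age": "integer",
            "height": "decimal",
            "weight": "decimal",
        }

    def test_empty_dir_gives_empty_schema(self, tmp_path):
        schema = extract_schema(str(tmp_path), "csv_dir")
        assert schema.tables == []

    def test_headerless_csv_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("")
        with pytest.raises(SchemaError):
            extract_schema(str(tmp_path), "csv_dir")

    def test_datatype_inference_precedence(self, tmp_path):
        write_csv(
            tmp_path / "t.csv",
            ["id", "mixed", "dates", "flags", "free"],
            [
                ["1", "2", "2011-01-05", "true", "hello"],
                ["2", "2.5", "2012-03-01", "false", "3"],
            ],
        )
        table = extract_schema(str(tmp_path), "csv_dir").tables[0]
        assert {c.name: c.datatype for c in table.columns} == {
            "id": "integer",
            "mixed": "decimal",
            "dates": "date",
            "flags": "boolean",
            "free": "text",
        }

    def test_sql_dump_matches_hand_parsed_ddl(self, tmp_path):
        dump = tmp_path / "d.sql"
        dump.write_text(
            "CREATE TABLE alpha (id INTEGER, height DECIMAL, born DATE);\n"
            "CREATE TABLE beta (id INTEGER, label VARCHAR(40), ok BOOLEAN);\n"
            "INSERT INTO alpha VALUES ('1', '1.72', '1950-02-03');\n"
        )
        schema = extract_schema(str(dump), "sql_dump", db_name="d")
        assert [t.name for t in schema.tables] == ["alpha", "beta"]
        assert {c.name: c.datatype for c in schema.table("alpha").columns} == {
            "id": "integer",
            "height": "decimal",
            "born": "date",
        }
        assert {c.name: c.datatype for c in schema.table("beta").columns} == {
            "id": "integer",
            "label": "text",
            "ok": "boolean",
        }

    def test_vendor_sql_rejected_loudly(self, tmp_path):
        dump = tmp_path / "d.sql"
        dump.write_text("LOCK TABLES alpha WRITE;\n")
        with pytest.raises(SchemaError):
            extract_schema(str(dump), "sql_dump")

    def test_key_override(self, tmp_path):
        write_csv(tmp_path / "t.csv", ["code", "name"], [["a", "x"]])
        schema = extract_schema(str(tmp_path), "csv_dir", key_overrides={"t": "name"})
        assert schema.table("t").key_column == "name"


class TestBuildModel:
    def test_three_levels_and_five_terms(self):
        schema = SourceSchema(
            "CDB",
            [
                SourceTable(
                    "patient",
                    [SourceColumn("age", "integer"), SourceColumn("height", "decimal"),
                     SourceColumn("weight", "decimal")],
                    "age",
                )
            ],
        )
        model = build_model(schema)
        assert model.depth == 3
        assert model.term_count == 5
        assert model.root.name == "CDB"
        assert [t.name for t in model.table_terms] == ["patient"]
        assert sorted(t.name for t in model.column_terms) == [
            "patient.age", "patient.height", "patient.weight",
        ]

    def test_key_only_table_keeps_key_term_marked(self):
        # key columns become terms too, flagged is_key so the ETL treats
        # them as system rows rather than facts
        schema = SourceSchema("d", [SourceTable("t", [SourceColumn("id", "integer")], "id")])
        model = build_model(schema)
        assert model.depth == 3
        (key_term,) = model.column_terms
        assert key_term.is_key

    def test_childless_table_term_still_counts_its_level(self):
        from iptrans.cdbmodel import ClinicalDatabaseModel, ModelTerm

        model = ClinicalDatabaseModel(
            "d", [ModelTerm("d:0", "d"), ModelTerm("d:1", "t", "d:0")]
        )
        assert model.depth == 2
        assert model.table_terms[0].name == "t"

    def test_term_count_matches_schema_on_random_schemas(self):
        rng = random.Random(42)
        for _ in range(25):
            schema = random_schema(rng)
            model = build_model(schema)
            assert model.term_count == 1 + len(schema.tables) + schema.n_columns
            assert model.depth == 3

    def test_deterministic_sibling_order_and_ids(self):
        schema = SourceSchema(
            "d",
            [
                SourceTable("zeta", [SourceColumn("id")], "id"),
                SourceTable("alpha", [SourceColumn("id")], "id"),
            ],
        )
        model = build_model(schema)
        assert [t.name for t in model.table_terms] == ["alpha", "zeta"]
        assert [t.id for t in model.terms] == [f"d:{i:07d}" for i in range(5)]


class TestOboRoundTrip:
    def test_round_trip_identity_on_random_schemas(self):
        rng = random.Random(7)
        for _ in range(25):
            model = build_model(random_schema(rng))
            assert read_obo(write_obo(model)) == model

    def test_column_term_without_is_a_rejected(self):
        text = (
            "format-version: 1.2\n\n[Term]\nid: d:0000000\nname: d\n\n"
            "[Term]\nid: d:0000001\nname: t\nis_a: d:0000000\n\n"
            "[Term]\nid: d:0000002\nname: t.c\n"
        )
        with pytest.raises(ModelError):
            read_obo(text)

    def test_four_level_hierarchy_rejected(self):
        text = (
            "format-version: 1.2\n\n[Term]\nid: d:0\nname: d\n\n"
            "[Term]\nid: d:1\nname: t\nis_a: d:0\n\n"
            "[Term]\nid: d:2\nname: t.c\nis_a: d:1\n\n"
            "[Term]\nid: d:3\nname: t.c.x\nis_a: d:2\n"
        )
        with pytest.raises(ModelError):
            read_obo(text)

    def test_independent_parser_sees_same_counts(self):
        obonet = pytest.importorskip("obonet")
        rng = random.Random(11)
        for _ in range(5):
            schema = random_schema(rng)
            model = build_model(schema)
            graph = obonet.read_obo(io.StringIO(write_obo(model)))
            assert graph.number_of_nodes() == model.term_count
            assert graph.number_of_edges() == model.term_count - 1


class TestLoadModel:
    @pytest.fixture
    def model(self):
        return build_model(
            SourceSchema(
                "CDB",
                [
                    SourceTable(
                        "patient",
                        [SourceColumn("age", "integer"), SourceColumn("height", "decimal"),
                         SourceColumn("weight", "decimal")],
                        "age",
                    )
                ],
            )
        )

    def test_load_counts(self, tmp_store, model):
        report = load_model(tmp_store, model)
        assert report.terms == 5
        assert report.edges == 4

    def test_conserves_row_counts(self, tmp_store, model):
        before = tmp_store.count("cvterm")
        load_model(tmp_store, model)
        assert tmp_store.count("cvterm") == before + model.term_count

    def test_replace_is_idempotent(self, tmp_store, model):
        load_model(tmp_store, model)
        snapshot = tmp_store.conn.execute(
            "SELECT name FROM cvterm ORDER BY name"
        ).fetchall()
        load_model(tmp_store, model, replace=True)
        assert tmp_store.conn.execute(
            "SELECT name FROM cvterm ORDER BY name"
        ).fetchall() == snapshot

    def test_conflict_without_replace(self, tmp_store, model):
        load_model(tmp_store, model)
        with pytest.raises(ModelConflictError):
            load_model(tmp_store, model)

    def test_columns_reachable_from_root_in_two_hops(self, tmp_store, model):
        load_model(tmp_store, model)
        is_a = tmp_store.internal_term("is_a")
        root = tmp_store.term_id("CDB", "CDB")
        one_hop = {
            r[0]
            for r in tmp_store.conn.execute(
                "SELECT subject_id FROM cvterm_relationship WHERE object_id = ? AND type_id = ?",
                (root, is_a),
            )
        }
        two_hop = set(one_hop)
        for t in one_hop:
            two_hop |= {
                r[0]
                for r in tmp_store.conn.execute(
                    "SELECT subject_id FROM cvterm_relationship WHERE object_id = ? AND type_id = ?",
                    (t, is_a),
                )
            }
        for term in model.column_terms:
            assert tmp_store.term_id("CDB", term.name) in two_hop

    def test_store_round_trip(self, tmp_store, model):
        load_model(tmp_store, model)
        assert model_from_store(tmp_store, "CDB") == model
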