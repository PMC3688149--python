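"""ETL: patients, typed facts, rank groups, parent links, conservation."""

import pytest

from iptrans.cdbmodel import SourceReader, build_model, extract_schema, load_model
from iptrans.etl import migrate
from iptrans.pipeline import run_migration
from iptrans.store import init_store
from iptrans.synthdata import SynthSpec, default_config, generate_cdb


@pytest.fixture
def migrated_tiny(tmp_store, tiny_source):
    schema = extract_schema(tiny_source.dir, "csv_dir", db_name=tiny_source.db_name)
    model = build_model(schema)
    load_model(tmp_store, model)
    reader = SourceReader(tiny_source.dir, "csv_dir")
    report = migrate(tmp_store, reader, model, tiny_source.config)
    return tmp_store, model, report


class TestWorkedExample:
    def test_patient_measurements_become_csd_rows(self, migrated_tiny):
        store, model, report = migrated_tiny
        assert report.patients_created == 1
        (pid, skey, _) = store.patients()[0]
        assert skey == "9"
        for col, expected in (("age", "58"), ("height", "1.72"), ("weight", "80.0")):
            tid = store.term_id("CDB", f"patient.{col}")
            rows = store.conn.execute(
                "SELECT value FROM csd WHERE patient_id = ? AND type_id = ?", (pid, tid)
            ).fetchall()
            assert rows == [(expected,)]

    def test_drugs_share_type_distinguished_by_rank(self, migrated_tiny):
        store, model, _ = migrated_tiny
        tid = store.term_id("CDB", "prescription.drug")
        rows = store.conn.execute(
            "SELECT value, rank FROM csd WHERE type_id = ? ORDER BY rank", (tid,)
        ).fetchall()
        assert rows == [("Carboplatin", 0), ("Decadron", 1), ("Furosemide", 2)]

    def test_dosage_anchored_to_carboplatin_via_parent(self, migrated_tiny):
        store, model, _ = migrated_tiny
        drug_tid = store.term_id("CDB", "prescription.drug")
        dose_tid = store.term_id("CDB", "prescription.dosage")
        (dose_parent,) = store.conn.execute(
            "SELECT parent_csd FROM csd WHERE type_id = ?", (dose_tid,)
        ).fetchone()
        parent = store.get_csd(dose_parent)
        assert parent.type_id == drug_tid
        assert parent.value == "Carboplatin"

    def test_null_cells_create_no_rows(self, migrated_tiny):
        store, model, report = migrated_tiny
        # two empty dosage cells in the prescription fixture
        assert report.cells_skipped_null == 2
        dose_tid = store.term_id("CDB", "prescription.dosage")
        assert (
            store.conn.execute(
                "SELECT COUNT(*) FROM csd WHERE type_id = ?", (dose_tid,)
            ).fetchone()[0]
            == 1
        )

    def test_integrity_clean_after_migration(self, migrated_tiny):
        store, _, _ = migrated_tiny
        assert store.integrity_check() == []


class TestConservation:
    def test_counts_match_manifest(self, seed1):
        m = seed1.manifest["expected"]
        report = run_migration(
            seed1.store, seed1.src_dir, "csv_dir", seed1.config,
            db_name=seed1.spec.db_name,
        ).migration
        assert report.patients_created == m["patients_created"]
        assert report.csd_created == m["csd_created"]
        assert report.patientprops_created == m["patientprops_created"]
        assert report.cells_skipped_null == m["cells_skipped_null"]
        assert report.key_cells == m["key_cells"]

    def test_conservation_law(self, seed1):
        # every cell of a patient-linked table is accounted for exactly once
        total_cells = sum(
            t["n_cells"]
            for name, t in seed1.manifest["tables"].items()
            if name not in seed1.config.reference_tables
        )
        m = seed1.manifest["expected"]
        assert (
            m["csd_created"]
            + m["patientprops_created"]
            + m["cells_skipped_null"]
            + m["key_cells"]
            == total_cells
        )

    def test_ranks_dense_per_patient_and_table(self, seed1):
        store = seed1.store
        db = seed1.spec.db_name
        per_patient = seed1.manifest["per_patient_rows"]
        key_tid = store.term_id(db, "visit.id")
        for skey, n_rows in per_patient["visit"].items():
            pid = store.conn.execute(
                "SELECT patient_id FROM patient WHERE source_key = ?", (skey,)
            ).fetchone()[0]
            ranks = {
                r[0]
                for r in store.conn.execute(
                    "SELECT rank FROM csd WHERE patient_id = ? AND type_id = ?",
                    (pid, key_tid),
                )
            }
            assert ranks == set(range(n_rows))

    def test_parent_links_stay_in_row_group(self, seed1):
        rows = seed1.store.conn.execute(
            "SELECT a.patient_id, a.rank, b.patient_id, b.rank FROM csd a"
            " JOIN csd b ON a.parent_csd = b.csd_id"
        ).fetchall()
        assert rows, "expected some parent-linked facts"
        for pa, ra, pb, rb in rows:
            assert (pa, ra) == (pb, rb)

    def test_rerun_is_deterministic(self, tmp_path):
        spec = SynthSpec(seed=5, n_patients=30)
        src = str(tmp_path / "src")
        generate_cdb(spec, src)
        config = default_config()

        def snapshot():
            store = init_store(str(tmp_path / "s.db"))
            run_migration(store, src, "csv_dir", config, db_name=spec.db_name)
            rows = []
            for table in ("patient", "patientprop", "csd", "csdprop"):
                rows.append(
                    store.conn.execute(f"SELECT * FROM {table} ORDER BY 1").fetchall()
                )
            store.close()
            return rows

        assert snapshot() == snapshot()


class TestErrorPaths:
    def test_unknown_patient_row_skipped_with_violation(self, tmp_store, tiny_source, tmp_path):
        import csv as csvmod

        with open(f"{tiny_source.dir}/prescription.csv", "a", newline="") as fh:
            csvmod.writer(fh, lineterminator="\n").writerow(["4", "777", "Cisplatin", ""])
        schema = extract_schema(tiny_source.dir, "csv_dir", db_name="CDB")
        model = build_model(schema)
        load_model(tmp_store, model)
        report = migrate(
            tmp_store, SourceReader(tiny_source.dir, "csv_dir"), model, tiny_source.config
        )
        assert any("unknown patient" in v.problem for v in report.violations)
        drug_tid = tmp_store.term_id("CDB", "prescription.drug")
        values = {
            r[0]
            for r in tmp_store.conn.execute(
                "SELECT value FROM csd WHERE type_id = ?", (drug_tid,)
            )
        }
        assert "Cisplatin" not in values

    def test_unparseable_cell_stored_as_text_with_violation(self, tmp_store, tmp_path):
        from conftest import write_csv
        from iptrans.etl import MigrationConfig
        from iptrans.cdbmodel import SourceColumn, SourceSchema, SourceTable

        src = tmp_path / "cdb2"
        src.mkdir()
        write_csv(src / "patient.csv", ["id", "age"], [["1", "fifty"]])
        schema = SourceSchema(
            "X", [SourceTable("patient", [SourceColumn("id", "integer"),
                                          SourceColumn("age", "integer")], "id")]
        )
        model = build_model(schema)
        load_model(tmp_store, model)
        config = MigrationConfig(patient_table="patient")
        report = migrate(tmp_store, SourceReader(str(src), "csv_dir"), model, config)
        assert any("not a valid integer" in v.problem for v in report.violations)
        tid = tmp_store.term_id("X", "patient.age")
        assert tmp_store.conn.execute(
            "SELECT value FROM csd WHERE type_id = ?", (tid,)
        ).fetchone()[0] == "fifty"
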