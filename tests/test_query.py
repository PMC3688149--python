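"""Query engine: planning, split-query execution, concept expansion,
patient <-> assay traversal and integrated export."""

import random

import pytest

from iptrans.cdbmodel import SourceReader, build_model, extract_schema, load_model
from iptrans.etl import load_expression, migrate
from iptrans.mapping import ReferenceOntology, add_mapping, create_ome
from iptrans.query import (
    And,
    Not,
    Or,
    Predicate,
    QueryError,
    TypeError_,
    assays_to_patients,
    export_integrated,
    parse_expr,
    patients_to_assays,
    plan,
    select_assays,
    select_patients,
)
from iptrans.synthdata import generate_expression, patients_with_group

from oracle import AttributeIndex, attribute_pool, evaluate, random_expression


@pytest.fixture(scope="module")
def rng():
    return random.Random(20240917)


@pytest.fixture(scope="session")
def seed1_expression(seed1):
    """Expression data generated for the seed-1 patients and loaded."""
    patients = patients_with_group(seed1.store, seed1.spec.db_name, "patients.sex")
    bundle = generate_expression(seed1.spec, patients)
    if seed1.store.count("assay") == 0:
        load_expression(seed1.store, bundle["tables"])
    return patients, bundle


class TestParseAndPlan:
    def test_sexpr_grammar(self):
        expr = parse_expr("(and (gt CDB:patients.age 60) (eq CDB:patients.sex M))")
        assert isinstance(expr, And)
        assert expr.children[0] == Predicate("CDB:patients.age", ">", "60")
        assert expr.children[1] == Predicate("CDB:patients.sex", "=", "M")

    def test_malformed_expressions_rejected(self):
        for bad in ["(xor (eq a b))", "(eq a 1", "(not (eq a 1) (eq b 2))", "()"]:
            with pytest.raises(QueryError):
                parse_expr(bad)

    def test_conjunction_plans_two_atoms(self, seed1):
        db = seed1.spec.db_name
        expr = And(
            (
                Predicate(f"{db}:patients.age", ">", "60"),
                Predicate(f"{db}:patients.sex", "=", "M"),
            )
        )
        qplan = plan(seed1.store, expr, db)
        assert qplan.root.op == "and"
        assert len(qplan.atoms) == 2

    def test_single_predicate_plans_one_atom_no_set_ops(self, seed1):
        db = seed1.spec.db_name
        qplan = plan(seed1.store, Predicate(f"{db}:patients.age", ">", "60"), db)
        assert qplan.root.op == "atom"
        assert len(qplan.atoms) == 1

    def test_ordering_on_text_attribute_rejected(self, seed1):
        db = seed1.spec.db_name
        with pytest.raises(TypeError_):
            plan(seed1.store, Predicate(f"{db}:patients.city", ">", "A"), db)

    def test_concept_leaf_expands_across_sources(self, seed1):
        db = seed1.spec.db_name
        cro = ReferenceOntology.toy()
        model = seed1.model
        ome = create_ome(cro, [(model.to_schema(), model)])
        add_mapping(ome, 0, "patients.age", "age")
        qplan = plan(seed1.store, Predicate("age", ">", "60"), db, ome=ome)
        assert len(qplan.atoms) == 1
        # map a second term to the same concept: the leaf becomes a union
        add_mapping(ome, 0, "visit.heart_rate", "age")
        qplan = plan(seed1.store, Predicate("age", ">", "60"), db, ome=ome)
        assert qplan.root.op == "or"
        assert len(qplan.atoms) == 2


class TestSelectPatients:
    def test_impossible_value_gives_empty_set(self, seed1):
        db = seed1.spec.db_name
        qplan = plan(
            seed1.store, Predicate(f"{db}:prescription.drug", "=", "NoSuchDrug"), db
        )
        assert select_patients(seed1.store, qplan) == set()

    def test_drug_predicate_finds_prescribed_patients(self, seed1):
        db = seed1.spec.db_name
        tid = seed1.store.term_id(db, "prescription.drug")
        expected = {
            r[0]
            for r in seed1.store.conn.execute(
                "SELECT DISTINCT patient_id FROM csd WHERE type_id = ? AND value = ?",
                (tid, "Carboplatin"),
            )
        }
        assert expected, "fixture should prescribe Carboplatin to someone"
        qplan = plan(
            seed1.store, Predicate(f"{db}:prescription.drug", "=", "Carboplatin"), db
        )
        assert select_patients(seed1.store, qplan) == expected

    def test_random_expressions_match_brute_force(self, seed1, rng):
        index = AttributeIndex(seed1)
        pool = attribute_pool(seed1)
        db = seed1.spec.db_name
        for _ in range(40):
            expr = random_expression(rng, pool, depth=3)
            got = select_patients(seed1.store, plan(seed1.store, expr, db))
            want = evaluate(index, expr)
            assert got == want, f"mismatch for {expr}"

    def test_de_morgan_identity(self, seed1, rng):
        pool = attribute_pool(seed1)
        db = seed1.spec.db_name
        for _ in range(20):
            a = random_expression(rng, pool, depth=2)
            b = random_expression(rng, pool, depth=2)
            lhs = select_patients(seed1.store, plan(seed1.store, Not(And((a, b))), db))
            rhs = select_patients(seed1.store, plan(seed1.store, Or((Not(a), Not(b))), db))
            assert lhs == rhs

    def test_all_ranks_mode_requires_every_instance(self, seed1):
        db = seed1.spec.db_name
        any_mode = select_patients(
            seed1.store,
            plan(seed1.store, Predicate(f"{db}:prescription.drug", "=", "Carboplatin"), db),
        )
        all_mode = select_patients(
            seed1.store,
            plan(
                seed1.store,
                Predicate(f"{db}:prescription.drug", "=", "Carboplatin", all_ranks=True),
                db,
            ),
        )
        assert all_mode <= any_mode


class TestTraversal:
    def test_patient_without_biomaterial_maps_to_nothing(self, tmp_store, tiny_source):
        model = build_model(extract_schema(tiny_source.dir, "csv_dir", db_name="CDB"))
        load_model(tmp_store, model)
        migrate(tmp_store, SourceReader(tiny_source.dir, "csv_dir"), model, tiny_source.config)
        (pid, _, _) = tmp_store.patients()[0]
        assert patients_to_assays(tmp_store, [pid]) == set()

    def test_adjointness_for_all_assayed_patients(self, seed1, seed1_expression):
        patients, _ = seed1_expression
        for p in patients:
            assays = patients_to_assays(seed1.store, [p["patient_id"]])
            assert assays
            assert p["patient_id"] in assays_to_patients(seed1.store, assays)

    def test_shared_two_channel_assay_returns_both_patients(self, tmp_store):
        cv = tmp_store.upsert_cv("CDB")
        p1 = tmp_store.add_patient("1", cv)
        p2 = tmp_store.add_patient("2", cv)
        tables = {
            "biomaterial": [{"name": "bm1"}, {"name": "bm2"}],
            "biomaterialprop": [
                {"biomaterial": "bm1", "value": p1},
                {"biomaterial": "bm2", "value": p2},
            ],
            "assay": [{"name": "two_channel"}],
            "assay_biomaterial": [
                {"assay": "two_channel", "biomaterial": "bm1"},
                {"assay": "two_channel", "biomaterial": "bm2"},
            ],
            "expression_value": [],
        }
        load_expression(tmp_store, tables)
        (aid,) = select_assays(tmp_store, "two_channel")
        assert assays_to_patients(tmp_store, [aid]) == {p1, p2}

    def test_unknown_ids_ignored_with_warning(self, seed1, seed1_expression):
        with pytest.warns(UserWarning, match="unknown"):
            assert patients_to_assays(seed1.store, [10**9]) == set()


class TestExport:
    def test_shape_and_cross_path_consistency(self, seed1, seed1_expression):
        patients, bundle = seed1_expression
        db = seed1.spec.db_name
        chosen = [p["patient_id"] for p in patients[:2]]
        assays = sorted(patients_to_assays(seed1.store, chosen))
        attrs = [f"{db}:patients.age", f"{db}:patients.sex"]
        df = export_integrated(seed1.store, chosen, attrs, assays, wide=True)
        assert len(df) == 2  # one (patient, assay) pair each
        assert list(df.columns[:5]) == [
            "patient_id", "assay_id", "assay_name", attrs[0], attrs[1],
        ]
        n_probes = bundle["manifest"]["n_probes"]
        assert len(df.columns) == 5 + n_probes
        # attribute values must agree with the bridge view for the same patient
        from iptrans.bridge import read_view

        view = {r["id"]: r for r in read_view(seed1.store, f"bl_{db}_patients")}
        keys = {pid: skey for pid, skey, _ in seed1.store.patients()}
        for _, row in df.iterrows():
            vrow = view[int(keys[row["patient_id"]])]
            exported = row[attrs[1]]
            assert (exported is None and vrow["sex"] is None) or exported == vrow["sex"]

    def test_empty_patient_set_gives_header_only(self, seed1, seed1_expression):
        df = export_integrated(seed1.store, [], [], [1], wide=True)
        assert len(df) == 0
        assert "patient_id" in df.columns

    def test_long_format(self, seed1, seed1_expression):
        patients, bundle = seed1_expression
        pid = patients[0]["patient_id"]
        assays = sorted(patients_to_assays(seed1.store, [pid]))
        df = export_integrated(seed1.store, [pid], [], assays, wide=False)
        assert set(df.columns) >= {"patient_id", "assay_id", "feature", "value"}
        assert len(df) == bundle["manifest"]["n_probes"]
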