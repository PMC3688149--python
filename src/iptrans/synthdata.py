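"""Deterministic synthetic legacy clinical databases and toy expression
data.

The generator emulates the structure of a clinical research database
at desk scale: a demographics table (the patient table, mixing stable
socio-demographic columns with measured attributes), temporal clinical
facts (visits, diagnoses — several rows per patient), a multivalued
prescription table whose dosage depends on its drug (exercising rank
groups and parent links), and a patient-independent drug catalogue
(exercising the reference-table path).  Default scale: 5 tables,
26 columns, 200 patients — large enough to exercise every migration
device, small enough for sub-minute tests.

Everything derives from one integer seed; the same seed yields
byte-identical files.  A ground-truth manifest records exact cell,
NULL and per-patient row counts — the oracle for the ETL conservation
law — plus the planted differential-expression signal.

The expression generator emits one biomaterial per patient (carrying
the patient id as a property) and one single-channel assay per
biomaterial, with independent Gaussian noise on log2 intensities and a
mean shift of ``effect_size`` on a flagged probe subset between the two
levels of a binary clinical attribute.  No array-effect structure is
simulated: the artifact tests linkage, not normalization.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
import random
import sqlite3
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .etl import MigrationConfig

_DRUGS = [
    ("Carboplatin", "L01"),
    ("Decadron", "H02"),
    ("Furosemide", "C03"),
    ("Cisplatin", "L01"),
    ("Paclitaxel", "L01"),
    ("Ondansetron", "A04"),
    ("Morphine", "N02"),
    ("Omeprazole", "A02"),
]
_CITIES = ["Riverside", "Lakewood", "Hillcrest", "Westfield", "Northport", "Easton"]
_ICD = ["C01", "C02.1", "C03.9", "C04", "C05.2", "C06", "C09.8", "C10.1"]
_ROUTES = ["oral", "iv"]
_NOTE_WORDS = [
    "stable", "improved", "worsened", "follow-up", "referred", "pain",
    "swelling", "biopsy", "margin", "recurrence",
]


@dataclass
class SynthSpec:
    """Parameters of one synthetic clinical database."""

    seed: int = 1
    n_patients: int = 200
    null_probability: float = 0.2
    max_visits: int = 3
    max_prescriptions: int = 4
    max_diagnoses: int = 2
    n_probes: int = 50
    n_flagged: int = 10
    group_attribute: str = "sex"  # binary column of the patient table
    effect_size: float = 1.0

    def __post_init__(self):
        if not (0 <= self.null_probability < 1):
            raise ValueError("null_probability must be in [0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_flagged > self.n_probes:
            raise ValueError("n_flagged cannot exceed n_probes")

    @property
    def db_name(self) -> str:
        return f"synthcdb{self.seed}"


def default_config() -> MigrationConfig:
    """The migration configuration matching the generated database."""
    return MigrationConfig(
        patient_table="patients",
        patientprop_columns=["sex", "birthdate", "address"],
        reference_tables=["drug_catalog"],
        patient_fk={
            "visit": "patient_id",
            "prescription": "patient_id",
            "diagnosis": "patient_id",
        },
        parent_columns={"prescription": {"dosage": "drug"}},
    )


def _maybe_null(rng: random.Random, p: float, value: str) -> str:
    return "" if rng.random() < p else value


def generate_cdb(spec: SynthSpec, out_dir: str) -> Dict:
    """Write the synthetic database as a CSV directory, an embedded
    SQLite copy and a SQL dump, plus the ground-truth manifest.

    Returns the manifest (also written to ``manifest.json``).
    """
    rng = random.Random(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    tables: Dict[str, Dict] = {}

    # patients --------------------------------------------------------
    header = ["id", "sex", "birthdate", "address", "city", "smoker", "age", "height", "weight"]
    rows = []
    for pid in range(1, spec.n_patients + 1):
        sex = rng.choice(["M", "F"])  # the group attribute; never NULL
        birth = f"{rng.randint(1935, 1990)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
        row = [
            str(pid),
            sex,
            _maybe_null(rng, spec.null_probability, birth),
            _maybe_null(rng, spec.null_probability, f"{rng.randint(1, 999)} Main St"),
            _maybe_null(rng, spec.null_probability, rng.choice(_CITIES)),
            _maybe_null(rng, spec.null_probability, rng.choice(["true", "false"])),
            _maybe_null(rng, spec.null_probability, str(rng.randint(30, 85))),
            _maybe_null(rng, spec.null_probability, f"{rng.uniform(1.50, 1.95):.2f}"),
            _maybe_null(rng, spec.null_probability, f"{rng.uniform(45, 120):.1f}"),
        ]
        rows.append(row)
    tables["patients"] = {"header": header, "rows": rows, "key": "id", "fk": None}

    # visit -----------------------------------------------------------
    header = ["id", "patient_id", "visit_date", "systolic_bp", "heart_rate", "note"]
    rows, rid = [], 1
    per_patient_visits: Dict[str, int] = {}
    for pid in range(1, spec.n_patients + 1):
        n = rng.randint(1, spec.max_visits)
        per_patient_visits[str(pid)] = n
        for _ in range(n):
            date = f"{rng.randint(2009, 2012)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
            rows.append(
                [
                    str(rid),
                    str(pid),
                    _maybe_null(rng, spec.null_probability, date),
                    _maybe_null(rng, spec.null_probability, str(rng.randint(90, 180))),
                    _maybe_null(rng, spec.null_probability, str(rng.randint(50, 110))),
                    _maybe_null(
                        rng, spec.null_probability,
                        " ".join(rng.sample(_NOTE_WORDS, 2)),
                    ),
                ]
            )
            rid += 1
    tables["visit"] = {"header": header, "rows": rows, "key": "id", "fk": "patient_id"}

    # prescription ----------------------------------------------------
    header = ["id", "patient_id", "drug", "dosage", "route"]
    rows, rid = [], 1
    per_patient_rx: Dict[str, int] = {}
    for pid in range(1, spec.n_patients + 1):
        n = rng.randint(0, spec.max_prescriptions)
        per_patient_rx[str(pid)] = n
        for _ in range(n):
            drug = _maybe_null(rng, spec.null_probability, rng.choice(_DRUGS)[0])
            # dosage depends on its drug: absent whenever the drug is
            dosage = "" if not drug else _maybe_null(
                rng, spec.null_probability, f"{rng.choice([10, 25, 50, 100, 150])} mg"
            )
            rows.append(
                [
                    str(rid),
                    str(pid),
                    drug,
                    dosage,
                    _maybe_null(rng, spec.null_probability, rng.choice(_ROUTES)),
                ]
            )
            rid += 1
    tables["prescription"] = {"header": header, "rows": rows, "key": "id", "fk": "patient_id"}

    # diagnosis -------------------------------------------------------
    header = ["id", "patient_id", "icd_code", "severity", "confirmed"]
    rows, rid = [], 1
    per_patient_dx: Dict[str, int] = {}
    for pid in range(1, spec.n_patients + 1):
        n = rng.randint(1, spec.max_diagnoses)
        per_patient_dx[str(pid)] = n
        for _ in range(n):
            rows.append(
                [
                    str(rid),
                    str(pid),
                    _maybe_null(rng, spec.null_probability, rng.choice(_ICD)),
                    _maybe_null(rng, spec.null_probability, str(rng.randint(1, 5))),
                    _maybe_null(rng, spec.null_probability, rng.choice(["true", "false"])),
                ]
            )
            rid += 1
    tables["diagnosis"] = {"header": header, "rows": rows, "key": "id", "fk": "patient_id"}

    # drug_catalog (reference) ---------------------------------------
    header = ["id", "name", "atc_class"]
    rows = [[str(i + 1), name, atc] for i, (name, atc) in enumerate(_DRUGS)]
    tables["drug_catalog"] = {"header": header, "rows": rows, "key": "id", "fk": None}

    _write_csvs(tables, out_dir)
    _write_sqlite(tables, os.path.join(out_dir, "cdb.sqlite"))
    _write_dump(tables, os.path.join(out_dir, "cdb.sql"))

    manifest = _build_manifest(
        spec, tables,
        {"visit": per_patient_visits, "prescription": per_patient_rx,
         "diagnosis": per_patient_dx},
    )
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


_SQL_TYPES = {
    "id": "INTEGER", "patient_id": "INTEGER", "age": "INTEGER",
    "systolic_bp": "INTEGER", "heart_rate": "INTEGER", "severity": "INTEGER",
    "height": "DECIMAL", "weight": "DECIMAL",
    "birthdate": "DATE", "visit_date": "DATE",
    "smoker": "BOOLEAN", "confirmed": "BOOLEAN",
}


def _write_csvs(tables: Dict, out_dir: str) -> None:
    for name, t in tables.items():
        path = os.path.join(out_dir, f"{name}.csv")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(t["header"])
            w.writerows(t["rows"])


def _write_sqlite(tables: Dict, path: str) -> None:
    if os.path.exists(path):
        os.remove(path)
    conn = sqlite3.connect(path)
    try:
        for name, t in tables.items():
            cols = ", ".join(
                f"{c} {_SQL_TYPES.get(c, 'TEXT')}" for c in t["header"]
            )
            conn.execute(f"CREATE TABLE {name} ({cols})")
            marks = ", ".join("?" * len(t["header"]))
            conn.executemany(
                f"INSERT INTO {name} VALUES ({marks})",
                [[None if c == "" else c for c in row] for row in t["rows"]],
            )
        conn.commit()
    finally:
        conn.close()


def _write_dump(tables: Dict, path: str) -> None:
    lines = []
    for name, t in tables.items():
        cols = ", ".join(f"{c} {_SQL_TYPES.get(c, 'TEXT')}" for c in t["header"])
        lines.append(f"CREATE TABLE {name} ({cols});")
        for row in t["rows"]:
            vals = ", ".join(
                "NULL" if c == "" else f"'{c.replace(chr(39), chr(39) * 2)}'" for c in row
            )
            lines.append(f"INSERT INTO {name} VALUES ({vals});")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _build_manifest(spec: SynthSpec, tables: Dict, per_patient: Dict) -> Dict:
    config = default_config()
    out: Dict = {
        "db_name": spec.db_name,
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "tables": {},
        "per_patient_rows": per_patient,
    }
    exp_csd = exp_pp = exp_null = exp_key = 0
    for name, t in tables.items():
        n_rows = len(t["rows"])
        n_cells = n_rows * len(t["header"])
        key_idx = t["header"].index(t["key"])
        fk_idx = t["header"].index(t["fk"]) if t["fk"] else None
        n_null = sum(1 for row in t["rows"] for c in row if c == "")
        out["tables"][name] = {
            "columns": t["header"],
            "key": t["key"],
            "fk": t["fk"],
            "n_rows": n_rows,
            "n_cells": n_cells,
            "n_null_cells": n_null,
        }
        if name in config.reference_tables:
            continue
        for row in t["rows"]:
            for i, cell in enumerate(row):
                if i == key_idx or i == fk_idx:
                    exp_key += 1
                elif cell == "":
                    exp_null += 1
                elif name == config.patient_table and t["header"][i] in config.patientprop_columns:
                    exp_pp += 1
                else:
                    exp_csd += 1
    out["expected"] = {
        "patients_created": len(tables[config.patient_table]["rows"]),
        "csd_created": exp_csd,
        "patientprops_created": exp_pp,
        "cells_skipped_null": exp_null,
        "key_cells": exp_key,
    }
    return out


def sha256_dir(out_dir: str) -> Dict[str, str]:
    """SHA-256 of every generated file except the SQLite copy (whose
    bytes depend on the library version; its *contents* are compared
    through extraction instead)."""
    out = {}
    for name in sorted(os.listdir(out_dir)):
        if name.endswith(".sqlite"):
            continue
        with open(os.path.join(out_dir, name), "rb") as fh:
            out[name] = hashlib.sha256(fh.read()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# expression data


def generate_expression(spec: SynthSpec, patients: List[Dict]) -> Dict:
    """Toy microarray tables for a set of migrated patients.

    ``patients`` is a list of dicts with keys ``patient_id`` (store
    surrogate id), ``source_key`` and ``group`` (the value of the binary
    group attribute, e.g. ``"M"``/``"F"``).  One biomaterial and one
    assay per patient; log2 intensities are N(8, 1) with the planted
    ``effect_size`` shift on the flagged probes for the second group
    level (levels ordered alphabetically).

    Returns {"tables": ..., "manifest": ...}; load the tables with
    :func:`iptrans.etl.load_expression`.
    """
    if not patients:
        raise ValueError("no patients to generate expression data for")
    rng = random.Random(spec.seed + 1_000_003)
    levels = sorted({str(p["group"]) for p in patients})
    if len(levels) != 2:
        raise ValueError(f"group attribute must be binary, found levels {levels}")
    probes = [f"P{i + 1:04d}" for i in range(spec.n_probes)]
    flagged = probes[: spec.n_flagged]
    tables: Dict[str, List[Dict]] = {
        "biomaterial": [],
        "biomaterialprop": [],
        "assay": [],
        "assay_biomaterial": [],
        "expression_value": [],
    }
    for p in patients:
        bm = f"bm_{p['source_key']}"
        ay = f"assay_{p['source_key']}"
        tables["biomaterial"].append({"name": bm})
        tables["biomaterialprop"].append({"biomaterial": bm, "value": p["patient_id"]})
        tables["assay"].append({"name": ay})
        tables["assay_biomaterial"].append({"assay": ay, "biomaterial": bm})
        shift = spec.effect_size if str(p["group"]) == levels[1] else 0.0
        for probe in probes:
            mu = 8.0 + (shift if probe in flagged else 0.0)
            tables["expression_value"].append(
                {"assay": ay, "feature": probe, "value": rng.gauss(mu, 1.0)}
            )
    manifest = {
        "n_probes": spec.n_probes,
        "flagged_probes": flagged,
        "group_attribute": spec.group_attribute,
        "group_levels": levels,
        "effect_size": spec.effect_size,
        "n_patients": len(patients),
    }
    return {"tables": tables, "manifest": manifest}


def patients_with_group(store, db_name: str, group_column: str) -> List[Dict]:
    """Fetch migrated patients with their group-attribute value.

    The group attribute is looked up among both ``patientprop`` and
    ``csd`` rows of the patient table's column term; patients lacking a
    value are skipped.
    """
    cv_id = store.cv_id(db_name)
    if cv_id is None:
        raise ValueError(f"no clinical database {db_name!r} in the store")
    term = store.term_id(db_name, group_column)
    if term is None:
        raise ValueError(f"no term {group_column!r} in {db_name!r}")
    out = []
    for pid, skey, _cv in store.patients(cv_id):
        row = None
        for table in ("patientprop", "csd"):
            row = store.conn.execute(
                f"SELECT value FROM {table} WHERE patient_id = ? AND type_id = ?"
                " ORDER BY rank LIMIT 1",
                (pid, term),
            ).fetchone()
            if row:
                break
        if row:
            out.append({"patient_id": pid, "source_key": skey, "group": row[0]})
    return out
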