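"""Extraction, transformation and load of legacy rows into the
Clinical Module.

The migration walks the source tables in a fixed order (patient table
first, then the remaining patient-linked tables, then the reference
tables, each group alphabetically) so a re-run produces an identical
store.  Every non-NULL cell becomes exactly one EAV row typed by its
column term; NULL cells produce no row (EAV sparsity — required for
faithful NULL reinstatement by the bridge views).

Disambiguation devices:

* ``rank`` — all facts extracted from one source row share one rank,
  the 0-based ordinal of that row among the patient's rows in that
  table; repeated attributes (one row per drug) are told apart by it.
* ``parent_csd`` — a configured child column (e.g. ``dosage``) is
  anchored to the fact from its declared anchor column (``drug``) in
  the same source row.

Legacy keys: the patient table's key becomes ``patient.source_key``;
other tables' key cells are migrated as *system* rows typed by the key
term, excluded from fact counts but required for exact round-trips.
Foreign keys to reference tables are stored verbatim as the fact value;
bridge views re-join by value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from ._canon import canonicalize, is_null
from .cdbmodel import ClinicalDatabaseModel, SourceReader, SourceSchema
from .store import Store


class ConfigError(Exception):
    """Migration configuration inconsistent with the schema."""


@dataclass
class MigrationConfig:
    """Column classification steering the migration.

    ``patientprop_columns`` hold facts that do not change over time
    (sex, birthdate, address) and land in ``patientprop``; every other
    patient-linked fact lands in ``csd``; ``reference_tables`` are
    patient-independent and land in ``csdprop``.  ``patient_fk`` names,
    per non-patient table, the column referencing the patient.
    ``parent_columns`` declares intra-row dependencies as
    ``{table: {child_column: anchor_column}}``.
    """

    patient_table: str
    patientprop_columns: List[str] = field(default_factory=list)
    reference_tables: List[str] = field(default_factory=list)
    patient_fk: Dict[str, str] = field(default_factory=dict)
    parent_columns: Dict[str, Dict[str, str]] = field(default_factory=dict)
    key_columns: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str) -> "MigrationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls(**data)

    def to_file(self, path: str) -> None:
        data = {
            "patient_table": self.patient_table,
            "patientprop_columns": self.patientprop_columns,
            "reference_tables": self.reference_tables,
            "patient_fk": self.patient_fk,
            "parent_columns": self.parent_columns,
            "key_columns": self.key_columns,
        }
        with open(path, "w", encoding="utf-8") as fh:
            if path.endswith(".json"):
                json.dump(data, fh, indent=2)
            else:
                yaml.safe_dump(data, fh, sort_keys=False)

    def validate(self, schema: SourceSchema) -> None:
        names = {t.name for t in schema.tables}
        if self.patient_table not in names:
            raise ConfigError(f"patient table {self.patient_table!r} not in schema")
        pt = schema.table(self.patient_table)
        for col in self.patientprop_columns:
            if col not in pt.column_names:
                raise ConfigError(f"patientprop column {col!r} not in {self.patient_table!r}")
        for t in self.reference_tables:
            if t not in names:
                raise ConfigError(f"reference table {t!r} not in schema")
        for tname, fk in self.patient_fk.items():
            if tname not in names or fk not in schema.table(tname).column_names:
                raise ConfigError(f"patient_fk {tname}.{fk} not in schema")
        for tname, pairs in self.parent_columns.items():
            if tname not in names:
                raise ConfigError(f"parent_columns table {tname!r} not in schema")
            cols = schema.table(tname).column_names
            for child, anchor in pairs.items():
                if child not in cols or anchor not in cols:
                    raise ConfigError(
                        f"parent pair {child!r}->{anchor!r} names unknown columns of {tname!r}"
                    )

    def linked_tables(self, schema: SourceSchema) -> List[str]:
        """Patient-linked tables other than the patient table, sorted."""
        return sorted(
            t.name
            for t in schema.tables
            if t.name != self.patient_table and t.name not in self.reference_tables
        )


@dataclass
class MigrationViolation:
    table: str
    row: int
    column: Optional[str]
    problem: str


@dataclass
class MigrationReport:
    patients_created: int = 0
    patientprops_created: int = 0
    csd_created: int = 0
    csdprop_created: int = 0
    cells_skipped_null: int = 0
    key_cells: int = 0  # key + patient-fk cells (system-handled, not facts)
    # reference tables are tallied apart so that the conservation law over
    # patient-linked tables stays exact
    ref_key_cells: int = 0
    ref_cells_skipped_null: int = 0
    stages: List[str] = field(default_factory=list)
    violations: List[MigrationViolation] = field(default_factory=list)

    def violations_tsv(self) -> str:
        lines = ["table\trow\tcolumn\tproblem"]
        for v in self.violations:
            lines.append(f"{v.table}\t{v.row}\t{v.column or ''}\t{v.problem}")
        return "\n".join(lines) + "\n"


def _term_ids(store: Store, model: ClinicalDatabaseModel) -> Dict[str, int]:
    ids = {}
    for term in model.terms:
        tid = store.term_id(model.db_name, term.name)
        if tid is None:
            raise ConfigError(
                f"model term {term.name!r} not loaded; run load_model first"
            )
        ids[term.name] = tid
    return ids


def _wipe_cdb(store: Store, cv_id: int) -> None:
    c = store.conn
    pids = [r[0] for r in c.execute("SELECT patient_id FROM patient WHERE cdb_cv_id = ?", (cv_id,))]
    if pids:
        marks = ",".join("?" * len(pids))
        csd_ids = [
            r[0] for r in c.execute(f"SELECT csd_id FROM csd WHERE patient_id IN ({marks})", pids)
        ]
        if csd_ids:
            cmarks = ",".join("?" * len(csd_ids))
            c.execute(
                f"DELETE FROM csd_relationship WHERE subject_id IN ({cmarks})"
                f" OR object_id IN ({cmarks})",
                csd_ids * 2,
            )
        c.execute(f"DELETE FROM csd WHERE patient_id IN ({marks})", pids)
        c.execute(f"DELETE FROM patientprop WHERE patient_id IN ({marks})", pids)
        c.execute(f"DELETE FROM appointment WHERE patient_id IN ({marks})", pids)
        c.execute(f"DELETE FROM patient WHERE patient_id IN ({marks})", pids)
    term_ids = [r[0] for r in c.execute("SELECT cvterm_id FROM cvterm WHERE cv_id = ?", (cv_id,))]
    if term_ids:
        marks = ",".join("?" * len(term_ids))
        c.execute(f"DELETE FROM csdprop WHERE type_id IN ({marks})", term_ids)


def migrate(
    store: Store,
    source: SourceReader,
    model: ClinicalDatabaseModel,
    config: MigrationConfig,
    replace: bool = True,
) -> MigrationReport:
    """Run the ETL stage: extract rows, canonicalize values, load the
    Clinical Module.  The model must already be loaded into the store.
    """
    schema = model.to_schema()
    config.validate(schema)
    cv_id = store.cv_id(model.db_name)
    if cv_id is None:
        raise ConfigError(f"model {model.db_name!r} not loaded into the store")
    if replace:
        _wipe_cdb(store, cv_id)
    terms = _term_ids(store, model)
    report = MigrationReport()
    report.stages.append("extract")

    # ---- patient table ------------------------------------------------
    pt = schema.table(config.patient_table)
    p_rows = source.read_table(pt.name)
    report.stages.append("transform")
    patient_ids: Dict[str, int] = {}  # canonical source key -> surrogate id
    key_dt = pt.column(pt.key_column).datatype

    def canon(table, row_idx, col, value, datatype):
        try:
            return canonicalize(value, datatype)
        except ValueError:
            report.violations.append(
                MigrationViolation(
                    table, row_idx, col, f"value {value!r} is not a valid {datatype}; stored as text"
                )
            )
            return str(value)

    for i, row in enumerate(p_rows):
        raw_key = row.get(pt.key_column)
        if is_null(raw_key):
            report.violations.append(
                MigrationViolation(pt.name, i, pt.key_column, "NULL patient key; row skipped")
            )
            continue
        key = canon(pt.name, i, pt.key_column, raw_key, key_dt)
        if key in patient_ids:
            report.violations.append(
                MigrationViolation(pt.name, i, pt.key_column, f"duplicate patient key {key!r}; row skipped")
            )
            continue
        pid = store.add_patient(key, cv_id)
        patient_ids[key] = pid
        report.patients_created += 1
        report.key_cells += 1
        for col in pt.columns:
            if col.name == pt.key_column:
                continue
            value = row.get(col.name)
            if is_null(value):
                report.cells_skipped_null += 1
                continue
            cvalue = canon(pt.name, i, col.name, value, col.datatype)
            type_id = terms[f"{pt.name}.{col.name}"]
            if col.name in config.patientprop_columns:
                store.add_patientprop(pid, type_id, cvalue, rank=0)
                report.patientprops_created += 1
            else:
                store.add_csd(pid, type_id, cvalue, rank=0)
                report.csd_created += 1

    # ---- other patient-linked tables ----------------------------------
    for tname in config.linked_tables(schema):
        table = schema.table(tname)
        fk = config.patient_fk.get(tname)
        if fk is None:
            raise ConfigError(f"table {tname!r} has no patient_fk declared")
        parent_pairs = config.parent_columns.get(tname, {})
        rank_counter: Dict[int, int] = {}
        fk_dt = table.column(fk).datatype
        for i, row in enumerate(source.read_table(tname)):
            raw_fk = row.get(fk)
            if is_null(raw_fk):
                report.violations.append(
                    MigrationViolation(tname, i, fk, "NULL patient reference; row skipped")
                )
                continue
            fk_val = canon(tname, i, fk, raw_fk, fk_dt)
            pid = patient_ids.get(fk_val)
            if pid is None:
                report.violations.append(
                    MigrationViolation(tname, i, fk, f"unknown patient {fk_val!r}; row skipped")
                )
                continue
            rank = rank_counter.get(pid, 0)
            rank_counter[pid] = rank + 1
            report.key_cells += 1  # the fk cell, carried by the patient link
            created: Dict[str, int] = {}  # column -> csd_id for this source row
            deferred = []  # parent-linked children inserted after anchors
            for col in table.columns:
                if col.name == fk:
                    continue
                value = row.get(col.name)
                if col.name == table.key_column:
                    report.key_cells += 1
                    if is_null(value):
                        continue
                    cvalue = canon(tname, i, col.name, value, col.datatype)
                    created[col.name] = store.add_csd(
                        pid, terms[f"{tname}.{col.name}"], cvalue, rank=rank
                    )
                    continue
                if is_null(value):
                    report.cells_skipped_null += 1
                    continue
                cvalue = canon(tname, i, col.name, value, col.datatype)
                if col.name in parent_pairs:
                    deferred.append((col.name, cvalue))
                    continue
                created[col.name] = store.add_csd(
                    pid, terms[f"{tname}.{col.name}"], cvalue, rank=rank
                )
                report.csd_created += 1
            for cname, cvalue in deferred:
                anchor = parent_pairs[cname]
                parent_id = created.get(anchor)
                if parent_id is None:
                    report.violations.append(
                        MigrationViolation(
                            tname, i, cname, f"anchor column {anchor!r} is NULL; stored without parent"
                        )
                    )
                created[cname] = store.add_csd(
                    pid, terms[f"{tname}.{cname}"], cvalue, rank=rank, parent_csd=parent_id
                )
                report.csd_created += 1

    # ---- reference tables ---------------------------------------------
    for tname in sorted(config.reference_tables):
        table = schema.table(tname)
        for i, row in enumerate(source.read_table(tname)):
            for col in table.columns:
                value = row.get(col.name)
                if col.name == table.key_column:
                    report.ref_key_cells += 1
                    if is_null(value):
                        continue
                    cvalue = canon(tname, i, col.name, value, col.datatype)
                    store.add_csdprop(terms[f"{tname}.{col.name}"], cvalue, rank=i)
                    continue
                if is_null(value):
                    report.ref_cells_skipped_null += 1
                    continue
                cvalue = canon(tname, i, col.name, value, col.datatype)
                store.add_csdprop(terms[f"{tname}.{col.name}"], cvalue, rank=i)
                report.csdprop_created += 1

    report.stages.append("load")
    store.commit()
    return report


def attach_relationship(
    store: Store, subject_csd: int, object_csd: int, rel_term_id: int
) -> int:
    """Link two clinical facts through ``csd_relationship`` — the
    alternative to ``parent_csd`` for cross-record relationships."""
    return store.add_csd_relationship(subject_csd, object_csd, rel_term_id)


# ---------------------------------------------------------------------------
# expression loading (microarray subset)


def load_expression(store: Store, tables: Dict[str, List[Dict]]) -> Dict[str, int]:
    """Load biomaterial / assay / expression tables into the store.

    ``tables`` maps table name to rows as produced by
    :func:`iptrans.synthdata.generate_expression` (or any loader using
    the same shapes).  The patient link travels as a ``patient_id``
    property on the biomaterial.
    """
    pid_term = store.internal_term("patient_id")
    bm_ids: Dict[str, int] = {}
    as_ids: Dict[str, int] = {}
    counts = {"biomaterial": 0, "assay": 0, "assay_biomaterial": 0, "expression_value": 0}
    for row in tables.get("biomaterial", []):
        cur = store.conn.execute("INSERT INTO biomaterial (name) VALUES (?)", (row["name"],))
        bm_ids[row["name"]] = cur.lastrowid
        counts["biomaterial"] += 1
    for row in tables.get("biomaterialprop", []):
        store.conn.execute(
            "INSERT INTO biomaterialprop (biomaterial_id, type_id, value) VALUES (?, ?, ?)",
            (bm_ids[row["biomaterial"]], pid_term, str(row["value"])),
        )
    for row in tables.get("assay", []):
        cur = store.conn.execute("INSERT INTO assay (name) VALUES (?)", (row["name"],))
        as_ids[row["name"]] = cur.lastrowid
        counts["assay"] += 1
    for row in tables.get("assay_biomaterial", []):
        store.conn.execute(
            "INSERT INTO assay_biomaterial (assay_id, biomaterial_id) VALUES (?, ?)",
            (as_ids[row["assay"]], bm_ids[row["biomaterial"]]),
        )
        counts["assay_biomaterial"] += 1
    for row in tables.get("expression_value", []):
        store.conn.execute(
            "INSERT INTO expression_value (assay_id, feature_name, value) VALUES (?, ?, ?)",
            (as_ids[row["assay"]], row["feature"], float(row["value"])),
        )
        counts["expression_value"] += 1
    store.commit()
    return counts
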