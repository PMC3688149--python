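"""Bridge layer: views that pivot EAV rows back into the legacy shape.

For each source table a view ``bl_<db>_<table>`` reconstructs the
original rows, so queries and tools written for the legacy database run
unchanged against the integrated store.  The pivot uses conditional
aggregation grouped by (patient, rank) — one scan of ``csd`` per view,
regardless of how many columns the view has.  Passing
``materialize=True`` additionally writes each view out as a physical
table (``<view>_mat``), trading redundancy for query speed.

Row reconstruction:

* the patient table pivots ``patientprop`` and rank-0 ``csd`` rows,
  keyed by ``patient.source_key``;
* other patient-linked tables pivot ``csd`` by (patient, rank); the
  patient-reference column is refilled from ``source_key`` and the
  legacy key from its system row;
* reference tables pivot ``csdprop`` by rank;
* NULL cells reappear as NULL (no EAV row was stored for them);
* integer/decimal columns are CAST so comparisons behave numerically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from ._canon import canonicalize, cast_sql, is_null
from .cdbmodel import ClinicalDatabaseModel, SourceSchema
from .etl import MigrationConfig
from .store import Store


class BridgeError(Exception):
    pass


@dataclass
class BridgeView:
    view_name: str
    table_name: str
    columns: List[str]
    definition: str
    materialized: bool = False

    @property
    def materialized_name(self) -> str:
        return f"{self.view_name}_mat"


def _ident(name: str) -> str:
    """Quote an identifier for the view DDL."""
    return '"' + name.replace('"', '""') + '"'


def _sanitize(name: str) -> str:
    return re.sub(r"\W", "_", name)


def build_bridge(
    store: Store,
    model: ClinicalDatabaseModel,
    config: MigrationConfig,
    materialize: bool = False,
) -> List[BridgeView]:
    """Compile and create one bridge view per source table."""
    schema = model.to_schema()
    config.validate(schema)
    cv_id = store.cv_id(model.db_name)
    if cv_id is None:
        raise BridgeError(f"model {model.db_name!r} is not loaded")
    terms = {
        t.name: store.term_id(model.db_name, t.name) for t in model.terms
    }
    if any(v is None for v in terms.values()):
        raise BridgeError(f"model {model.db_name!r} is not fully loaded")
    views = []
    existing = set(store.table_names()) | {
        r[0] for r in store.conn.execute("SELECT name FROM sqlite_master WHERE type='view'")
    }
    for table in schema.tables:
        vname = f"bl_{_sanitize(model.db_name)}_{_sanitize(table.name)}"
        if vname in existing:
            raise BridgeError(
                f"name {vname!r} already exists; drop it or rename the database/table"
            )
        if table.name == config.patient_table:
            sql = _patient_view_sql(table, config, terms, cv_id)
        elif table.name in config.reference_tables:
            sql = _reference_view_sql(table, terms)
        else:
            sql = _linked_view_sql(table, config, terms, cv_id)
        store.conn.execute(f"CREATE VIEW {_ident(vname)} AS {sql}")
        view = BridgeView(vname, table.name, table.column_names, sql, materialize)
        if materialize:
            store.conn.execute(
                f"CREATE TABLE {_ident(view.materialized_name)} AS SELECT * FROM {_ident(vname)}"
            )
        views.append(view)
    store.commit()
    return views


def drop_bridge(store: Store, model: ClinicalDatabaseModel) -> int:
    """Drop all bridge views (and materializations) of a database."""
    prefix = f"bl_{_sanitize(model.db_name)}_"
    n = 0
    for kind in ("view", "table"):
        names = [
            r[0]
            for r in store.conn.execute(
                "SELECT name FROM sqlite_master WHERE type=? AND name LIKE ?",
                (kind, prefix + "%"),
            )
        ]
        for name in names:
            store.conn.execute(f"DROP {kind.upper()} {_ident(name)}")
            n += 1
    store.commit()
    return n


def _patient_view_sql(table, config: MigrationConfig, terms, cv_id: int) -> str:
    cols = []
    for col in table.columns:
        if col.name == table.key_column:
            cols.append(f"{cast_sql('p.source_key', col.datatype)} AS {_ident(col.name)}")
            continue
        tid = terms[f"{table.name}.{col.name}"]
        src = "patientprop" if col.name in config.patientprop_columns else "csd"
        sub = (
            f"(SELECT x.value FROM {src} x WHERE x.patient_id = p.patient_id"
            f" AND x.type_id = {tid} AND x.rank = 0)"
        )
        cols.append(f"{cast_sql(sub, col.datatype)} AS {_ident(col.name)}")
    return (
        "SELECT " + ", ".join(cols) + f" FROM patient p WHERE p.cdb_cv_id = {cv_id}"
    )


def _linked_view_sql(table, config: MigrationConfig, terms, cv_id: int) -> str:
    fk = config.patient_fk[table.name]
    type_ids = [
        terms[f"{table.name}.{c.name}"] for c in table.columns if c.name != fk
    ]
    cols = []
    for col in table.columns:
        if col.name == fk:
            cols.append(f"{cast_sql('MAX(p.source_key)', col.datatype)} AS {_ident(col.name)}")
            continue
        tid = terms[f"{table.name}.{col.name}"]
        expr = f"MAX(CASE WHEN c.type_id = {tid} THEN c.value END)"
        cols.append(f"{cast_sql(expr, col.datatype)} AS {_ident(col.name)}")
    in_list = ", ".join(str(t) for t in type_ids)
    return (
        "SELECT "
        + ", ".join(cols)
        + " FROM csd c JOIN patient p ON p.patient_id = c.patient_id"
        + f" WHERE p.cdb_cv_id = {cv_id} AND c.type_id IN ({in_list})"
        + " GROUP BY c.patient_id, c.rank"
    )


def _reference_view_sql(table, terms) -> str:
    type_ids = [terms[f"{table.name}.{c.name}"] for c in table.columns]
    cols = []
    for col in table.columns:
        tid = terms[f"{table.name}.{col.name}"]
        expr = f"MAX(CASE WHEN type_id = {tid} THEN value END)"
        cols.append(f"{cast_sql(expr, col.datatype)} AS {_ident(col.name)}")
    in_list = ", ".join(str(t) for t in type_ids)
    return (
        "SELECT "
        + ", ".join(cols)
        + f" FROM csdprop WHERE type_id IN ({in_list}) GROUP BY rank"
    )


# ---------------------------------------------------------------------------
# round-trip comparison


@dataclass
class CellDiff:
    key: object
    column: str
    expected: object
    actual: object


@dataclass
class DiffReport:
    table: str
    structural: Optional[str] = None  # column-set mismatch description
    missing_keys: List[object] = field(default_factory=list)
    extra_keys: List[object] = field(default_factory=list)
    cell_diffs: List[CellDiff] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return (
            self.structural is None
            and not self.missing_keys
            and not self.extra_keys
            and not self.cell_diffs
        )

    @property
    def size(self) -> int:
        return (
            (1 if self.structural else 0)
            + len(self.missing_keys)
            + len(self.extra_keys)
            + len(self.cell_diffs)
        )


def _canon_cell(value, datatype: str):
    if is_null(value):
        return None
    try:
        return canonicalize(str(value), datatype)
    except ValueError:
        return str(value)


def compare_tables(
    view_rows: List[dict],
    source_rows: List[dict],
    key: str,
    datatypes: Optional[Dict[str, str]] = None,
    table: str = "",
    max_diffs: int = 20,
) -> DiffReport:
    """Diff two row sets cell by cell, canonicalized, ignoring row order.

    Rows are matched on the key column (ties broken by full-row sort, so
    duplicate keys still compare as multisets).  A column-set mismatch
    yields a structural diff, not a cell diff.
    """
    report = DiffReport(table=table)
    cols_a = set(view_rows[0]) if view_rows else None
    cols_b = set(source_rows[0]) if source_rows else None
    if cols_a is not None and cols_b is not None and cols_a != cols_b:
        report.structural = (
            f"column sets differ: only-left={sorted(cols_a - cols_b)},"
            f" only-right={sorted(cols_b - cols_a)}"
        )
        return report
    columns = sorted(cols_a or cols_b or set())
    datatypes = datatypes or {}

    def canon_rows(rows):
        out = []
        for r in rows:
            out.append(
                tuple(_canon_cell(r.get(c), datatypes.get(c, "text")) for c in columns)
            )
        return sorted(out, key=lambda t: tuple((x is None, str(x)) for x in t))

    ca, cb = canon_rows(view_rows), canon_rows(source_rows)
    if ca == cb:
        return report
    ki = columns.index(key) if key in columns else 0
    from collections import Counter

    ca_c, cb_c = Counter(ca), Counter(cb)
    only_a = list((ca_c - cb_c).elements())
    only_b = list((cb_c - ca_c).elements())
    # pair off rows with the same key to report cell-level diffs
    by_key_b = {}
    for row in only_b:
        by_key_b.setdefault(row[ki], []).append(row)
    for row in only_a:
        matches = by_key_b.get(row[ki])
        if matches:
            other = matches.pop(0)
            for c, (x, y) in zip(columns, zip(row, other)):
                if x != y and len(report.cell_diffs) < max_diffs:
                    report.cell_diffs.append(CellDiff(row[ki], c, y, x))
        else:
            report.extra_keys.append(row[ki])
    for rows in by_key_b.values():
        report.missing_keys.extend(r[ki] for r in rows)
    return report


def read_view(store: Store, view_name: str) -> List[dict]:
    cur = store.conn.execute(f"SELECT * FROM {_ident(view_name)}")
    cols = [d[0] for d in cur.description]
    return [dict(zip(cols, row)) for row in cur.fetchall()]


def verify_roundtrip(
    store: Store,
    model: ClinicalDatabaseModel,
    config: MigrationConfig,
    source,
    views: Optional[List[BridgeView]] = None,
) -> List[DiffReport]:
    """Compare every bridge view against the original source table."""
    schema = model.to_schema()
    if views is None:
        views = [
            BridgeView(
                f"bl_{_sanitize(model.db_name)}_{_sanitize(t.name)}",
                t.name,
                t.column_names,
                "",
            )
            for t in schema.tables
        ]
    reports = []
    for view in views:
        table = schema.table(view.table_name)
        datatypes = {c.name: c.datatype for c in table.columns}
        source_rows = source.read_table(table.name)
        view_rows = read_view(store, view.view_name)
        reports.append(
            compare_tables(
                view_rows, source_rows, table.key_column, datatypes, table=table.name
            )
        )
    return reports
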