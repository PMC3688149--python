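"""Clinical database models: schema extraction, the three-level model,
OBO serialization, and loading into the controlled-vocabulary tables.

A legacy clinical source (a directory of CSV files, an embedded SQLite
database, or a SQL dump) is first described by a :class:`SourceSchema`.
From it a :class:`ClinicalDatabaseModel` is built — a strict three-level
hierarchy of terms: the root (by convention the database name), one term
per table, one term per column.  The model is the source's formal
description; serialized as OBO it travels between tools, and loaded into
the ``cv``/``cvterm`` tables it types every migrated fact.
"""

from __future__ import annotations

import csv
import glob
import os
import re
import sqlite3
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from . import obo as obomod
from ._canon import DATATYPES, infer_datatype
from .store import INTERNAL_CV, Store

DATATYPE_PROP = "datatype"
IS_KEY_PROP = "is_key"


class SchemaError(Exception):
    """Invalid or unreadable source schema."""


class ModelError(Exception):
    """A hierarchy that is not a valid three-level model."""


# ---------------------------------------------------------------------------
# source schemas


@dataclass(frozen=True)
class SourceColumn:
    name: str
    datatype: str = "text"

    def __post_init__(self):
        if self.datatype not in DATATYPES:
            raise SchemaError(f"unknown datatype {self.datatype!r} for column {self.name!r}")


@dataclass
class SourceTable:
    name: str
    columns: List[SourceColumn]
    key_column: str

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate column names in table {self.name!r}")
        if self.key_column not in names:
            raise SchemaError(
                f"key column {self.key_column!r} not among columns of table {self.name!r}"
            )

    def column(self, name: str) -> SourceColumn:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def column_names(self) -> List[str]:
        return [c.name for c in self.columns]


@dataclass
class SourceSchema:
    db_name: str
    tables: List[SourceTable] = field(default_factory=list)

    def __post_init__(self):
        names = [t.name for t in self.tables]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate table names in schema {self.db_name!r}")

    def table(self, name: str) -> SourceTable:
        for t in self.tables:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def n_columns(self) -> int:
        return sum(len(t.columns) for t in self.tables)


def default_key_column(table_name: str, column_names: List[str]) -> str:
    """Row-identifier heuristic: ``id``, then ``<table>_id``, else the
    first column.  Overridable through the migration config."""
    if "id" in column_names:
        return "id"
    if f"{table_name}_id" in column_names:
        return f"{table_name}_id"
    return column_names[0]


# -- extraction -------------------------------------------------------------

_SQL_TYPE_MAP = {
    "INT": "integer",
    "INTEGER": "integer",
    "SMALLINT": "integer",
    "BIGINT": "integer",
    "REAL": "decimal",
    "FLOAT": "decimal",
    "DOUBLE": "decimal",
    "DECIMAL": "decimal",
    "NUMERIC": "decimal",
    "DATE": "date",
    "BOOLEAN": "boolean",
    "BOOL": "boolean",
    "TEXT": "text",
    "VARCHAR": "text",
    "CHAR": "text",
    "CLOB": "text",
}


def _map_sql_type(sql_type: str) -> str:
    base = re.sub(r"\(.*\)", "", sql_type).strip().upper()
    base = base.split()[0] if base else ""
    if base in _SQL_TYPE_MAP:
        return _SQL_TYPE_MAP[base]
    raise SchemaError(f"unsupported SQL type {sql_type!r}; supported: {sorted(_SQL_TYPE_MAP)}")


def extract_schema(
    source: str,
    kind: str,
    key_overrides: Optional[Dict[str, str]] = None,
    db_name: Optional[str] = None,
) -> SourceSchema:
    """Describe a legacy source as a :class:`SourceSchema`.

    ``kind`` is one of ``csv_dir``, ``embedded_db``, ``sql_dump``.  CSV
    datatypes are inferred cell-by-cell (see :func:`infer_datatype`);
    database and dump datatypes are read from the DDL.
    """
    key_overrides = key_overrides or {}
    if kind == "csv_dir":
        return _extract_csv_dir(source, key_overrides, db_name)
    if kind == "embedded_db":
        return _extract_embedded_db(source, key_overrides, db_name)
    if kind == "sql_dump":
        return _extract_sql_dump(source, key_overrides, db_name)
    raise SchemaError(f"unknown source kind {kind!r}")


def _extract_csv_dir(path: str, key_overrides, db_name) -> SourceSchema:
    if not os.path.isdir(path):
        raise SchemaError(f"not a directory: {path}")
    tables = []
    for fname in sorted(glob.glob(os.path.join(path, "*.csv"))):
        tname = os.path.splitext(os.path.basename(fname))[0]
        with open(fname, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise SchemaError(f"CSV file {fname} has no header row")
            if not header or any(not h.strip() for h in header):
                raise SchemaError(f"CSV file {fname} has an invalid header row")
            rows = list(reader)
        columns = []
        for i, col in enumerate(header):
            cells = [r[i] if i < len(r) else "" for r in rows]
            columns.append(SourceColumn(col, infer_datatype(cells)))
        key = key_overrides.get(tname) or default_key_column(tname, header)
        tables.append(SourceTable(tname, columns, key))
    return SourceSchema(db_name or os.path.basename(os.path.normpath(path)), tables)


def _extract_embedded_db(path: str, key_overrides, db_name) -> SourceSchema:
    if not os.path.exists(path):
        raise SchemaError(f"no such file: {path}")
    conn = sqlite3.connect(path)
    try:
        names = [
            r[0]
            for r in conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
                " AND name NOT LIKE 'sqlite_%' ORDER BY name"
            )
        ]
        tables = []
        for tname in names:
            info = conn.execute(f"PRAGMA table_info({tname})").fetchall()
            columns = [SourceColumn(row[1], _map_sql_type(row[2] or "TEXT")) for row in info]
            header = [c.name for c in columns]
            key = key_overrides.get(tname) or default_key_column(tname, header)
            tables.append(SourceTable(tname, columns, key))
    finally:
        conn.close()
    return SourceSchema(db_name or os.path.splitext(os.path.basename(path))[0], tables)


_CREATE_RE = re.compile(
    r"^CREATE\s+TABLE\s+(?:IF\s+NOT\s+EXISTS\s+)?[\"`]?(\w+)[\"`]?\s*\((.*)\)\s*$",
    re.IGNORECASE | re.DOTALL,
)
_INSERT_RE = re.compile(
    r"^INSERT\s+INTO\s+[\"`]?(\w+)[\"`]?\s*(?:\(([^)]*)\))?\s*VALUES\s*(.*)$",
    re.IGNORECASE | re.DOTALL,
)


def _split_top_level(text: str, sep: str = ",") -> List[str]:
    parts, depth, buf, quote = [], 0, [], None
    for ch in text:
        if quote:
            buf.append(ch)
            if ch == quote:
                quote = None
            continue
        if ch in ("'", '"'):
            quote = ch
            buf.append(ch)
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    tail = "".join(buf).strip()
    if tail:
        parts.append(tail)
    return parts


_CONSTRAINT_WORDS = ("PRIMARY", "FOREIGN", "UNIQUE", "CHECK", "CONSTRAINT")


def _parse_sql_dump(text: str):
    """Parse the supported dump subset: CREATE TABLE and INSERT statements.

    Vendor-specific syntax is rejected loudly rather than half-parsed.
    Returns (tables, rows): column definitions per table and the inserted
    row values per table, in statement order.
    """
    # strip -- comments
    lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith("--")]
    statements = [s.strip() for s in _split_top_level("\n".join(lines), ";") if s.strip()]
    tables: Dict[str, List[SourceColumn]] = {}
    rows: Dict[str, List[List[Optional[str]]]] = {}
    columns_order: Dict[str, List[str]] = {}
    for stmt in statements:
        m = _CREATE_RE.match(stmt)
        if m:
            tname, body = m.group(1), m.group(2)
            if tname in tables:
                raise SchemaError(f"duplicate CREATE TABLE for {tname!r}")
            cols = []
            for item in _split_top_level(body):
                first = item.split()[0].upper() if item.split() else ""
                if first in _CONSTRAINT_WORDS:
                    continue  # table-level constraints carry no column
                parts = item.split()
                if len(parts) < 2:
                    raise SchemaError(f"cannot parse column definition {item!r} in {tname!r}")
                cname = parts[0].strip('"`')
                cols.append(SourceColumn(cname, _map_sql_type(parts[1])))
            tables[tname] = cols
            columns_order[tname] = [c.name for c in cols]
            rows[tname] = []
            continue
        m = _INSERT_RE.match(stmt)
        if m:
            tname = m.group(1)
            if tname not in tables:
                raise SchemaError(f"INSERT into unknown table {tname!r}")
            values_part = m.group(3).strip()
            for tup in _split_top_level(values_part):
                tup = tup.strip()
                if not (tup.startswith("(") and tup.endswith(")")):
                    raise SchemaError(f"cannot parse VALUES tuple {tup!r}")
                cells = []
                for cell in _split_top_level(tup[1:-1]):
                    cell = cell.strip()
                    if cell.upper() == "NULL":
                        cells.append(None)
                    elif cell.startswith("'") and cell.endswith("'"):
                        cells.append(cell[1:-1].replace("''", "'"))
                    else:
                        cells.append(cell)
                if m.group(2):
                    names = [c.strip().strip('"`') for c in m.group(2).split(",")]
                    row = dict(zip(names, cells))
                    cells = [row.get(c) for c in columns_order[tname]]
                rows[tname].append(cells)
            continue
        raise SchemaError(f"unsupported SQL statement (only CREATE TABLE / INSERT): {stmt[:60]!r}")
    return tables, rows


def _extract_sql_dump(path: str, key_overrides, db_name) -> SourceSchema:
    if not os.path.exists(path):
        raise SchemaError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        tables, _rows = _parse_sql_dump(fh.read())
    out = []
    for tname in sorted(tables):
        cols = tables[tname]
        header = [c.name for c in cols]
        key = key_overrides.get(tname) or default_key_column(tname, header)
        out.append(SourceTable(tname, cols, key))
    name = db_name or os.path.splitext(os.path.basename(path))[0]
    return SourceSchema(name, out)


# ---------------------------------------------------------------------------
# reading source rows (shared with the ETL stage)


class SourceReader:
    """Uniform row access to a legacy source, whatever its kind.

    ``read_table`` yields rows as dicts in source order; cells are text
    or None (empty CSV cells and SQL NULLs both map to None).
    """

    def __init__(self, source: str, kind: str):
        self.source = source
        self.kind = kind
        if kind == "sql_dump":
            with open(source, encoding="utf-8") as fh:
                self._dump_tables, self._dump_rows = _parse_sql_dump(fh.read())

    def read_table(self, name: str) -> List[Dict[str, Optional[str]]]:
        if self.kind == "csv_dir":
            fname = os.path.join(self.source, f"{name}.csv")
            with open(fname, newline="", encoding="utf-8") as fh:
                reader = csv.DictReader(fh)
                return [
                    {k: (None if v == "" else v) for k, v in row.items()} for row in reader
                ]
        if self.kind == "embedded_db":
            conn = sqlite3.connect(self.source)
            try:
                conn.row_factory = sqlite3.Row
                rows = conn.execute(f"SELECT * FROM {name}").fetchall()
                return [
                    {k: (None if row[k] is None else str(row[k])) for k in row.keys()}
                    for row in rows
                ]
            finally:
                conn.close()
        if self.kind == "sql_dump":
            cols = [c.name for c in self._dump_tables[name]]
            return [dict(zip(cols, row)) for row in self._dump_rows[name]]
        raise SchemaError(f"unknown source kind {self.kind!r}")


# ---------------------------------------------------------------------------
# the three-level model


@dataclass(frozen=True)
class ModelTerm:
    id: str
    name: str
    parent_id: Optional[str] = None  # None only for the root
    datatype: Optional[str] = None  # set only on column terms
    is_key: bool = False


@dataclass
class ClinicalDatabaseModel:
    """The three-level hierarchy describing one legacy database.

    Level 1 is the root (named after the database), level 2 the tables,
    level 3 the columns; column terms are qualified ``table.column`` so
    two tables sharing a column name never collide in the vocabulary.
    """

    db_name: str
    terms: List[ModelTerm]

    @property
    def root(self) -> ModelTerm:
        return self.terms[0]

    @property
    def table_terms(self) -> List[ModelTerm]:
        return [t for t in self.terms if t.parent_id == self.root.id]

    @property
    def column_terms(self) -> List[ModelTerm]:
        table_ids = {t.id for t in self.table_terms}
        return [t for t in self.terms if t.parent_id in table_ids]

    @property
    def depth(self) -> int:
        """Number of hierarchy levels (3 whenever any table has a column)."""
        if self.column_terms:
            return 3
        return 2 if self.table_terms else 1

    @property
    def term_count(self) -> int:
        return len(self.terms)

    def term_names(self) -> List[str]:
        return [t.name for t in self.terms]

    def to_schema(self) -> SourceSchema:
        """Reconstruct the schema the model describes (column order is
        the model's deterministic alphabetical order)."""
        tables = []
        for tt in self.table_terms:
            cols, key = [], None
            for ct in self.terms:
                if ct.parent_id != tt.id:
                    continue
                cname = ct.name.split(".", 1)[1]
                cols.append(SourceColumn(cname, ct.datatype or "text"))
                if ct.is_key:
                    key = cname
            if key is None:
                key = default_key_column(tt.name, [c.name for c in cols])
            tables.append(SourceTable(tt.name, cols, key))
        return SourceSchema(self.db_name, tables)


def build_model(schema: SourceSchema) -> ClinicalDatabaseModel:
    """Build the model from a schema.

    Deterministic: siblings in alphabetical order, identifiers
    ``<db_name>:<zero-padded ordinal>`` assigned in traversal order
    (root, then each table followed by its columns).
    """
    counter = 0

    def next_id() -> str:
        nonlocal counter
        tid = f"{schema.db_name}:{counter:07d}"
        counter += 1
        return tid

    terms = [ModelTerm(next_id(), schema.db_name)]
    root_id = terms[0].id
    for table in sorted(schema.tables, key=lambda t: t.name):
        table_term = ModelTerm(next_id(), table.name, root_id)
        terms.append(table_term)
        for col in sorted(table.columns, key=lambda c: c.name):
            terms.append(
                ModelTerm(
                    next_id(),
                    f"{table.name}.{col.name}",
                    table_term.id,
                    datatype=col.datatype,
                    is_key=(col.name == table.key_column),
                )
            )
    return ClinicalDatabaseModel(schema.db_name, terms)


# -- OBO serialization ------------------------------------------------------


def write_obo(model: ClinicalDatabaseModel) -> str:
    """Serialize a model as OBO 1.2 text; datatype and key-column
    annotations travel as ``property_value`` lines."""
    doc = obomod.OboDocument(
        header={"format-version": "1.2", "ontology": model.db_name}
    )
    for term in model.terms:
        props = []
        if term.datatype is not None:
            props.append((DATATYPE_PROP, term.datatype))
        if term.is_key:
            props.append((IS_KEY_PROP, "true"))
        doc.terms.append(
            obomod.OboTerm(
                id=term.id,
                name=term.name,
                is_a=[term.parent_id] if term.parent_id else [],
                property_values=props,
            )
        )
    return obomod.write_obo(doc)


def read_obo(text: str) -> ClinicalDatabaseModel:
    """Parse OBO text back into a model; raises :class:`ModelError` when
    the term hierarchy is not a clean three-level tree."""
    doc = obomod.parse_obo(text)
    by_id = doc.term_by_id()
    roots = [t for t in doc.terms if not t.is_a]
    if len(roots) != 1:
        raise ModelError(f"model must have exactly one root term, found {len(roots)}")
    root = roots[0]
    children: Dict[str, List[obomod.OboTerm]] = {}
    for t in doc.terms:
        for parent in t.is_a:
            if parent not in by_id:
                raise ModelError(f"term {t.id} has unknown parent {parent}")
            children.setdefault(parent, []).append(t)
        if len(t.is_a) > 1:
            raise ModelError(f"term {t.id} has multiple parents")

    table_stanzas = sorted(children.get(root.id, []), key=lambda t: t.name)
    terms = [ModelTerm(root.id, root.name)]
    seen = {root.id}
    for tt in table_stanzas:
        terms.append(ModelTerm(tt.id, tt.name, root.id))
        seen.add(tt.id)
        for ct in sorted(children.get(tt.id, []), key=lambda t: t.name):
            if children.get(ct.id):
                raise ModelError(f"term {ct.id} is below level three")
            if "." not in ct.name:
                raise ModelError(f"column term {ct.id} name {ct.name!r} is not table-qualified")
            terms.append(
                ModelTerm(
                    ct.id,
                    ct.name,
                    tt.id,
                    datatype=ct.prop(DATATYPE_PROP),
                    is_key=ct.prop(IS_KEY_PROP) == "true",
                )
            )
            seen.add(ct.id)
    if seen != set(by_id):
        orphans = sorted(set(by_id) - seen)
        raise ModelError(f"terms not reachable from the root in <=2 hops: {orphans}")
    return ClinicalDatabaseModel(root.name, terms)


# -- loading into the store -------------------------------------------------


@dataclass
class LoadReport:
    terms: int
    edges: int


class ModelConflictError(Exception):
    """A model with this database name is already loaded."""


def load_model(store: Store, model: ClinicalDatabaseModel, replace: bool = False) -> LoadReport:
    """Load the model into ``cv``/``cvterm``: one vocabulary named after
    the database, one term per node, one is_a edge per parent link.
    Datatype and key annotations land in ``cvtermprop``.
    """
    existing = store.cv_id(model.db_name)
    if existing is not None:
        if not replace:
            raise ModelConflictError(
                f"model {model.db_name!r} already loaded; pass replace=True to reload"
            )
        _reset_model(store, existing, keep_names={t.name for t in model.terms})
    cv_id = store.upsert_cv(model.db_name)
    is_a = store.internal_term("is_a")
    dt_prop = store.upsert_cvterm(INTERNAL_CV, DATATYPE_PROP)
    key_prop = store.upsert_cvterm(INTERNAL_CV, IS_KEY_PROP)
    ids: Dict[str, int] = {}
    edges = 0
    for term in model.terms:
        tid = store.upsert_cvterm(model.db_name, term.name, definition=term.id)
        ids[term.id] = tid
        if term.parent_id is not None:
            store.add_cvterm_relationship(tid, ids[term.parent_id], is_a)
            edges += 1
        if term.datatype is not None:
            store.set_cvtermprop(tid, dt_prop, term.datatype)
        if term.is_key:
            store.set_cvtermprop(tid, key_prop, "true")
    store.commit()
    return LoadReport(terms=len(model.terms), edges=edges)


def _reset_model(store: Store, cv_id: int, keep_names) -> None:
    """Clear a vocabulary's edges and annotations so the model can be
    re-asserted in place.  Terms shared with the incoming model keep
    their ids (migrated facts that reference them stay valid); terms the
    new model no longer mentions are deleted, which fails loudly if
    stored facts still point at them."""
    c = store.conn
    term_ids = [r[0] for r in c.execute("SELECT cvterm_id FROM cvterm WHERE cv_id = ?", (cv_id,))]
    if not term_ids:
        return
    marks = ",".join("?" * len(term_ids))
    c.execute(
        f"DELETE FROM cvterm_relationship WHERE subject_id IN ({marks})"
        f" OR object_id IN ({marks})",
        term_ids * 2,
    )
    c.execute(f"DELETE FROM cvtermprop WHERE cvterm_id IN ({marks})", term_ids)
    stale = [
        r[0]
        for r in c.execute(
            f"SELECT cvterm_id FROM cvterm WHERE cv_id = ? AND name NOT IN"
            f" ({','.join('?' * len(keep_names))})",
            (cv_id, *sorted(keep_names)),
        )
    ]
    if stale:
        smarks = ",".join("?" * len(stale))
        try:
            c.execute(f"DELETE FROM cvterm WHERE cvterm_id IN ({smarks})", stale)
        except Exception as exc:
            raise ModelConflictError(
                f"cannot replace model: {len(stale)} obsolete terms still have"
                f" stored facts ({exc}); migrate or wipe the data first"
            ) from exc


def model_from_store(store: Store, db_name: str) -> ClinicalDatabaseModel:
    """Rebuild the model for ``db_name`` from the loaded vocabulary."""
    cv_id = store.cv_id(db_name)
    if cv_id is None:
        raise ModelConflictError(f"no model loaded for {db_name!r}")
    rows = store.conn.execute(
        "SELECT cvterm_id, name, definition FROM cvterm WHERE cv_id = ?", (cv_id,)
    ).fetchall()
    is_a = store.internal_term("is_a")
    parent = dict(
        store.conn.execute(
            "SELECT subject_id, object_id FROM cvterm_relationship r"
            " JOIN cvterm s ON r.subject_id = s.cvterm_id"
            " WHERE r.type_id = ? AND s.cv_id = ?",
            (is_a, cv_id),
        ).fetchall()
    )
    dt_prop = store.term_id(INTERNAL_CV, DATATYPE_PROP)
    key_prop = store.term_id(INTERNAL_CV, IS_KEY_PROP)
    props: Dict[int, Dict[int, str]] = {}
    for cvterm_id, type_id, value in store.conn.execute(
        "SELECT cvterm_id, type_id, value FROM cvtermprop"
    ):
        props.setdefault(cvterm_id, {})[type_id] = value
    doc_terms = []
    by_store_id = {r[0]: r for r in rows}
    for cvterm_id, name, obo_id in rows:
        parent_obo = by_store_id[parent[cvterm_id]][2] if cvterm_id in parent else None
        p = props.get(cvterm_id, {})
        doc_terms.append(
            (obo_id, name, parent_obo, p.get(dt_prop), p.get(key_prop) == "true")
        )
    root = [t for t in doc_terms if t[2] is None]
    if len(root) != 1:
        raise ModelError(f"vocabulary {db_name!r} does not hold a single-rooted model")
    by_obo = {t[0]: t for t in doc_terms}
    ordered = [ModelTerm(*root[0])]
    tables = sorted((t for t in doc_terms if t[2] == root[0][0]), key=lambda t: t[1])
    for tt in tables:
        ordered.append(ModelTerm(*tt))
        cols = sorted((t for t in doc_terms if t[2] == tt[0]), key=lambda t: t[1])
        ordered.extend(ModelTerm(*ct) for ct in cols)
    return ClinicalDatabaseModel(root[0][1], ordered)
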