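"""The integrated clinical data store.

A single-file SQLite database holding three groups of tables:

* the Controlled Vocabulary subset (``cv``, ``cvterm``,
  ``cvterm_relationship``, ``cvtermprop``) where ontologies and legacy
  database models live — every stored fact is typed by a ``cvterm``;
* the Clinical Module — seven tables (``patient``, ``patientprop``,
  ``appointment``, ``project_cdb``, ``csd``, ``csd_relationship``,
  ``csdprop``) storing clinical and socio-demographic facts in
  Entity-Attribute-Value form, plus the General-module ``project``;
* a minimal microarray subset (``biomaterial``, ``biomaterialprop``,
  ``assay``, ``assay_biomaterial``, ``expression_value``) linking
  patients to hybridizations and expression values.

The schema is expressed in portable SQL DDL (``SCHEMA_DDL``) so that a
server backend remains possible; SQLite keeps the artifact desk-scale.
All value columns are text; datatype metadata lives on the model term
(see :mod:`iptrans.cdbmodel`).
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass
from typing import Iterable, Optional

SCHEMA_VERSION = 1

#: The seven tables of the Clinical Module namespace.
CLINICAL_MODULE_TABLES = (
    "patient",
    "patientprop",
    "appointment",
    "project_cdb",
    "csd",
    "csd_relationship",
    "csdprop",
)

CV_MODULE_TABLES = ("cv", "cvterm", "cvterm_relationship", "cvtermprop")
GENERAL_MODULE_TABLES = ("project",)
MAGE_MODULE_TABLES = (
    "biomaterial",
    "biomaterialprop",
    "assay",
    "assay_biomaterial",
    "expression_value",
)

#: Bootstrap vocabulary: internal terms every store starts with.
INTERNAL_CV = "iptrans_internal"
INTERNAL_TERMS = (
    "is_a",
    "exact_match",
    "patient_id",
    "drug",
    "dosage",
    "datatype",
    "is_key",
)

# Uniqueness of (entity, attribute, rank) in the EAV tables is enforced by
# the loaders and audited by integrity_check rather than by UNIQUE
# constraints, so that a corrupted store can still be opened and reported on.
SCHEMA_DDL = """\
CREATE TABLE IF NOT EXISTS cv (
    cv_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE CHECK (name <> '')
);
CREATE TABLE IF NOT EXISTS cvterm (
    cvterm_id INTEGER PRIMARY KEY,
    cv_id INTEGER NOT NULL REFERENCES cv (cv_id),
    name TEXT NOT NULL CHECK (name <> ''),
    definition TEXT,
    is_relationship INTEGER NOT NULL DEFAULT 0,
    UNIQUE (cv_id, name)
);
CREATE TABLE IF NOT EXISTS cvterm_relationship (
    cvterm_relationship_id INTEGER PRIMARY KEY,
    subject_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id),
    object_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id),
    type_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id)
);
CREATE TABLE IF NOT EXISTS cvtermprop (
    cvtermprop_id INTEGER PRIMARY KEY,
    cvterm_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id),
    type_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id),
    value TEXT,
    rank INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS project (
    project_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS project_cdb (
    project_id INTEGER NOT NULL REFERENCES project (project_id),
    cdb_cv_id INTEGER NOT NULL REFERENCES cv (cv_id),
    UNIQUE (project_id, cdb_cv_id)
);
CREATE TABLE IF NOT EXISTS patient (
    patient_id INTEGER PRIMARY KEY,
    source_key TEXT NOT NULL,
    cdb_cv_id INTEGER NOT NULL REFERENCES cv (cv_id),
    UNIQUE (cdb_cv_id, source_key)
);
CREATE TABLE IF NOT EXISTS patientprop (
    patientprop_id INTEGER PRIMARY KEY,
    patient_id INTEGER NOT NULL REFERENCES patient (patient_id),
    type_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id),
    value TEXT,
    rank INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS appointment (
    appointment_id INTEGER PRIMARY KEY,
    patient_id INTEGER NOT NULL REFERENCES patient (patient_id),
    date TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS csd (
    csd_id INTEGER PRIMARY KEY,
    patient_id INTEGER NOT NULL REFERENCES patient (patient_id),
    type_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id),
    value TEXT,
    rank INTEGER NOT NULL DEFAULT 0,
    parent_csd INTEGER REFERENCES csd (csd_id)
);
CREATE TABLE IF NOT EXISTS csd_relationship (
    csd_relationship_id INTEGER PRIMARY KEY,
    subject_id INTEGER NOT NULL REFERENCES csd (csd_id),
    object_id INTEGER NOT NULL REFERENCES csd (csd_id),
    type_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id)
);
CREATE TABLE IF NOT EXISTS csdprop (
    csdprop_id INTEGER PRIMARY KEY,
    type_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id),
    value TEXT,
    rank INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS biomaterial (
    biomaterial_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS biomaterialprop (
    biomaterialprop_id INTEGER PRIMARY KEY,
    biomaterial_id INTEGER NOT NULL REFERENCES biomaterial (biomaterial_id),
    type_id INTEGER NOT NULL REFERENCES cvterm (cvterm_id),
    value TEXT
);
CREATE TABLE IF NOT EXISTS assay (
    assay_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS assay_biomaterial (
    assay_id INTEGER NOT NULL REFERENCES assay (assay_id),
    biomaterial_id INTEGER NOT NULL REFERENCES biomaterial (biomaterial_id),
    UNIQUE (assay_id, biomaterial_id)
);
CREATE TABLE IF NOT EXISTS expression_value (
    assay_id INTEGER NOT NULL REFERENCES assay (assay_id),
    feature_name TEXT NOT NULL,
    value REAL,
    UNIQUE (assay_id, feature_name)
);
CREATE INDEX IF NOT EXISTS idx_csd_patient_type ON csd (patient_id, type_id, rank);
CREATE INDEX IF NOT EXISTS idx_csd_type ON csd (type_id);
CREATE INDEX IF NOT EXISTS idx_patientprop ON patientprop (patient_id, type_id, rank);
CREATE INDEX IF NOT EXISTS idx_csdprop_type ON csdprop (type_id, rank);
"""


class StoreError(Exception):
    """Base class for store failures."""


class SchemaVersionError(StoreError):
    """Existing file carries an incompatible schema."""


class ValidationError(StoreError):
    """Invalid input to a store operation."""


@dataclass(frozen=True)
class CSDRecord:
    """One clinic-social fact in Entity-Attribute-Value form.

    ``rank`` distinguishes repeated instances of the same attribute for
    one patient (e.g. several drugs); ``parent_csd`` anchors a dependent
    fact (a dosage) to the record it qualifies (its drug).
    """

    csd_id: int
    patient_id: int
    type_id: int
    value: Optional[str]
    rank: int = 0
    parent_csd: Optional[int] = None

    def as_eav(self) -> tuple:
        """The record reduced to its EAV triple: (entity, attribute, value)."""
        return (self.patient_id, self.type_id, self.value)


@dataclass(frozen=True)
class Violation:
    """One integrity rule broken by a stored row."""

    table: str
    row_key: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[{self.row_key}]: {self.rule}"


class Store:
    """Handle on an open store file; thin wrapper over sqlite3."""

    def __init__(self, conn: sqlite3.Connection, path: str):
        self.conn = conn
        self.path = path
        conn.execute("PRAGMA foreign_keys = ON")

    # -- vocabulary ---------------------------------------------------

    def upsert_cv(self, name: str) -> int:
        if not name or not str(name).strip():
            raise ValidationError("vocabulary name must be non-empty")
        cur = self.conn.execute("SELECT cv_id FROM cv WHERE name = ?", (name,))
        row = cur.fetchone()
        if row:
            return row[0]
        cur = self.conn.execute("INSERT INTO cv (name) VALUES (?)", (name,))
        return cur.lastrowid

    def upsert_cvterm(
        self,
        cv_name: str,
        term_name: str,
        definition: Optional[str] = None,
        is_relationship: bool = False,
    ) -> int:
        """Get-or-create a term; the vocabulary is created if absent.

        Idempotent on (cv, name): repeated calls return the same id.
        """
        if not term_name or not str(term_name).strip():
            raise ValidationError("term name must be non-empty")
        cv_id = self.upsert_cv(cv_name)
        cur = self.conn.execute(
            "SELECT cvterm_id FROM cvterm WHERE cv_id = ? AND name = ?",
            (cv_id, term_name),
        )
        row = cur.fetchone()
        if row:
            return row[0]
        cur = self.conn.execute(
            "INSERT INTO cvterm (cv_id, name, definition, is_relationship)"
            " VALUES (?, ?, ?, ?)",
            (cv_id, term_name, definition, int(is_relationship)),
        )
        return cur.lastrowid

    def cv_id(self, name: str) -> Optional[int]:
        row = self.conn.execute("SELECT cv_id FROM cv WHERE name = ?", (name,)).fetchone()
        return row[0] if row else None

    def term_id(self, cv_name: str, term_name: str) -> Optional[int]:
        row = self.conn.execute(
            "SELECT cvterm_id FROM cvterm JOIN cv USING (cv_id)"
            " WHERE cv.name = ? AND cvterm.name = ?",
            (cv_name, term_name),
        ).fetchone()
        return row[0] if row else None

    def internal_term(self, name: str) -> int:
        tid = self.term_id(INTERNAL_CV, name)
        if tid is None:
            raise StoreError(f"bootstrap term missing: {name}")
        return tid

    def add_cvterm_relationship(self, subject_id: int, object_id: int, type_id: int) -> None:
        if subject_id == object_id:
            raise ValidationError("a term cannot relate to itself")
        self.conn.execute(
            "INSERT INTO cvterm_relationship (subject_id, object_id, type_id)"
            " VALUES (?, ?, ?)",
            (subject_id, object_id, type_id),
        )

    def set_cvtermprop(self, cvterm_id: int, type_id: int, value: str, rank: int = 0) -> None:
        self.conn.execute(
            "DELETE FROM cvtermprop WHERE cvterm_id = ? AND type_id = ? AND rank = ?",
            (cvterm_id, type_id, rank),
        )
        self.conn.execute(
            "INSERT INTO cvtermprop (cvterm_id, type_id, value, rank) VALUES (?, ?, ?, ?)",
            (cvterm_id, type_id, value, rank),
        )

    # -- clinical module ----------------------------------------------

    def add_patient(self, source_key: str, cdb_cv_id: int) -> int:
        cur = self.conn.execute(
            "INSERT INTO patient (source_key, cdb_cv_id) VALUES (?, ?)",
            (str(source_key), cdb_cv_id),
        )
        return cur.lastrowid

    def add_patientprop(self, patient_id: int, type_id: int, value: str, rank: int = 0) -> int:
        cur = self.conn.execute(
            "INSERT INTO patientprop (patient_id, type_id, value, rank) VALUES (?, ?, ?, ?)",
            (patient_id, type_id, value, rank),
        )
        return cur.lastrowid

    def add_csd(
        self,
        patient_id: int,
        type_id: int,
        value: Optional[str],
        rank: int = 0,
        parent_csd: Optional[int] = None,
    ) -> int:
        cur = self.conn.execute(
            "INSERT INTO csd (patient_id, type_id, value, rank, parent_csd)"
            " VALUES (?, ?, ?, ?, ?)",
            (patient_id, type_id, value, rank, parent_csd),
        )
        return cur.lastrowid

    def add_csdprop(self, type_id: int, value: str, rank: int = 0) -> int:
        cur = self.conn.execute(
            "INSERT INTO csdprop (type_id, value, rank) VALUES (?, ?, ?)",
            (type_id, value, rank),
        )
        return cur.lastrowid

    def add_csd_relationship(self, subject_id: int, object_id: int, type_id: int) -> int:
        if subject_id == object_id:
            raise ValidationError("csd_relationship subject and object must differ")
        cur = self.conn.execute(
            "INSERT INTO csd_relationship (subject_id, object_id, type_id) VALUES (?, ?, ?)",
            (subject_id, object_id, type_id),
        )
        return cur.lastrowid

    def add_appointment(self, patient_id: int, date: str) -> int:
        cur = self.conn.execute(
            "INSERT INTO appointment (patient_id, date) VALUES (?, ?)",
            (patient_id, date),
        )
        return cur.lastrowid

    def get_csd(self, csd_id: int) -> Optional[CSDRecord]:
        row = self.conn.execute(
            "SELECT csd_id, patient_id, type_id, value, rank, parent_csd"
            " FROM csd WHERE csd_id = ?",
            (csd_id,),
        ).fetchone()
        return CSDRecord(*row) if row else None

    def patients(self, cdb_cv_id: Optional[int] = None) -> list:
        if cdb_cv_id is None:
            cur = self.conn.execute(
                "SELECT patient_id, source_key, cdb_cv_id FROM patient ORDER BY patient_id"
            )
        else:
            cur = self.conn.execute(
                "SELECT patient_id, source_key, cdb_cv_id FROM patient"
                " WHERE cdb_cv_id = ? ORDER BY patient_id",
                (cdb_cv_id,),
            )
        return cur.fetchall()

    # -- introspection ------------------------------------------------

    def table_names(self) -> list:
        cur = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type = 'table'"
            " AND name NOT LIKE 'sqlite_%' ORDER BY name"
        )
        return [r[0] for r in cur.fetchall()]

    def clinical_module_tables(self) -> tuple:
        """The Clinical Module tables actually present in this store."""
        present = set(self.table_names())
        return tuple(t for t in CLINICAL_MODULE_TABLES if t in present)

    def count(self, table: str) -> int:
        if table not in self.table_names():
            raise ValidationError(f"no such table: {table}")
        return self.conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def dump_schema(self) -> str:
        """The portable DDL the store was created from."""
        return SCHEMA_DDL

    def commit(self) -> None:
        self.conn.commit()

    def close(self) -> None:
        self.conn.commit()
        self.conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- integrity ----------------------------------------------------

    def integrity_check(self) -> list:
        """Audit every stored row against the module invariants.

        Returns a list of :class:`Violation`; an empty list means the
        store is consistent.  Reports, never raises, on data problems.
        """
        v: list = []
        c = self.conn

        for table, entity in (("csd", "patient_id"), ("patientprop", "patient_id")):
            cur = c.execute(
                f"SELECT {entity}, type_id, rank, COUNT(*) FROM {table}"
                f" GROUP BY {entity}, type_id, rank HAVING COUNT(*) > 1"
            )
            for ent, tid, rank, n in cur.fetchall():
                v.append(
                    Violation(
                        table,
                        f"{entity}={ent},type_id={tid},rank={rank}",
                        f"(entity, type_id, rank) must be unique; found {n} rows",
                    )
                )

        # parent_csd must stay within one patient's record set
        cur = c.execute(
            "SELECT a.csd_id, a.patient_id, b.patient_id FROM csd a"
            " JOIN csd b ON a.parent_csd = b.csd_id WHERE a.patient_id <> b.patient_id"
        )
        for csd_id, pa, pb in cur.fetchall():
            v.append(
                Violation(
                    "csd",
                    f"csd_id={csd_id}",
                    f"parent_csd crosses patients ({pa} -> {pb})",
                )
            )

        # parent chains must be acyclic (walk with a visited set)
        parents = dict(
            c.execute("SELECT csd_id, parent_csd FROM csd WHERE parent_csd IS NOT NULL")
        )
        for start in parents:
            seen = set()
            node = start
            while node in parents:
                if node in seen:
                    v.append(Violation("csd", f"csd_id={start}", "parent_csd chain has a cycle"))
                    break
                seen.add(node)
                node = parents[node]

        cur = c.execute(
            "SELECT csd_relationship_id FROM csd_relationship WHERE subject_id = object_id"
        )
        for (rid,) in cur.fetchall():
            v.append(
                Violation("csd_relationship", f"csd_relationship_id={rid}", "subject equals object")
            )

        # every typed row must resolve to a cvterm
        for table, key in (
            ("csd", "csd_id"),
            ("patientprop", "patientprop_id"),
            ("csdprop", "csdprop_id"),
            ("biomaterialprop", "biomaterialprop_id"),
        ):
            cur = c.execute(
                f"SELECT t.{key} FROM {table} t LEFT JOIN cvterm ct ON t.type_id = ct.cvterm_id"
                " WHERE ct.cvterm_id IS NULL"
            )
            for (rid,) in cur.fetchall():
                v.append(Violation(table, f"{key}={rid}", "type_id does not resolve to a cvterm"))

        cur = c.execute(
            "SELECT a.appointment_id FROM appointment a"
            " LEFT JOIN patient p ON a.patient_id = p.patient_id WHERE p.patient_id IS NULL"
        )
        for (rid,) in cur.fetchall():
            v.append(Violation("appointment", f"appointment_id={rid}", "patient does not exist"))

        cur = c.execute(
            "SELECT assay_id, biomaterial_id, COUNT(*) FROM assay_biomaterial"
            " GROUP BY assay_id, biomaterial_id HAVING COUNT(*) > 1"
        )
        for aid, bid, n in cur.fetchall():
            v.append(
                Violation(
                    "assay_biomaterial",
                    f"assay_id={aid},biomaterial_id={bid}",
                    f"pair must be unique; found {n} rows",
                )
            )

        v.extend(self._is_a_cycle_violations())
        return v

    def _is_a_cycle_violations(self) -> list:
        """Detect cycles among is_a edges within each vocabulary."""
        out: list = []
        is_a = self.term_id(INTERNAL_CV, "is_a")
        if is_a is None:
            return out
        edges = self.conn.execute(
            "SELECT r.subject_id, r.object_id, s.cv_id FROM cvterm_relationship r"
            " JOIN cvterm s ON r.subject_id = s.cvterm_id WHERE r.type_id = ?",
            (is_a,),
        ).fetchall()
        by_cv: dict = {}
        for s, o, cv in edges:
            by_cv.setdefault(cv, {}).setdefault(s, []).append(o)
        for cv, adj in by_cv.items():
            state: dict = {}

            def dfs(node) -> bool:
                state[node] = 1
                for nxt in adj.get(node, ()):
                    if state.get(nxt) == 1:
                        return True
                    if state.get(nxt) is None and dfs(nxt):
                        return True
                state[node] = 2
                return False

            for node in list(adj):
                if state.get(node) is None and dfs(node):
                    out.append(
                        Violation("cvterm_relationship", f"cv_id={cv}", "is_a edges form a cycle")
                    )
                    break
        return out


def init_store(path: str) -> Store:
    """Create or reopen the store file at ``path``.

    Creates every table and the bootstrap vocabulary on first use;
    idempotent on re-open.  An existing file that is not an iptrans
    store raises :class:`SchemaVersionError`.
    """
    existing = os.path.exists(path) and path != ":memory:" and os.path.getsize(path) > 0
    try:
        conn = sqlite3.connect(path)
    except sqlite3.OperationalError as exc:  # unwritable path etc.
        raise OSError(f"cannot open store at {path}: {exc}") from exc
    if existing:
        try:
            (version,) = conn.execute("PRAGMA user_version").fetchone()
        except sqlite3.DatabaseError as exc:
            conn.close()
            raise SchemaVersionError(f"{path} is not a store file: {exc}") from exc
        if version != SCHEMA_VERSION:
            conn.close()
            raise SchemaVersionError(
                f"{path} has schema version {version}, expected {SCHEMA_VERSION}"
            )
    try:
        conn.executescript(SCHEMA_DDL)
    except sqlite3.OperationalError as exc:
        conn.close()
        raise OSError(f"cannot initialize store at {path}: {exc}") from exc
    conn.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
    store = Store(conn, path)
    for term in INTERNAL_TERMS:
        store.upsert_cvterm(INTERNAL_CV, term, is_relationship=term in ("is_a", "exact_match"))
    store.commit()
    return store
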