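"""Bidirectional clinical <-> biomolecular query engine.

Patient selection follows the split-query strategy for EAV stores:
instead of one wide pivoting query, a boolean expression is decomposed
into one small single-attribute query per predicate leaf, and the leaf
result sets are combined with set operations — AND becomes
intersection, OR union, NOT complement against the clinical database's
own patient set (never the whole store, so multi-source stores do not
leak across databases).

Predicates may be phrased against source terms directly
(``CDB:prescription.drug``) or against reference-ontology concepts;
concept leaves are expanded through the ontological mapping
environment to every mapped source term (OR-combined) *before*
planning, so execution never consults the environment.

Multivalued attributes (one EAV row per rank) qualify a patient when
ANY rank satisfies the predicate; an ALL-ranks mode is available per
predicate.

The clinical <-> expression link is the biomaterial path: patient ->
biomaterialprop (patient-id property) -> biomaterial ->
assay_biomaterial -> assay, traversed in either direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from ._canon import canonicalize, parses_as
from .mapping import OntologicalMappingEnvironment, translate_concept
from .store import INTERNAL_CV, Store

OPERATORS = ("=", "!=", "<", "<=", ">", ">=", "contains")
_ORDERING = ("<", "<=", ">", ">=")


class QueryError(Exception):
    pass


class LookupError_(QueryError):
    """Attribute or concept cannot be resolved."""


class TypeError_(QueryError):
    """Operator incompatible with the attribute datatype."""


# ---------------------------------------------------------------------------
# expressions


@dataclass(frozen=True)
class Predicate:
    """One atomic condition on a clinical or socio-demographic attribute.

    ``attribute`` is ``<cv>:<term>`` for a source term or a bare concept
    name resolved through the mapping environment.
    """

    attribute: str
    operator: str
    literal: str
    all_ranks: bool = False

    def __post_init__(self):
        if self.operator not in OPERATORS:
            raise QueryError(f"unknown operator {self.operator!r}")


@dataclass(frozen=True)
class And:
    children: Tuple["Expr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise QueryError("AND needs at least 2 children")


@dataclass(frozen=True)
class Or:
    children: Tuple["Expr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise QueryError("OR needs at least 2 children")


@dataclass(frozen=True)
class Not:
    child: "Expr"


Expr = Union[Predicate, And, Or, Not]


def parse_expr(text: str) -> Expr:
    """Parse the small s-expression grammar used by the CLI.

    ``(and (gt CDB:patient.age 60) (eq CDB:patient.sex male))``
    Operators: eq ne lt le gt ge contains; combinators: and or not.
    """
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def read() -> Expr:
        nonlocal pos
        if pos >= len(tokens):
            raise QueryError("unexpected end of expression")
        tok = tokens[pos]
        pos += 1
        if tok != "(":
            raise QueryError(f"expected '(', got {tok!r}")
        head = tokens[pos]
        pos += 1
        if head in ("and", "or"):
            children = []
            while tokens[pos] != ")":
                children.append(read())
            pos += 1
            return And(tuple(children)) if head == "and" else Or(tuple(children))
        if head == "not":
            child = read()
            if tokens[pos] != ")":
                raise QueryError("NOT takes exactly one child")
            pos += 1
            return Not(child)
        ops = {"eq": "=", "ne": "!=", "lt": "<", "le": "<=", "gt": ">", "ge": ">=",
               "contains": "contains"}
        if head not in ops:
            raise QueryError(f"unknown form {head!r}")
        attr = tokens[pos]
        pos += 1
        lit_parts = []
        while tokens[pos] != ")":
            lit_parts.append(tokens[pos])
            pos += 1
        pos += 1
        return Predicate(attr, ops[head], " ".join(lit_parts))

    try:
        expr = read()
    except IndexError:
        raise QueryError("unbalanced or truncated expression") from None
    if pos != len(tokens):
        raise QueryError("trailing tokens after expression")
    return expr


# ---------------------------------------------------------------------------
# planning


@dataclass(frozen=True)
class AtomicQuery:
    """One single-attribute EAV query."""

    type_id: int
    datatype: str
    operator: str
    literal: str
    all_ranks: bool = False


@dataclass(frozen=True)
class PlanNode:
    op: str  # "atom" | "and" | "or" | "not"
    atom: Optional[AtomicQuery] = None
    children: Tuple["PlanNode", ...] = ()


@dataclass
class QueryPlan:
    cdb_cv_id: int
    root: PlanNode

    @property
    def atoms(self) -> List[AtomicQuery]:
        out: List[AtomicQuery] = []

        def walk(node: PlanNode):
            if node.op == "atom":
                out.append(node.atom)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out


def _attr_datatype(store: Store, type_id: int) -> str:
    from .cdbmodel import DATATYPE_PROP

    dt_prop = store.term_id(INTERNAL_CV, DATATYPE_PROP)
    row = store.conn.execute(
        "SELECT value FROM cvtermprop WHERE cvterm_id = ? AND type_id = ?",
        (type_id, dt_prop),
    ).fetchone()
    return row[0] if row else "text"


def _resolve_term(store: Store, qualified: str) -> Tuple[int, int, str]:
    """``cv:term`` -> (cv_id, cvterm_id, datatype)."""
    if ":" not in qualified:
        raise LookupError_(f"attribute {qualified!r} must be '<cv>:<term>' or a concept")
    cv_name, term_name = qualified.split(":", 1)
    cv_id = store.cv_id(cv_name)
    tid = store.term_id(cv_name, term_name)
    if cv_id is None or tid is None:
        raise LookupError_(f"attribute {qualified!r} not found in the store")
    return cv_id, tid, _attr_datatype(store, tid)


def plan(
    store: Store,
    expr: Expr,
    cdb: str,
    ome: Optional[OntologicalMappingEnvironment] = None,
    expand_descendants: bool = False,
) -> QueryPlan:
    """Compile an expression into atomic queries plus a combination tree.

    ``cdb`` names the clinical database whose patient set NOT
    complements against.  Concept attributes (no ``cv:`` prefix, or not
    resolvable as a term) require ``ome`` and expand to the union of
    their mapped source terms.
    """
    cv_id = store.cv_id(cdb)
    if cv_id is None:
        raise LookupError_(f"clinical database {cdb!r} not found")

    def atom(pred: Predicate, type_id: int, datatype: str) -> PlanNode:
        if pred.operator in _ORDERING and datatype not in ("integer", "decimal", "date"):
            raise TypeError_(
                f"ordering operator {pred.operator!r} on non-orderable"
                f" attribute {pred.attribute!r} ({datatype})"
            )
        lit = pred.literal
        if datatype in ("integer", "decimal", "date", "boolean") and pred.operator != "contains":
            if parses_as(lit, datatype):
                lit = canonicalize(lit, datatype)
        return PlanNode(
            "atom",
            AtomicQuery(type_id, datatype, pred.operator, lit, pred.all_ranks),
        )

    def compile_(node: Expr) -> PlanNode:
        if isinstance(node, Predicate):
            if ":" in node.attribute:
                _, tid, dt = _resolve_term(store, node.attribute)
                return atom(node, tid, dt)
            # a bare name is a reference-ontology concept
            if ome is None:
                raise LookupError_(
                    f"concept attribute {node.attribute!r} needs a mapping environment"
                )
            hits = translate_concept(ome, node.attribute, expand_descendants)
            leaves = []
            for k, term in hits:
                db = ome.source_models[k].db_name
                _, tid, dt = _resolve_term(store, f"{db}:{term}")
                leaves.append(atom(node, tid, dt))
            if not leaves:
                # concept mapped nowhere: empty result leaf
                return PlanNode("or_empty")
            if len(leaves) == 1:
                return leaves[0]
            return PlanNode("or", children=tuple(leaves))
        if isinstance(node, And):
            return PlanNode("and", children=tuple(compile_(c) for c in node.children))
        if isinstance(node, Or):
            return PlanNode("or", children=tuple(compile_(c) for c in node.children))
        if isinstance(node, Not):
            return PlanNode("not", children=(compile_(node.child),))
        raise QueryError(f"unknown expression node {node!r}")

    return QueryPlan(cv_id, compile_(expr))


# ---------------------------------------------------------------------------
# execution


def _atom_sql(atom: AtomicQuery) -> Tuple[str, list]:
    if atom.operator == "contains":
        cond = "instr(x.value, ?) > 0"
        params = [atom.literal]
    elif atom.datatype in ("integer", "decimal"):
        cond = f"CAST(x.value AS REAL) {atom.operator} CAST(? AS REAL)"
        params = [atom.literal]
    else:
        cond = f"x.value {atom.operator} ?"
        params = [atom.literal]
    return cond, params


def _run_atom(store: Store, atom: AtomicQuery, cv_id: int) -> Set[int]:
    cond, params = _atom_sql(atom)
    pids: Set[int] = set()
    for table in ("csd", "patientprop"):
        sql = (
            f"SELECT DISTINCT x.patient_id FROM {table} x"
            " JOIN patient p ON p.patient_id = x.patient_id"
            f" WHERE p.cdb_cv_id = ? AND x.type_id = ? AND {cond}"
        )
        pids |= {r[0] for r in store.conn.execute(sql, [cv_id, atom.type_id] + params)}
    if atom.all_ranks:
        # drop patients with any rank that fails the condition
        for table in ("csd", "patientprop"):
            sql = (
                f"SELECT DISTINCT x.patient_id FROM {table} x"
                " JOIN patient p ON p.patient_id = x.patient_id"
                f" WHERE p.cdb_cv_id = ? AND x.type_id = ? AND NOT ({cond})"
            )
            pids -= {r[0] for r in store.conn.execute(sql, [cv_id, atom.type_id] + params)}
    return pids


def all_patients(store: Store, cv_id: int) -> Set[int]:
    return {
        r[0]
        for r in store.conn.execute(
            "SELECT patient_id FROM patient WHERE cdb_cv_id = ?", (cv_id,)
        )
    }


def select_patients(store: Store, qplan: QueryPlan) -> Set[int]:
    """Execute a plan: run each atomic query, combine with set ops."""

    def run(node: PlanNode) -> Set[int]:
        if node.op == "atom":
            return _run_atom(store, node.atom, qplan.cdb_cv_id)
        if node.op == "or_empty":
            return set()
        if node.op == "and":
            sets = [run(c) for c in node.children]
            out = sets[0]
            for s in sets[1:]:
                out &= s
            return out
        if node.op == "or":
            out: Set[int] = set()
            for c in node.children:
                out |= run(c)
            return out
        if node.op == "not":
            return all_patients(store, qplan.cdb_cv_id) - run(node.children[0])
        raise QueryError(f"unknown plan node {node.op!r}")

    return run(qplan.root)


# ---------------------------------------------------------------------------
# clinical <-> expression traversal


def patients_to_assays(store: Store, patients: Sequence[int]) -> Set[int]:
    """Assays of any biomaterial whose patient-id property is in the input."""
    pids = set(int(p) for p in patients)
    known = {r[0] for r in store.conn.execute("SELECT patient_id FROM patient")}
    unknown = pids - known
    if unknown:
        warnings.warn(f"ignoring unknown patient ids: {sorted(unknown)}")
        pids -= unknown
    if not pids:
        return set()
    pid_term = store.internal_term("patient_id")
    marks = ",".join("?" * len(pids))
    sql = (
        "SELECT DISTINCT ab.assay_id FROM biomaterialprop bp"
        " JOIN assay_biomaterial ab ON ab.biomaterial_id = bp.biomaterial_id"
        f" WHERE bp.type_id = ? AND CAST(bp.value AS INTEGER) IN ({marks})"
    )
    return {r[0] for r in store.conn.execute(sql, [pid_term, *sorted(pids)])}


def assays_to_patients(store: Store, assays: Sequence[int]) -> Set[int]:
    """Patients owning any biomaterial used in the input assays."""
    aids = set(int(a) for a in assays)
    known = {r[0] for r in store.conn.execute("SELECT assay_id FROM assay")}
    unknown = aids - known
    if unknown:
        warnings.warn(f"ignoring unknown assay ids: {sorted(unknown)}")
        aids -= unknown
    if not aids:
        return set()
    pid_term = store.internal_term("patient_id")
    marks = ",".join("?" * len(aids))
    sql = (
        "SELECT DISTINCT CAST(bp.value AS INTEGER) FROM assay_biomaterial ab"
        " JOIN biomaterialprop bp ON bp.biomaterial_id = ab.biomaterial_id"
        f" WHERE bp.type_id = ? AND ab.assay_id IN ({marks})"
    )
    return {r[0] for r in store.conn.execute(sql, [pid_term, *sorted(aids)])}


def select_assays(store: Store, name: Optional[str] = None) -> Set[int]:
    """Assay selection by name equality (the supported assay filter)."""
    if name is None:
        return {r[0] for r in store.conn.execute("SELECT assay_id FROM assay")}
    return {
        r[0]
        for r in store.conn.execute("SELECT assay_id FROM assay WHERE name = ?", (name,))
    }


# ---------------------------------------------------------------------------
# integrated export


def export_integrated(
    store: Store,
    patients: Sequence[int],
    attributes: Sequence[str],
    assays: Sequence[int],
    wide: bool = True,
):
    """One row per linked (patient, assay) pair, with the requested
    clinical attributes pivoted into columns and the expression values
    wide (one column per feature) or long (feature/value columns).

    ``attributes`` are ``<cv>:<term>`` names.  An attribute absent for a
    patient yields a NULL cell; a multivalued attribute contributes its
    lowest-rank value.  Returns a pandas DataFrame; write it with
    ``df.to_csv(path, sep="\\t", index=False)``.
    """
    import pandas as pd

    pid_term = store.internal_term("patient_id")
    pids = sorted(set(int(p) for p in patients))
    aids = sorted(set(int(a) for a in assays))
    attr_ids = {}
    for attr in attributes:
        _, tid, dt = _resolve_term(store, attr)
        attr_ids[attr] = (tid, dt)

    pairs: List[Tuple[int, int]] = []
    if pids and aids:
        marks_p = ",".join("?" * len(pids))
        marks_a = ",".join("?" * len(aids))
        sql = (
            "SELECT DISTINCT CAST(bp.value AS INTEGER), ab.assay_id"
            " FROM biomaterialprop bp"
            " JOIN assay_biomaterial ab ON ab.biomaterial_id = bp.biomaterial_id"
            f" WHERE bp.type_id = ? AND CAST(bp.value AS INTEGER) IN ({marks_p})"
            f" AND ab.assay_id IN ({marks_a})"
            " ORDER BY 1, 2"
        )
        pairs = list(store.conn.execute(sql, [pid_term, *pids, *aids]))

    def attr_value(pid: int, tid: int):
        for table in ("csd", "patientprop"):
            row = store.conn.execute(
                f"SELECT value FROM {table} WHERE patient_id = ? AND type_id = ?"
                " ORDER BY rank LIMIT 1",
                (pid, tid),
            ).fetchone()
            if row:
                return row[0]
        return None

    assay_names = dict(store.conn.execute("SELECT assay_id, name FROM assay"))
    features = [
        r[0]
        for r in store.conn.execute(
            "SELECT DISTINCT feature_name FROM expression_value ORDER BY feature_name"
        )
    ]
    records = []
    for pid, aid in pairs:
        base = {"patient_id": pid, "assay_id": aid, "assay_name": assay_names.get(aid)}
        for attr, (tid, _dt) in attr_ids.items():
            base[attr] = attr_value(pid, tid)
        expr = dict(
            store.conn.execute(
                "SELECT feature_name, value FROM expression_value WHERE assay_id = ?",
                (aid,),
            )
        )
        if wide:
            for f in features:
                base[f] = expr.get(f)
            records.append(base)
        else:
            for f in features:
                if f in expr:
                    records.append({**base, "feature": f, "value": expr[f]})
    columns = ["patient_id", "assay_id", "assay_name", *attr_ids]
    columns += features if wide else ["feature", "value"]
    return pd.DataFrame.from_records(records, columns=columns)
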