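"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's SQL paths: the query oracle
evaluates boolean expressions by a full scan of the bridge-view rows
(clinical data pivoted back into table shape), and the pivot oracle
rebuilds a legacy table from raw ``csd`` rows in plain Python.
"""

from __future__ import annotations

import random
from typing import Dict, List, Optional, Set, Tuple

from iptrans._canon import is_null
from iptrans.bridge import read_view
from iptrans.query import And, Expr, Not, Or, Predicate


class AttributeIndex:
    """Resolve ``<db>:<table>.<column>`` to per-patient value lists by
    scanning bridge views."""

    def __init__(self, pipeline):
        self.p = pipeline
        schema = pipeline.model.to_schema()
        self.datatypes = {
            f"{t.name}.{c.name}": c.datatype for t in schema.tables for c in t.columns
        }
        self.pid_by_key = {skey: pid for pid, skey, _ in pipeline.store.patients()}
        self._values: Dict[str, Dict[int, List]] = {}
        for view in pipeline.views:
            table = schema.table(view.table_name)
            if table.name in pipeline.config.reference_tables:
                continue
            if table.name == pipeline.config.patient_table:
                link_col = table.key_column
            else:
                link_col = pipeline.config.patient_fk[table.name]
            for row in read_view(pipeline.store, view.view_name):
                pid = self.pid_by_key.get(str(row[link_col]))
                if pid is None:
                    continue
                for col in table.columns:
                    if col.name == link_col:
                        continue
                    qname = f"{table.name}.{col.name}"
                    self._values.setdefault(qname, {}).setdefault(pid, []).append(
                        row[col.name]
                    )

    def all_patients(self) -> Set[int]:
        return set(self.pid_by_key.values())

    def values(self, qname: str, pid: int) -> List:
        return self._values.get(qname, {}).get(pid, [])


def _cell_matches(cell, op: str, literal: str, datatype: str) -> bool:
    if is_null(cell):
        return False
    if op == "contains":
        return literal in str(cell)
    if datatype in ("integer", "decimal"):
        try:
            a, b = float(cell), float(literal)
        except ValueError:
            return False
    else:
        a, b = str(cell), str(literal)
    return {
        "=": a == b,
        "!=": a != b,
        "<": a < b,
        "<=": a <= b,
        ">": a > b,
        ">=": a >= b,
    }[op]


def evaluate(index: AttributeIndex, expr: Expr) -> Set[int]:
    """Full-scan evaluation of an expression over pivoted rows."""
    if isinstance(expr, Predicate):
        qname = expr.attribute.split(":", 1)[1]
        dt = index.datatypes[qname]
        out = set()
        for pid in index.all_patients():
            cells = index.values(qname, pid)
            hits = [_cell_matches(c, expr.operator, expr.literal, dt) for c in cells]
            if expr.all_ranks:
                present = [
                    _cell_matches(c, expr.operator, expr.literal, dt)
                    for c in cells
                    if not is_null(c)
                ]
                if present and all(present):
                    out.add(pid)
            elif any(hits):
                out.add(pid)
        return out
    if isinstance(expr, And):
        sets = [evaluate(index, c) for c in expr.children]
        result = sets[0]
        for s in sets[1:]:
            result &= s
        return result
    if isinstance(expr, Or):
        result: Set[int] = set()
        for c in expr.children:
            result |= evaluate(index, c)
        return result
    if isinstance(expr, Not):
        return index.all_patients() - evaluate(index, expr.child)
    raise TypeError(expr)


def random_expression(
    rng: random.Random,
    attributes: List[Tuple[str, str, List[str]]],
    depth: int = 3,
) -> Expr:
    """A random boolean expression over (qualified attribute, datatype,
    observed literals) triples, up to the given depth."""

    def leaf() -> Predicate:
        attr, dt, literals = rng.choice(attributes)
        if dt in ("integer", "decimal", "date"):
            op = rng.choice(["=", "!=", "<", "<=", ">", ">="])
        else:
            op = rng.choice(["=", "!=", "contains"])
        literal = rng.choice(literals)
        if op == "contains" and len(literal) > 2:
            start = rng.randrange(0, len(literal) - 1)
            literal = literal[start : start + rng.randint(1, 3)]
        return Predicate(attr, op, literal)

    def build(d: int) -> Expr:
        if d <= 1 or rng.random() < 0.35:
            return leaf()
        kind = rng.choice(["and", "or", "not"])
        if kind == "not":
            return Not(build(d - 1))
        n = rng.randint(2, 3)
        children = tuple(build(d - 1) for _ in range(n))
        return And(children) if kind == "and" else Or(children)

    return build(depth)


def attribute_pool(pipeline) -> List[Tuple[str, str, List[str]]]:
    """Queryable attributes of the synthetic database with literals
    drawn from the stored values."""
    schema = pipeline.model.to_schema()
    db = pipeline.model.db_name
    pool = []
    for table in schema.tables:
        if table.name in pipeline.config.reference_tables:
            continue
        fk = (
            table.key_column
            if table.name == pipeline.config.patient_table
            else pipeline.config.patient_fk[table.name]
        )
        for col in table.columns:
            if col.name in (fk, table.key_column):
                continue
            tid = pipeline.store.term_id(db, f"{table.name}.{col.name}")
            values = [
                r[0]
                for r in pipeline.store.conn.execute(
                    "SELECT DISTINCT value FROM csd WHERE type_id = ?"
                    " UNION SELECT DISTINCT value FROM patientprop WHERE type_id = ?"
                    " LIMIT 20",
                    (tid, tid),
                )
                if r[0] is not None
            ]
            if values:
                pool.append((f"{db}:{table.name}.{col.name}", col.datatype, values))
    return pool
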