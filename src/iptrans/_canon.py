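"""Datatype parsing and canonical text rendering for EAV values.

Every value in the store is text; the datatype annotation lives on the
model term and drives parsing at migration time and casting at query /
pivot time.  Canonical rendering makes the legacy-table round trip
well-defined: integers carry no decimal point, decimals use the shortest
faithful representation, dates are ISO-8601, booleans are "true"/"false".
"""

from __future__ import annotations

import datetime
import re

#: The closed set of column datatypes, in inference precedence order.
DATATYPES = ("integer", "decimal", "date", "boolean", "text")

_INT_RE = re.compile(r"^[+-]?\d+$")
_DEC_RE = re.compile(r"^[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?$")


def parses_as(value: str, datatype: str) -> bool:
    """True if the text cell is a valid literal of ``datatype``."""
    if datatype == "text":
        return True
    v = value.strip()
    if not v:
        return False
    if datatype == "integer":
        return bool(_INT_RE.match(v))
    if datatype == "decimal":
        return bool(_DEC_RE.match(v))
    if datatype == "date":
        try:
            datetime.date.fromisoformat(v)
            return True
        except ValueError:
            return False
    if datatype == "boolean":
        return v.lower() in ("true", "false")
    raise ValueError(f"unknown datatype: {datatype!r}")


def infer_datatype(cells) -> str:
    """Infer a column datatype from its non-empty cells.

    A column is integer / decimal / date / boolean iff *all* non-empty
    cells parse as such, tested in that precedence; otherwise text.
    Deterministic — every cell is examined, no sampling.
    """
    observed = [c for c in cells if c is not None and str(c).strip() != ""]
    if not observed:
        return "text"
    for dt in ("integer", "decimal", "date", "boolean"):
        if all(parses_as(str(c), dt) for c in observed):
            return dt
    return "text"


def canonicalize(value: str, datatype: str) -> str:
    """Render a cell in canonical text form for its datatype.

    Raises ValueError when the cell does not parse, so callers can log
    the violation and fall back to storing the raw text.
    """
    v = str(value).strip()
    if datatype == "text":
        return str(value)
    if not parses_as(v, datatype):
        raise ValueError(f"{value!r} is not a valid {datatype}")
    if datatype == "integer":
        return str(int(v))
    if datatype == "decimal":
        f = float(v)
        if f == int(f) and abs(f) < 1e15:
            # shortest form that still reads back as the same float
            return f"{int(f)}.0"
        return repr(f)
    if datatype == "date":
        return datetime.date.fromisoformat(v).isoformat()
    if datatype == "boolean":
        return v.lower()
    raise ValueError(f"unknown datatype: {datatype!r}")


def is_null(cell) -> bool:
    """NULL convention: Python None or an empty / whitespace-only string."""
    return cell is None or str(cell).strip() == ""


def cast_sql(expr: str, datatype: str) -> str:
    """SQL expression casting a stored text value for typed output."""
    if datatype == "integer":
        return f"CAST({expr} AS INTEGER)"
    if datatype == "decimal":
        return f"CAST({expr} AS REAL)"
    return expr
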