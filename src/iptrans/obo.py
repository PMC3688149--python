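"""Minimal OBO 1.2 flat-file reader and writer.

Covers the subset needed to exchange clinical-database models and
reference ontologies: ``[Term]`` stanzas with ``id``, ``name``, ``def``,
``is_a`` and ``property_value`` lines, and ``[Typedef]`` stanzas for
relations.  Anything else in a stanza is preserved verbatim on read and
ignored; malformed stanzas raise :class:`OboParseError` with the
offending line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple


class OboParseError(Exception):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass
class OboTerm:
    id: str
    name: str = ""
    definition: Optional[str] = None
    is_a: List[str] = field(default_factory=list)
    # property_value: (property, value) pairs, order preserved
    property_values: List[Tuple[str, str]] = field(default_factory=list)

    def prop(self, key: str) -> Optional[str]:
        for k, v in self.property_values:
            if k == key:
                return v
        return None


@dataclass
class OboTypedef:
    id: str
    name: str = ""


@dataclass
class OboDocument:
    header: Dict[str, str] = field(default_factory=dict)
    terms: List[OboTerm] = field(default_factory=list)
    typedefs: List[OboTypedef] = field(default_factory=list)

    def term_by_id(self) -> Dict[str, OboTerm]:
        return {t.id: t for t in self.terms}


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _unquote(text: str, lineno: int) -> str:
    text = text.strip()
    if not text.startswith('"'):
        raise OboParseError("expected a quoted string", lineno)
    out = []
    i = 1
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            out.append(text[i + 1])
            i += 2
            continue
        if ch == '"':
            return "".join(out)
        out.append(ch)
        i += 1
    raise OboParseError("unterminated quoted string", lineno)


def write_obo(doc: OboDocument) -> str:
    lines: List[str] = []
    for key, value in doc.header.items():
        lines.append(f"{key}: {value}")
    for term in doc.terms:
        lines.append("")
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        if term.definition is not None:
            lines.append(f"def: {_quote(term.definition)} []")
        for parent in term.is_a:
            lines.append(f"is_a: {parent}")
        for prop, value in term.property_values:
            lines.append(f"property_value: {prop} {_quote(value)} xsd:string")
    for td in doc.typedefs:
        lines.append("")
        lines.append("[Typedef]")
        lines.append(f"id: {td.id}")
        lines.append(f"name: {td.name}")
    return "\n".join(lines) + "\n"


def parse_obo(text: str) -> OboDocument:
    doc = OboDocument()
    current: Optional[object] = None  # None = header, else OboTerm/OboTypedef
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!")[0].rstrip() if not raw.lstrip().startswith("!") else ""
        if not line.strip():
            continue
        if line.strip() == "[Term]":
            current = OboTerm(id="")
            doc.terms.append(current)
            continue
        if line.strip() == "[Typedef]":
            current = OboTypedef(id="")
            doc.typedefs.append(current)
            continue
        if line.strip().startswith("[") and line.strip().endswith("]"):
            raise OboParseError(f"unsupported stanza {line.strip()}", lineno)
        if ":" not in line:
            raise OboParseError(f"expected 'tag: value', got {line!r}", lineno)
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if current is None:
            doc.header[tag] = value
            continue
        if isinstance(current, OboTypedef):
            if tag == "id":
                current.id = value
            elif tag == "name":
                current.name = value
            continue
        if tag == "id":
            current.id = value
        elif tag == "name":
            current.name = value
        elif tag == "def":
            current.definition = _unquote(value, lineno)
        elif tag == "is_a":
            current.is_a.append(value.split("!")[0].strip())
        elif tag == "property_value":
            parts = value.split(None, 1)
            if len(parts) != 2:
                raise OboParseError("property_value needs a property and a value", lineno)
            prop, rest = parts
            current.property_values.append((prop, _unquote(rest, lineno)))
        # other tags ignored
    for i, term in enumerate(doc.terms):
        if not term.id:
            raise OboParseError(f"[Term] stanza #{i + 1} lacks an id")
    return doc
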