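"""The ontological mapping environment (OME).

Clinical sources are integrated through a common reference ontology
(CRO) acting as a mediated schema: every term of a source's clinical
database model may be exact-matched to one CRO concept, while one
concept may be matched from many terms across sources.  That asymmetry
is what lets a concept-level query fan out to every source that stores
the attribute.

Formally the environment is the 5-tuple

    OME = (CRO, S_k, SM_k, M_k, m),  k = 1..n

with S_k the source schemas, SM_k their models (r terms each), M_k the
per-source mapping sets (o relations, o <= r — each term maps at most
once) and m the exact-match relation kind.  A shipped toy CRO (~30
biomedical concepts with is_a structure) makes the package testable
out of the box; the loader accepts any OBO ontology, so a real
reference ontology can be substituted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from . import obo as obomod
from .cdbmodel import ClinicalDatabaseModel, SourceSchema

EXACT_MATCH = "exact match"


class MappingError(Exception):
    pass


class MembershipError(MappingError):
    """Term or concept not part of the environment."""


class ConflictError(MappingError):
    """Term already mapped."""


@dataclass
class ReferenceOntology:
    """A reference ontology: concepts, is_a edges, and (inert) relations."""

    name: str
    concepts: Dict[str, obomod.OboTerm] = field(default_factory=dict)  # by name
    is_a_parents: Dict[str, List[str]] = field(default_factory=dict)  # child -> parents
    relations: List[obomod.OboTypedef] = field(default_factory=list)

    @classmethod
    def from_obo(cls, text: str, name: Optional[str] = None) -> "ReferenceOntology":
        doc = obomod.parse_obo(text)
        by_id = doc.term_by_id()
        concepts: Dict[str, obomod.OboTerm] = {}
        for term in doc.terms:
            if term.name in concepts:
                raise MappingError(f"duplicate concept name {term.name!r}")
            concepts[term.name] = term
        parents: Dict[str, List[str]] = {}
        for term in doc.terms:
            for pid in term.is_a:
                if pid not in by_id:
                    raise MappingError(f"concept {term.id} has unknown parent {pid}")
                parents.setdefault(term.name, []).append(by_id[pid].name)
        onto = cls(
            name=name or doc.header.get("ontology", "reference"),
            concepts=concepts,
            is_a_parents=parents,
            relations=doc.typedefs,
        )
        if onto._has_cycle():
            raise MappingError("is_a edges of the reference ontology form a cycle")
        return onto

    @classmethod
    def toy(cls) -> "ReferenceOntology":
        """The shipped ~30-concept toy reference ontology."""
        text = (
            importlib.resources.files("iptrans.data").joinpath("toy_cro.obo").read_text()
        )
        return cls.from_obo(text)

    def _has_cycle(self) -> bool:
        state: Dict[str, int] = {}

        def dfs(node: str) -> bool:
            state[node] = 1
            for p in self.is_a_parents.get(node, ()):
                if state.get(p) == 1 or (state.get(p) is None and dfs(p)):
                    return True
            state[node] = 2
            return False

        return any(state.get(n) is None and dfs(n) for n in self.concepts)

    def descendants(self, concept: str) -> Set[str]:
        """All concepts below ``concept`` through is_a (excluding itself)."""
        if concept not in self.concepts:
            raise MembershipError(f"unknown concept {concept!r}")
        children: Dict[str, List[str]] = {}
        for child, parents in self.is_a_parents.items():
            for p in parents:
                children.setdefault(p, []).append(child)
        out: Set[str] = set()
        stack = [concept]
        while stack:
            for ch in children.get(stack.pop(), ()):
                if ch not in out:
                    out.add(ch)
                    stack.append(ch)
        return out


@dataclass(frozen=True)
class MappingRelation:
    """One exact match between a source-model term and a CRO concept."""

    source_index: int
    term: str
    concept: str
    kind: str = EXACT_MATCH


@dataclass
class OntologicalMappingEnvironment:
    """The 5-tuple (CRO, S_k, SM_k, M_k, m)."""

    cro: ReferenceOntology
    source_schemas: List[SourceSchema]
    source_models: List[ClinicalDatabaseModel]
    mapping_sets: List[List[MappingRelation]]
    match_kind: str = EXACT_MATCH

    @property
    def n_sources(self) -> int:
        return len(self.source_models)

    @property
    def all_mappings(self) -> List[MappingRelation]:
        """M — the union of every per-source mapping set."""
        return [m for ms in self.mapping_sets for m in ms]

    def components(self) -> Tuple:
        return (
            self.cro,
            self.source_schemas,
            self.source_models,
            self.mapping_sets,
            self.match_kind,
        )

    def model_terms(self, k: int) -> Set[str]:
        return set(self.source_models[k].term_names())


def create_ome(
    cro: ReferenceOntology,
    sources: List[Tuple[SourceSchema, ClinicalDatabaseModel]],
) -> OntologicalMappingEnvironment:
    """Assemble an environment with empty mapping sets."""
    for schema, model in sources:
        if model is None:
            raise MappingError(f"source {schema.db_name!r} has no model")
        if model.db_name != schema.db_name:
            raise MappingError(
                f"model {model.db_name!r} does not describe schema {schema.db_name!r}"
            )
    return OntologicalMappingEnvironment(
        cro=cro,
        source_schemas=[s for s, _ in sources],
        source_models=[m for _, m in sources],
        mapping_sets=[[] for _ in sources],
    )


def add_mapping(
    ome: OntologicalMappingEnvironment, k: int, term: str, concept: str
) -> OntologicalMappingEnvironment:
    """Add one exact match to M_k.  o <= r holds by construction: a term
    maps at most once and terms come from SM_k."""
    if not 0 <= k < ome.n_sources:
        raise MembershipError(f"no source with index {k}")
    if term not in ome.model_terms(k):
        raise MembershipError(f"term {term!r} is not in source model {k}")
    if concept not in ome.cro.concepts:
        raise MembershipError(f"concept {concept!r} is not in the reference ontology")
    if any(m.term == term for m in ome.mapping_sets[k]):
        raise ConflictError(f"term {term!r} of source {k} is already mapped")
    ome.mapping_sets[k].append(MappingRelation(k, term, concept))
    return ome


def translate_concept(
    ome: OntologicalMappingEnvironment, concept: str, expand_descendants: bool = False
) -> List[Tuple[int, str]]:
    """All (source, term) pairs exact-matched to the concept — and, with
    descendant expansion on, to any is_a descendant of it.  Deterministic
    order: (source index, term name)."""
    if concept not in ome.cro.concepts:
        raise MembershipError(f"unknown concept {concept!r}")
    wanted = {concept}
    if expand_descendants:
        wanted |= ome.cro.descendants(concept)
    hits = [
        (m.source_index, m.term) for m in ome.all_mappings if m.concept in wanted
    ]
    return sorted(hits)


# -- persistence ------------------------------------------------------------

_TSV_HEADER = "source\tterm\tconcept\tkind"


def mappings_to_tsv(ome: OntologicalMappingEnvironment) -> str:
    lines = [_TSV_HEADER]
    for m in ome.all_mappings:
        lines.append(f"{m.source_index}\t{m.term}\t{m.concept}\texact")
    return "\n".join(lines) + "\n"


def mappings_from_tsv(ome: OntologicalMappingEnvironment, text: str) -> None:
    """Load mappings from TSV into an environment with empty sets."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _TSV_HEADER:
        raise MappingError("bad mapping file header")
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 4 or parts[3] != "exact":
            raise MappingError(f"bad mapping line {ln!r}")
        add_mapping(ome, int(parts[0]), parts[1], parts[2])
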