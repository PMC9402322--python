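"""Triple-based mechanistic knowledge graph.

Entities are identified by concept ids (UMLS-style CUIs, ``C`` followed by
seven digits, or source-prefixed tokens such as ``DB:...`` for external
records that never resolved to a CUI).  Facts are subject-predicate-object
triples with set semantics; each triple carries the set of source tags
(provenance) that asserted it.  Entity records hold labels, semantic-type
codes and the ontology classification filled in by the validator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .vocab import default_registry

CUI_PATTERN = re.compile(r"^C\d{7}$")

#: Allowed provenance tags.
PROVENANCE_TAGS = (
    "MRCONSO",
    "MRREL",
    "MRSAT",
    "DRUGLINK",
    "GENELINK",
    "FIXTURE",
    "INFERRED",
)


class ConceptIdError(ValueError):
    """Raised when a token is not a well-formed concept identifier."""


def validate_concept_id(token: str) -> str:
    """Check that *token* is a valid concept id and return it.

    Valid ids are CUIs (``C`` + 7 digits) or source-prefixed external ids
    (``SOURCE:local``).  The pipe character is reserved by the RRF dialect
    and never allowed.
    """
    if not isinstance(token, str) or not token:
        raise ConceptIdError(f"empty or non-string concept id: {token!r}")
    if "|" in token:
        raise ConceptIdError(f"concept id contains reserved '|': {token!r}")
    if CUI_PATTERN.match(token):
        return token
    prefix, sep, local = token.partition(":")
    if sep and prefix and local:
        return token
    raise ConceptIdError(f"malformed concept id: {token!r}")


def is_concept_id(token: str) -> bool:
    try:
        validate_concept_id(token)
        return True
    except ConceptIdError:
        return False


@dataclass(frozen=True)
class Triple:
    """One fact.  Identity (for set semantics) is (subject, predicate, object,
    object_is_literal); provenance tags are merged on re-add."""

    subject: str
    predicate: str
    object: str
    object_is_literal: bool = False
    provenance: tuple = ()

    def key(self) -> tuple:
        return (self.subject, self.predicate, self.object, self.object_is_literal)


class Variable(str):
    """A named variable in a triple pattern (``Variable("x")``)."""

    __slots__ = ()

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"?{str.__str__(self)}"


def _term(value):
    """Parse a pattern term: strings starting with '?' become variables."""
    if isinstance(value, Variable):
        return value
    if isinstance(value, str) and value.startswith("?"):
        return Variable(value[1:])
    return value


@dataclass(frozen=True)
class TriplePattern:
    """A triple with constants and/or variables; zero variables makes it a
    membership test."""

    subject: object
    predicate: object
    object: object

    @classmethod
    def parse(cls, subject, predicate, object) -> "TriplePattern":
        return cls(_term(subject), _term(predicate), _term(object))

    def variables(self) -> list:
        return [t for t in (self.subject, self.predicate, self.object) if isinstance(t, Variable)]


@dataclass
class EntityRecord:
    """Annotations attached to a concept id."""

    labels: list = field(default_factory=list)
    semantic_types: set = field(default_factory=set)
    core_class: Optional[str] = None
    subclass: Optional[str] = None
    subclass_candidates: set = field(default_factory=set)

    def add_label(self, label: str) -> None:
        if label and label not in self.labels:
            self.labels.append(label)

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "semantic_types": sorted(self.semantic_types),
            "core_class": self.core_class,
            "subclass": self.subclass,
            "subclass_candidates": sorted(self.subclass_candidates),
        }


class KnowledgeGraph:
    """In-memory triple store with entity annotations and pattern matching."""

    def __init__(self, registry: Optional[dict] = None):
        self.registry = registry if registry is not None else default_registry()
        self._triples: dict = {}  # key tuple -> set of provenance tags
        self.entities: dict = {}  # concept id -> EntityRecord

    # -- construction -----------------------------------------------------

    def ensure_entity(self, concept_id: str, label: Optional[str] = None) -> EntityRecord:
        validate_concept_id(concept_id)
        rec = self.entities.get(concept_id)
        if rec is None:
            rec = self.entities[concept_id] = EntityRecord()
        if label:
            rec.add_label(label)
        return rec

    def object_is_literal(self, predicate: str, obj: str) -> bool:
        """Decide literal-ness of an object from the registry, falling back
        to the token shape for unregistered predicates."""
        spec = self.registry.get(predicate)
        if spec is not None:
            return spec.object_kind == "literal"
        return not is_concept_id(obj)

    def add_triple(
        self,
        subject: str,
        predicate: str,
        obj: str,
        provenance: str = "FIXTURE",
        object_is_literal: Optional[bool] = None,
    ) -> Triple:
        """Add one fact; idempotent.  Entity records are auto-created for
        any new concept ids.  Malformed ids raise :class:`ConceptIdError`
        naming the offending token."""
        validate_concept_id(subject)
        if object_is_literal is None:
            object_is_literal = self.object_is_literal(predicate, obj)
        if not object_is_literal:
            validate_concept_id(obj)
        if "|" in obj:
            raise ConceptIdError(f"object contains reserved '|': {obj!r}")
        self.ensure_entity(subject)
        if not object_is_literal:
            self.ensure_entity(obj)
        key = (subject, predicate, obj, object_is_literal)
        tags = self._triples.setdefault(key, set())
        if provenance:
            tags.add(provenance)
        return self._as_triple(key)

    def add(self, t: Triple) -> Triple:
        out = None
        for tag in t.provenance or ("FIXTURE",):
            out = self.add_triple(t.subject, t.predicate, t.object, tag, t.object_is_literal)
        return out

    # -- access -----------------------------------------------------------

    def _as_triple(self, key: tuple) -> Triple:
        s, p, o, lit = key
        return Triple(s, p, o, lit, tuple(sorted(self._triples[key])))

    def triples(self) -> Iterator[Triple]:
        for key in self._triples:
            yield self._as_triple(key)

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, t) -> bool:
        if isinstance(t, Triple):
            return t.key() in self._triples
        if isinstance(t, tuple) and len(t) == 3:
            s, p, o = t
            return (s, p, o, True) in self._triples or (s, p, o, False) in self._triples
        return False

    def has(self, subject: str, predicate: str, obj: str) -> bool:
        return (subject, predicate, obj) in self

    def predicates(self) -> set:
        return {p for (_, p, _, _) in self._triples}

    # -- pattern matching -------------------------------------------------

    def match(self, pattern: TriplePattern) -> list:
        """All variable bindings under which *pattern* instantiates to a
        triple in the graph, as a list of dicts sorted lexicographically on
        bound values.  A fully ground pattern returns ``[{}]`` if the
        triple is present, else ``[]``."""
        out = []
        for key in self._triples:
            s, p, o, _ = key
            binding = _unify_triple(pattern, s, p, o)
            if binding is not None and binding not in out:
                out.append(binding)
        out.sort(key=lambda b: tuple(sorted(b.items())))
        return out

    def match_triples(self, pattern: TriplePattern) -> list:
        """The matching triples themselves, deterministically ordered."""
        hits = []
        for key in self._triples:
            s, p, o, _ = key
            if _unify_triple(pattern, s, p, o) is not None:
                hits.append(self._as_triple(key))
        hits.sort(key=lambda t: t.key())
        return hits

    # -- whole-graph operations -------------------------------------------

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph(registry=dict(self.registry))
        g._triples = {k: set(v) for k, v in self._triples.items()}
        for cid, rec in self.entities.items():
            g.entities[cid] = EntityRecord(
                labels=list(rec.labels),
                semantic_types=set(rec.semantic_types),
                core_class=rec.core_class,
                subclass=rec.subclass,
                subclass_candidates=set(rec.subclass_candidates),
            )
        return g

    def triple_set(self) -> set:
        return set(self._triples)

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            {k: frozenset(v) for k, v in self._triples.items()}
            == {k: frozenset(v) for k, v in other._triples.items()}
            and {c: r.as_dict() for c, r in self.entities.items()}
            == {c: r.as_dict() for c, r in other.entities.items()}
        )


def _unify_triple(pattern: TriplePattern, s: str, p: str, o: str):
    binding: dict = {}
    for term, value in ((pattern.subject, s), (pattern.predicate, p), (pattern.object, o)):
        if isinstance(term, Variable):
            name = str(term)
            if name in binding:
                if binding[name] != value:
                    return None
            else:
                binding[name] = value
        elif term != value:
            return None
    return binding
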