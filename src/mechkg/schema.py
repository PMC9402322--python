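"""Four-class / seven-subclass ontology, instance classification and the
structural consistency check.

The ontology covers four core levels — pharmacological, biomolecular,
physiological and genetic — with seven subclasses: drugs under
pharmacological; genes, enzymes and biological processes under
biomolecular; effect and mechanism of action under physiological; and
SNPs under genetic.  Instances are assigned to subclasses through their
UMLS-style semantic-type codes (e.g. T028, Gene or Genome, classifies to
the genes subclass).  Transporter proteins such as ABCB1 live in the
enzymes subclass and are distinguished by a ``has_role`` annotation, so
the seven-subclass shape is preserved while the rule layer can still tell
metabolizing enzymes from transporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .kgraph import KnowledgeGraph
from .vocab import default_registry

CORE_CLASSES = ["pharmacological", "biomolecular", "physiological", "genetic"]

SUBCLASS_TO_CORE = {
    "drugs": "pharmacological",
    "genes": "biomolecular",
    "enzymes": "biomolecular",
    "biological_processes": "biomolecular",
    "effect": "physiological",
    "mechanism_of_action": "physiological",
    "snps": "genetic",
}

# Default semantic-type -> subclass assignments.  T028 (Gene or Genome) ->
# genes is fixed by the terminology; the remaining codes are the package's
# minimal working set and are fully overridable in the run config.
DEFAULT_SEMTYPE_MAP = {
    "T121": "drugs",  # Pharmacologic Substance
    "T109": "drugs",  # Organic Chemical
    "T200": "drugs",  # Clinical Drug
    "T028": "genes",  # Gene or Genome
    "T126": "enzymes",  # Enzyme
    "T116": "enzymes",  # Amino Acid, Peptide, or Protein
    "T043": "biological_processes",  # Cell Function
    "T038": "biological_processes",  # Biologic Function
    "T044": "mechanism_of_action",  # Molecular Function
    "T042": "mechanism_of_action",  # Organ or Tissue Function
    "T046": "effect",  # Pathologic Function
    "T047": "effect",  # Disease or Syndrome
    "T184": "effect",  # Sign or Symptom
    "T086": "snps",  # Nucleotide Sequence
}

VIOLATION_KINDS = (
    "UNCLASSIFIED",
    "MULTI_CLASS_CONFLICT",
    "DOMAIN_VIOLATION",
    "RANGE_VIOLATION",
    "UNKNOWN_PREDICATE",
)


@dataclass
class Schema:
    core_classes: list = field(default_factory=lambda: list(CORE_CLASSES))
    subclasses: dict = field(default_factory=lambda: dict(SUBCLASS_TO_CORE))
    semtype_map: dict = field(default_factory=lambda: dict(DEFAULT_SEMTYPE_MAP))
    relation_constraints: dict = field(default_factory=dict)
    #: treat unclassified entities as violations rather than warnings
    strict_unclassified: bool = False
    #: apply predicate domain/range constraints
    check_domain_range: bool = True

    def __post_init__(self):
        for sub, core in self.subclasses.items():
            if core not in self.core_classes:
                raise ValueError(f"subclass {sub!r} maps to unknown core {core!r}")
        for code, sub in self.semtype_map.items():
            if sub not in self.subclasses:
                raise ValueError(f"semantic type {code!r} maps to unknown subclass {sub!r}")

    def core_of(self, subclass: str) -> Optional[str]:
        return self.subclasses.get(subclass)


@dataclass(frozen=True)
class Violation:
    kind: str
    subject: str  # entity id or triple rendering
    detail: str


@dataclass
class ConsistencyReport:
    violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def is_consistent(self) -> bool:
        return not self.violations

    def by_kind(self, kind: str) -> list:
        return [v for v in self.violations if v.kind == kind]

    def as_dict(self) -> dict:
        return {
            "is_consistent": self.is_consistent,
            "violations": [
                {"kind": v.kind, "subject": v.subject, "detail": v.detail}
                for v in self.violations
            ],
            "warnings": [
                {"kind": v.kind, "subject": v.subject, "detail": v.detail}
                for v in self.warnings
            ],
        }


def default_schema(registry: Optional[dict] = None, **overrides) -> Schema:
    """The default ontology: 4 core classes, 7 subclasses, the default
    semantic-type map, and domain/range constraints drawn from the
    predicate registry."""
    registry = registry if registry is not None else default_registry()
    constraints = {
        name: (spec.domain, spec.range_ if spec.object_kind == "concept" else None)
        for name, spec in registry.items()
    }
    return Schema(relation_constraints=constraints, **overrides)


def classify(graph: KnowledgeGraph, schema: Schema) -> KnowledgeGraph:
    """Assign subclass/core-class to every entity from its semantic types.

    Entities whose types map to several subclasses keep all candidates
    (the consistency check decides whether that is a conflict); entities
    with no mapped type remain unclassified.  Idempotent; mutates and
    returns *graph*.
    """
    for rec in graph.entities.values():
        candidates = {
            schema.semtype_map[t]
            for t in rec.semantic_types
            if t in schema.semtype_map
        }
        rec.subclass_candidates = candidates
        if len(candidates) == 1:
            rec.subclass = next(iter(candidates))
            rec.core_class = schema.core_of(rec.subclass)
        else:
            rec.subclass = None
            cores = {schema.core_of(c) for c in candidates}
            rec.core_class = cores.pop() if len(cores) == 1 else None
    return graph


def check_consistency(graph: KnowledgeGraph, schema: Schema) -> ConsistencyReport:
    """Structural consistency of a classified graph.

    Emits MULTI_CLASS_CONFLICT when an entity's candidate subclasses span
    more than one core class; DOMAIN/RANGE_VIOLATION when a triple's
    endpoints are classified outside the predicate's declared constraint;
    UNKNOWN_PREDICATE for predicates absent from the registry.
    Unclassified entities are warnings by default
    (``schema.strict_unclassified`` promotes them).
    """
    report = ConsistencyReport()

    for cid in sorted(graph.entities):
        rec = graph.entities[cid]
        cores = {schema.core_of(c) for c in rec.subclass_candidates}
        if len(cores) > 1:
            report.violations.append(
                Violation(
                    "MULTI_CLASS_CONFLICT",
                    cid,
                    "candidate subclasses %s span core classes %s"
                    % (sorted(rec.subclass_candidates), sorted(c for c in cores if c)),
                )
            )
        elif not rec.subclass_candidates:
            v = Violation("UNCLASSIFIED", cid, "no semantic type maps to a subclass")
            (report.violations if schema.strict_unclassified else report.warnings).append(v)

    for t in sorted(graph.triples(), key=lambda t: t.key()):
        rendering = f"({t.subject}, {t.predicate}, {t.object})"
        if t.predicate not in schema.relation_constraints:
            report.violations.append(
                Violation("UNKNOWN_PREDICATE", rendering, f"predicate {t.predicate!r} is not registered")
            )
            continue
        if not schema.check_domain_range:
            continue
        domain, range_ = schema.relation_constraints[t.predicate]
        if domain is not None:
            cand = graph.entities[t.subject].subclass_candidates
            if cand and not (cand & set(domain)):
                report.violations.append(
                    Violation(
                        "DOMAIN_VIOLATION",
                        rendering,
                        f"subject classified as {sorted(cand)}, allowed {sorted(domain)}",
                    )
                )
        if range_ is not None and not t.object_is_literal:
            cand = graph.entities[t.object].subclass_candidates
            if cand and not (cand & set(range_)):
                report.violations.append(
                    Violation(
                        "RANGE_VIOLATION",
                        rendering,
                        f"object classified as {sorted(cand)}, allowed {sorted(range_)}",
                    )
                )
    return report
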