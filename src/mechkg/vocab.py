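"""Registered relation vocabulary.

Every predicate that may appear in the mechanistic knowledge graph is
declared here: whether its object is a concept identifier or a controlled
literal, which similarity level (if any) it contributes to for
shared-feature matching, and its domain/range constraints in terms of the
ontology subclasses.  The registry is data, not behaviour: ETL, validation
and the rule layer all consult it, and callers may extend or override it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


# Similarity levels used by the shared-feature layer.  The four ontology
# core levels plus the two evidence types the interaction report uses
# (contraindication-on-allergy and shared substructure classes).
FEATURE_LEVELS = (
    "pharmacological",
    "biomolecular",
    "physiological",
    "genetic",
    "contraindication",
    "substructure",
)

#: Roles a protein target can play in a pharmacokinetic mechanism.
TARGET_ROLES = ("metabolizing_enzyme", "transporter")


@dataclass(frozen=True)
class PredicateSpec:
    """Declaration of a single relation.

    ``object_kind`` is ``"concept"`` (object must be a well-formed concept
    id) or ``"literal"`` (object is an uninterpreted string).
    ``feature_level`` marks predicates whose facts count as drug features
    at that similarity level.  ``domain``/``range_`` are sets of ontology
    subclass names; ``None`` means unconstrained.
    """

    name: str
    object_kind: str = "concept"
    feature_level: Optional[str] = None
    domain: Optional[frozenset] = None
    range_: Optional[frozenset] = None

    def __post_init__(self):
        if self.object_kind not in ("concept", "literal"):
            raise ValueError(f"bad object_kind {self.object_kind!r}")
        if self.feature_level is not None and self.feature_level not in FEATURE_LEVELS:
            raise ValueError(f"unknown feature level {self.feature_level!r}")


def _fs(*names: str) -> frozenset:
    return frozenset(names)


def default_registry() -> dict:
    """The default predicate registry, keyed by predicate name."""
    specs = [
        # pharmacokinetic mechanism predicates (layer 1)
        PredicateSpec("inhibits", domain=_fs("drugs"), range_=_fs("enzymes")),
        PredicateSpec("induces", domain=_fs("drugs"), range_=_fs("enzymes")),
        PredicateSpec("substrate_of", domain=_fs("drugs"), range_=_fs("enzymes")),
        # role annotation distinguishing metabolizing enzymes from transporters
        PredicateSpec("has_role", object_kind="literal", domain=_fs("enzymes")),
        # feature predicates (layer 2)
        PredicateSpec(
            "has_mechanism_of_action",
            feature_level="pharmacological",
            domain=_fs("drugs"),
            range_=_fs("mechanism_of_action"),
        ),
        PredicateSpec(
            "participates_in",
            feature_level="biomolecular",
            domain=_fs("drugs", "genes", "enzymes"),
            range_=_fs("biological_processes"),
        ),
        PredicateSpec(
            "has_target",
            feature_level="biomolecular",
            domain=_fs("drugs"),
            range_=_fs("enzymes", "genes"),
        ),
        PredicateSpec(
            "has_effect",
            feature_level="physiological",
            domain=_fs("drugs"),
            range_=_fs("effect"),
        ),
        PredicateSpec(
            "gene_association",
            feature_level="genetic",
            domain=_fs("drugs"),
            range_=_fs("genes"),
        ),
        PredicateSpec(
            "has_variant_association",
            feature_level="genetic",
            domain=_fs("drugs", "genes"),
            range_=_fs("snps"),
        ),
        PredicateSpec(
            "contraindicated_if",
            feature_level="contraindication",
            domain=_fs("drugs"),
            range_=_fs("effect"),
        ),
        PredicateSpec(
            "has_substructure_class",
            object_kind="literal",
            feature_level="substructure",
            domain=_fs("drugs"),
        ),
        # terminology hierarchy (unconstrained)
        PredicateSpec("related_to"),
        PredicateSpec("parent_of"),
        PredicateSpec("child_of"),
        PredicateSpec("broader"),
        PredicateSpec("narrower"),
    ]
    return {s.name: s for s in specs}


def feature_level_map(registry: dict) -> dict:
    """Map predicate name -> similarity level, for feature predicates only."""
    return {
        name: spec.feature_level
        for name, spec in registry.items()
        if spec.feature_level is not None
    }
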