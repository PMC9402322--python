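"""The six-rule, two-layer drug-drug interaction framework.

Layer 1 (rules R1-R4) detects a pharmacokinetic mechanism: one drug of
the pair (the perpetrator) inhibits or induces a metabolizing enzyme or
transporter that the other drug (the victim) is a substrate of.  Layer 2
(rule R5) detects shared biomedical features between the two drugs,
grouped into similarity levels (the four ontology levels plus
contraindication-on-allergy and shared substructure classes).  The
combination rule R6 accepts a pair as a potential DDI when a mechanism
exists in either direction and at least ``theta`` distinct similarity
levels are shared.

The rule base is loaded from a YAML file shipped with the package, so the
rules can be revised without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .engine import (
    Atom,
    BuiltinCheck,
    FactLeaf,
    ProofResult,
    RuleApp,
    RuleBase,
    VirtualPredicate,
    backward_chain,
    load_rulebase,
)
from .kgraph import KnowledgeGraph, TriplePattern, Variable
from .vocab import default_registry, feature_level_map

DEFAULT_THETA = 1

#: interaction flavor by mechanism mode: inhibition raises the victim's
#: exposure, induction reduces it; the verdict treats them identically.
MODE_FLAVOR = {"inhibition": "increased exposure", "induction": "reduced exposure"}
MODE_ROLE = {"inhibition": "inhibitor", "induction": "inducer"}
RULE_TARGET_KIND = {
    "R1": "metabolizing_enzyme",
    "R2": "metabolizing_enzyme",
    "R3": "transporter",
    "R4": "transporter",
}


class UnknownDrugError(KeyError):
    def __init__(self, drug_id: str):
        super().__init__(drug_id)
        self.drug_id = drug_id

    def __str__(self):
        return f"unknown drug id: {self.drug_id!r}"


def feature_view(registry: Optional[dict] = None) -> VirtualPredicate:
    """The feature/3 view: ``feature(D, level, V)`` holds for every stored
    triple ``(D, p, V)`` whose predicate *p* is registered at a similarity
    level."""
    registry = registry if registry is not None else default_registry()
    levels = feature_level_map(registry)

    def resolver(graph: KnowledgeGraph):
        for t in sorted(graph.triples(), key=lambda t: t.key()):
            level = levels.get(t.predicate)
            if level is not None:
                yield (t.subject, level, t.object), t

    return VirtualPredicate("feature", 3, resolver)


def default_rulebase(theta: int = DEFAULT_THETA, registry: Optional[dict] = None) -> RuleBase:
    """Load the shipped six-rule base with the shared-level threshold
    substituted into the combination rule."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    text = resources.files("mechkg.data").joinpath("rules_default.yaml").read_text()
    return load_rulebase(
        text, params={"theta": theta}, virtuals={"feature": feature_view(registry)}
    )


# ---------------------------------------------------------------------------
# match records


@dataclass(frozen=True)
class MechanismMatch:
    target: str
    target_kind: str  # metabolizing_enzyme | transporter
    perpetrator: str
    perpetrator_role: str  # inhibitor | inducer
    victim: str
    rule_id: str
    proof: object = None

    @property
    def mode(self) -> str:
        return "inhibition" if self.perpetrator_role == "inhibitor" else "induction"

    @property
    def flavor(self) -> str:
        return MODE_FLAVOR[self.mode]

    def identity(self) -> tuple:
        return (self.target, self.target_kind, self.perpetrator, self.perpetrator_role, self.victim, self.rule_id)

    def as_dict(self) -> dict:
        return {
            "target": self.target,
            "target_kind": self.target_kind,
            "perpetrator": self.perpetrator,
            "perpetrator_role": self.perpetrator_role,
            "victim": self.victim,
            "rule": self.rule_id,
            "flavor": self.flavor,
        }


@dataclass(frozen=True)
class FeatureMatch:
    level: str
    shared_value: str
    evidence: tuple  # pair of graph triples (s, p, o)

    def identity(self) -> tuple:
        return (self.level, self.shared_value)

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "shared_value": self.shared_value,
            "evidence": [list(e) for e in self.evidence],
        }


@dataclass
class DDIAssessment:
    drug_a: str
    drug_b: str
    mechanism_matches: list
    feature_matches: list
    threshold: int
    verdict: str  # POTENTIAL_DDI | NO_EVIDENCE
    rationale: list = field(default_factory=list)
    labels: dict = field(default_factory=dict)
    proof_results: list = field(default_factory=list)

    @property
    def shared_level_count(self) -> int:
        return len({m.level for m in self.feature_matches})

    @property
    def shared_levels(self) -> list:
        return sorted({m.level for m in self.feature_matches})

    def as_dict(self) -> dict:
        return {
            "drug_a": self.drug_a,
            "drug_b": self.drug_b,
            "labels": dict(self.labels),
            "threshold": self.threshold,
            "verdict": self.verdict,
            "mechanism_matches": [m.as_dict() for m in self.mechanism_matches],
            "feature_matches": [m.as_dict() for m in self.feature_matches],
            "shared_level_count": self.shared_level_count,
            "shared_levels": self.shared_levels,
            "rationale": list(self.rationale),
            "proofs": [pr.to_dict() for pr in self.proof_results],
        }


# ---------------------------------------------------------------------------
# layers


def _require_drug(graph: KnowledgeGraph, drug: str) -> None:
    if drug not in graph.entities:
        raise UnknownDrugError(drug)


def pharmacological_effect_layer(
    graph: KnowledgeGraph,
    drug_a: str,
    drug_b: str,
    rulebase: Optional[RuleBase] = None,
) -> list:
    """All layer-1 mechanism matches for the pair, in both orderings
    (either drug may be the perpetrator), each with its proof."""
    _require_drug(graph, drug_a)
    _require_drug(graph, drug_b)
    rb = rulebase if rulebase is not None else default_rulebase()
    matches: dict = {}
    for perp, victim in ((drug_a, drug_b), (drug_b, drug_a)):
        goal = Atom("mech", (perp, victim, Variable("T"), Variable("M")))
        for answer in backward_chain(graph, rb, goal).answers:
            _, args = answer.atom
            target, mode = args[2], args[3]
            for proof in answer.proofs:
                if not isinstance(proof, RuleApp):
                    continue
                kind = RULE_TARGET_KIND.get(proof.rule_id)
                if kind is None:
                    continue
                m = MechanismMatch(
                    target=target,
                    target_kind=kind,
                    perpetrator=perp,
                    perpetrator_role=MODE_ROLE[mode],
                    victim=victim,
                    rule_id=proof.rule_id,
                    proof=proof,
                )
                matches.setdefault(m.identity(), m)
    return [matches[k] for k in sorted(matches)]


def shared_feature_layer(
    graph: KnowledgeGraph,
    drug_a: str,
    drug_b: str,
    rulebase: Optional[RuleBase] = None,
) -> tuple:
    """All layer-2 shared-feature matches and the number of distinct
    similarity levels matched."""
    _require_drug(graph, drug_a)
    _require_drug(graph, drug_b)
    rb = rulebase if rulebase is not None else default_rulebase()
    goal = Atom("shared", (drug_a, drug_b, Variable("L"), Variable("V")))
    matches: dict = {}
    for answer in backward_chain(graph, rb, goal).answers:
        _, args = answer.atom
        level, value = args[2], args[3]
        evidence = _feature_evidence(answer.proofs)
        m = FeatureMatch(level=level, shared_value=value, evidence=evidence)
        matches.setdefault(m.identity(), m)
    ordered = [matches[k] for k in sorted(matches)]
    return ordered, len({m.level for m in ordered})


def _feature_evidence(proofs) -> tuple:
    for proof in proofs:
        if isinstance(proof, RuleApp):
            sources = tuple(
                c.source
                for c in proof.children
                if isinstance(c, FactLeaf) and c.source is not None
            )
            if sources:
                return sources
    return ()


def assess_ddi(
    graph: KnowledgeGraph,
    drug_a: str,
    drug_b: str,
    theta: int = DEFAULT_THETA,
    rulebase: Optional[RuleBase] = None,
    registry: Optional[dict] = None,
) -> DDIAssessment:
    """Full two-layer assessment of one drug pair.

    The verdict is driven by backward chaining on the combination rule's
    goal in both directions; it coincides with the invariant
    "mechanism exists and shared levels >= theta".  The match sets are
    symmetric in the pair up to role labeling.
    """
    _require_drug(graph, drug_a)
    _require_drug(graph, drug_b)
    rb = rulebase if rulebase is not None else default_rulebase(theta, registry)
    mechs = pharmacological_effect_layer(graph, drug_a, drug_b, rb)
    feats, n_levels = shared_feature_layer(graph, drug_a, drug_b, rb)
    results = [
        backward_chain(graph, rb, Atom("potential_ddi", (a, b)))
        for a, b in ((drug_a, drug_b), (drug_b, drug_a))
    ]
    accepted = any(r.status == "ACCEPTED" for r in results)
    verdict = "POTENTIAL_DDI" if accepted else "NO_EVIDENCE"

    labels = {d: _label(graph, d) for d in (drug_a, drug_b)}
    for m in mechs:
        labels.setdefault(m.target, _label(graph, m.target))
    for f in feats:
        if f.shared_value in graph.entities:
            labels.setdefault(f.shared_value, _label(graph, f.shared_value))
    rationale = []
    for m in mechs:
        rationale.append(
            f"{labels.get(m.perpetrator, m.perpetrator)} is a "
            f"{_label(graph, m.target)} {m.perpetrator_role} while "
            f"{labels.get(m.victim, m.victim)} is a substrate "
            f"({m.target_kind.replace('_', ' ')}; expected {m.flavor} of the victim)."
        )
    if feats:
        rationale.append(
            "Shared biomedical features at %d level(s): %s."
            % (n_levels, ", ".join(sorted({m.level for m in feats})))
        )
    if not accepted:
        if not mechs:
            rationale.append("No pharmacokinetic mechanism links the pair.")
        elif n_levels < theta:
            rationale.append(
                f"Only {n_levels} shared similarity level(s); threshold is {theta}."
            )
    return DDIAssessment(
        drug_a=drug_a,
        drug_b=drug_b,
        mechanism_matches=mechs,
        feature_matches=feats,
        threshold=theta,
        verdict=verdict,
        rationale=rationale,
        labels=labels,
        proof_results=[r for r in results if r.status == "ACCEPTED"],
    )


def _label(graph: KnowledgeGraph, cid: str) -> str:
    rec = graph.entities.get(cid)
    if rec is not None and rec.labels:
        return rec.labels[0]
    return cid


def rank_pairs(
    graph: KnowledgeGraph,
    pairs: Iterable[tuple],
    theta: int = DEFAULT_THETA,
    rulebase: Optional[RuleBase] = None,
) -> list:
    """Assess all candidate pairs and order them by evidence strength:
    potential DDIs first, then descending shared-level count, descending
    feature-match count, descending mechanism count, and finally
    lexicographic pair id (a total, deterministic order)."""
    rb = rulebase if rulebase is not None else default_rulebase(theta)
    assessments = [assess_ddi(graph, a, b, theta, rb) for a, b in pairs]
    assessments.sort(
        key=lambda x: (
            x.verdict != "POTENTIAL_DDI",
            -x.shared_level_count,
            -len(x.feature_matches),
            -len(x.mechanism_matches),
            tuple(sorted((x.drug_a, x.drug_b))),
        )
    )
    return assessments
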