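"""Explanation artifacts: per-drug feature profiles and the rendered
interaction report.

The report mirrors the case study's summary-table layout: a
pharmacological-effects block with one row per target kind (metabolizing
enzymes, transporters) and a biomedical-features block with one row per
ontology level (pharmacological/MoA, biomolecular, physiological,
genetic), ``NA`` where a row has no matches, followed by the verdict and
a proof appendix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .kgraph import KnowledgeGraph, TriplePattern, Variable
from .rules import DDIAssessment, UnknownDrugError
from .vocab import FEATURE_LEVELS


@dataclass
class FeatureProfile:
    """Every registered fact about one drug, grouped two ways: by the
    source that asserted it and by ontology core class of the value."""

    drug: str
    per_source: dict = field(default_factory=dict)
    per_class: dict = field(default_factory=dict)

    @property
    def facts(self) -> list:
        return sorted({f for facts in self.per_source.values() for f in facts})

    def as_dict(self) -> dict:
        return {
            "drug": self.drug,
            "per_source": {
                k: [list(f) for f in v] for k, v in sorted(self.per_source.items())
            },
            "per_class": {
                k: [list(f) for f in v] for k, v in sorted(self.per_class.items())
            },
        }


def feature_profile(graph: KnowledgeGraph, drug: str) -> FeatureProfile:
    """Complete, deduplicated profile of *drug*: all triples with a
    registered predicate in which the drug is subject or object.

    Each fact is a ``(predicate, value, direction)`` tuple where direction
    is ``"out"`` (drug is subject) or ``"in"`` (drug is object); both
    groupings cover the same fact multiset.
    """
    if drug not in graph.entities:
        raise UnknownDrugError(drug)
    per_source: dict = {}
    per_class: dict = {}

    def add(fact, triple):
        for tag in triple.provenance:
            bucket = per_source.setdefault(tag, set())
            bucket.add(fact)
        per_class.setdefault(_value_class(graph, fact), set()).add(fact)

    for t in graph.match_triples(TriplePattern(drug, Variable("p"), Variable("o"))):
        if t.predicate in graph.registry:
            add((t.predicate, t.object, "out"), t)
    for t in graph.match_triples(TriplePattern(Variable("s"), Variable("p"), drug)):
        if t.predicate in graph.registry and t.subject != drug:
            add((t.predicate, t.subject, "in"), t)

    return FeatureProfile(
        drug=drug,
        per_source={k: sorted(v) for k, v in per_source.items()},
        per_class={k: sorted(v) for k, v in per_class.items()},
    )


def _value_class(graph: KnowledgeGraph, fact) -> str:
    predicate, value, _ = fact
    rec = graph.entities.get(value)
    if rec is not None and rec.core_class:
        return rec.core_class
    spec = graph.registry.get(predicate)
    if spec is not None and spec.feature_level:
        return spec.feature_level
    return "unclassified"


# ---------------------------------------------------------------------------
# interaction report

#: biomedical-feature rows in the rendered report, in print order
REPORT_FEATURE_ROWS = [
    ("Pharmacological (MoA)", "pharmacological"),
    ("Biomolecular", "biomolecular"),
    ("Physiological", "physiological"),
    ("Genetic", "genetic"),
    ("Contraindication", "contraindication"),
    ("Substructures", "substructure"),
]

TARGET_KIND_ROWS = [
    ("Metabolizing enzymes", "metabolizing_enzyme"),
    ("Transporters", "transporter"),
]


class ReportFormatError(ValueError):
    pass


def report_payload(assessment: DDIAssessment) -> dict:
    """The machine-readable report: the summary-table layout plus the
    verdict and a proof appendix."""
    la = assessment.labels.get(assessment.drug_a, assessment.drug_a)
    lb = assessment.labels.get(assessment.drug_b, assessment.drug_b)
    name = lambda cid: assessment.labels.get(cid, cid)
    effects = {}
    for row_name, kind in TARGET_KIND_ROWS:
        cells = {assessment.drug_a: [], assessment.drug_b: []}
        for m in assessment.mechanism_matches:
            if m.target_kind != kind:
                continue
            cells[m.perpetrator].append(f"{name(m.target)} {m.perpetrator_role}")
            cells[m.victim].append(f"{name(m.target)} substrate")
        effects[row_name] = {
            la: sorted(set(cells[assessment.drug_a])) or ["NA"],
            lb: sorted(set(cells[assessment.drug_b])) or ["NA"],
        }
    features = {}
    for row_name, level in REPORT_FEATURE_ROWS:
        values = sorted(
            {name(m.shared_value) for m in assessment.feature_matches if m.level == level}
        )
        features[row_name] = values or ["NA"]
    return {
        "drug_a": {"id": assessment.drug_a, "label": la},
        "drug_b": {"id": assessment.drug_b, "label": lb},
        "verdict": assessment.verdict,
        "threshold": assessment.threshold,
        "shared_level_count": assessment.shared_level_count,
        "shared_levels": assessment.shared_levels,
        "pharmacological_effects": effects,
        "biomedical_features": features,
        "mechanism_matches": [m.as_dict() for m in assessment.mechanism_matches],
        "feature_matches": [m.as_dict() for m in assessment.feature_matches],
        "rationale": list(assessment.rationale),
        "proofs": [pr.to_dict() for pr in assessment.proof_results],
    }


def render_report(assessment: DDIAssessment, format: str = "json") -> bytes:
    """Render the assessment as ``json`` or ``markdown`` bytes; a pure
    function of the assessment (byte-identical across runs)."""
    payload = report_payload(assessment)
    if format == "json":
        return (json.dumps(payload, indent=1, sort_keys=True) + "\n").encode()
    if format == "markdown":
        return _render_markdown(payload).encode()
    raise ReportFormatError(f"unknown report format {format!r}")


def _render_markdown(p: dict) -> str:
    la, lb = p["drug_a"]["label"], p["drug_b"]["label"]
    lines = [
        f"# Potential mechanism of interaction: {la} + {lb}",
        "",
        f"**Verdict: {p['verdict']}** "
        f"(shared similarity levels: {p['shared_level_count']}, "
        f"threshold: {p['threshold']})",
        "",
        f"| | {la} | {lb} |",
        "| --- | --- | --- |",
        "| *Pharmacological effects* | | |",
    ]
    for row, cells in p["pharmacological_effects"].items():
        lines.append(f"| {row} | {'; '.join(cells[la])} | {'; '.join(cells[lb])} |")
    lines.append("| *Biomedical features* | | |")
    for row, values in p["biomedical_features"].items():
        cell = "; ".join(values)
        lines.append(f"| {row} | {cell} | {cell} |")
    lines.append("")
    if p["rationale"]:
        lines.append("## Rationale")
        lines.extend(f"- {r}" for r in p["rationale"])
        lines.append("")
    if p["proofs"]:
        lines.append("## Proofs")
        lines.append("```json")
        lines.append(json.dumps(p["proofs"], indent=1, sort_keys=True))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# minimal structural validation against the shipped report schema


def load_report_schema() -> dict:
    from importlib import resources

    return json.loads(
        resources.files("mechkg.data").joinpath("report_schema.json").read_text()
    )


def validate_report(payload: dict, schema: Optional[dict] = None, path: str = "$") -> list:
    """Check *payload* against the shipped report schema.

    Supports the subset of JSON Schema the report schema uses (type,
    required, properties, items, enum); returns a list of problem strings,
    empty when valid.
    """
    schema = schema if schema is not None else load_report_schema()
    problems: list = []
    _validate(payload, schema, path, problems)
    return problems


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _validate(value, schema, path, problems) -> None:
    t = schema.get("type")
    if t is not None:
        expected = _TYPES[t]
        if not isinstance(value, expected) or (t == "integer" and isinstance(value, bool)):
            problems.append(f"{path}: expected {t}, got {type(value).__name__}")
            return
    if "enum" in schema and value not in schema["enum"]:
        problems.append(f"{path}: {value!r} not in {schema['enum']}")
    if t == "object":
        for key in schema.get("required", []):
            if key not in value:
                problems.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate(value[key], sub, f"{path}.{key}", problems)
    elif t == "array" and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}[{i}]", problems)
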