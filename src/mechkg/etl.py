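"""Extract and transform: RRF-dialect and link-CSV readers plus graph assembly.

The source dialects (deliberately much smaller than the real 18-column
UMLS RRF layout) are:

* MRCONSO — ``CUI|SAB|CODE|STR`` concept/atom records
* MRREL   — ``CUI1|REL|RELA|CUI2|SAB`` relationship records
* MRSAT   — ``CUI|ATN|ATV`` attribute records (``ATN=SEMTYPE`` carries
  semantic-type codes; a small map routes other attribute names to
  literal-valued predicates)
* links   — a headed CSV ``external_id,external_source,cui,relation,target``
  emulating DrugBank/PharmGKB records joined to concepts by shared
  identifiers

Malformed lines are skipped, counted and reported, never silently lost.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .kgraph import ConceptIdError, KnowledgeGraph, is_concept_id, validate_concept_id

RRF_KINDS = {"MRCONSO": 4, "MRREL": 5, "MRSAT": 3}

#: Normalization of coarse REL codes when no specific RELA is given.
REL_MAP = {
    "RO": "related_to",
    "PAR": "parent_of",
    "CHD": "child_of",
    "RB": "broader",
    "RN": "narrower",
}

#: MRSAT attribute names routed to literal-valued predicates.  SEMTYPE is
#: special-cased: it annotates the entity rather than creating a triple.
ATTRIBUTE_PREDICATES = {
    "ROLE": "has_role",
    "SUBSTRUCTURE": "has_substructure_class",
}

EXTERNAL_SOURCES = {"DRUGBANK_LIKE": ("DB", "DRUGLINK"), "PHARMGKB_LIKE": ("PGKB", "GENELINK")}

LINKS_HEADER = ["external_id", "external_source", "cui", "relation", "target"]


@dataclass(frozen=True)
class ConceptRecord:
    cui: str
    source_vocab: str
    code: str
    label: str


@dataclass(frozen=True)
class RelationRecord:
    cui1: str
    rel: str
    rela: Optional[str]
    cui2: str
    source_vocab: str


@dataclass(frozen=True)
class AttributeRecord:
    cui: str
    attribute_name: str
    attribute_value: str


@dataclass(frozen=True)
class ExternalLinkRecord:
    external_id: str
    external_source: str
    cui: Optional[str]
    relation: str
    target: str


@dataclass
class SourceCounts:
    parsed: int = 0
    skipped: int = 0
    triples: int = 0
    annotations: int = 0
    ignored: int = 0

    def as_dict(self) -> dict:
        return {
            "parsed": self.parsed,
            "skipped": self.skipped,
            "triples": self.triples,
            "annotations": self.annotations,
            "ignored": self.ignored,
        }


@dataclass
class LoadReport:
    """Per-source accounting of the ETL run plus unresolved external links."""

    per_source: dict = field(default_factory=dict)
    unresolved_links: list = field(default_factory=list)

    def source(self, name: str) -> SourceCounts:
        return self.per_source.setdefault(name, SourceCounts())

    def as_dict(self) -> dict:
        return {
            "per_source": {k: v.as_dict() for k, v in sorted(self.per_source.items())},
            "unresolved_links": list(self.unresolved_links),
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=1, sort_keys=True)


class SourceFileError(ValueError):
    """A source file is missing or matches no known dialect."""


# ---------------------------------------------------------------------------
# readers


def read_rrf(path, kind: str, report: Optional[LoadReport] = None) -> list:
    """Parse a pipe-delimited RRF-dialect file of the given *kind*.

    Returns one record per well-formed line; malformed lines are counted
    as skipped in *report*.  A non-empty file in which no line matches the
    dialect is a hard error (wrong file for the kind).
    """
    if kind not in RRF_KINDS:
        raise SourceFileError(f"unknown RRF kind {kind!r}")
    p = Path(path)
    if not p.is_file():
        raise SourceFileError(f"missing source file: {p}")
    report = report if report is not None else LoadReport()
    counts = report.source(kind)
    records = []
    lines = [ln for ln in p.read_text().splitlines() if ln.strip()]
    for line in lines:
        rec = _parse_rrf_line(line, kind)
        if rec is None:
            counts.skipped += 1
        else:
            counts.parsed += 1
            records.append(rec)
    if lines and not records:
        raise SourceFileError(
            f"{p} matches no well-formed {kind} line; wrong file or dialect"
        )
    return records


def _parse_rrf_line(line: str, kind: str):
    fields = line.split("|")
    if len(fields) != RRF_KINDS[kind]:
        return None
    if kind == "MRCONSO":
        cui, sab, code, label = fields
        if not is_concept_id(cui) or not label:
            return None
        return ConceptRecord(cui, sab, code, label)
    if kind == "MRREL":
        cui1, rel, rela, cui2, sab = fields
        if not (is_concept_id(cui1) and is_concept_id(cui2)):
            return None
        return RelationRecord(cui1, rel, rela or None, cui2, sab)
    cui, atn, atv = fields
    if not is_concept_id(cui) or not atn:
        return None
    return AttributeRecord(cui, atn, atv)


def read_links(path, report: Optional[LoadReport] = None) -> list:
    """Parse the external-links CSV (header required)."""
    p = Path(path)
    if not p.is_file():
        raise SourceFileError(f"missing source file: {p}")
    report = report if report is not None else LoadReport()
    counts = report.source("LINKS")
    records = []
    with p.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SourceFileError(f"{p}: empty links file (header required)")
        if [h.strip() for h in header] != LINKS_HEADER:
            raise SourceFileError(
                f"{p}: bad links header {header!r}; expected {LINKS_HEADER}"
            )
        for row in reader:
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(LINKS_HEADER):
                counts.skipped += 1
                continue
            external_id, source, cui, relation, target = (c.strip() for c in row)
            if not external_id or source not in EXTERNAL_SOURCES or not relation or not target:
                counts.skipped += 1
                continue
            if cui and not is_concept_id(cui):
                counts.skipped += 1
                continue
            counts.parsed += 1
            records.append(ExternalLinkRecord(external_id, source, cui or None, relation, target))
    return records


# ---------------------------------------------------------------------------
# graph assembly


def build_graph(
    concepts: Iterable[ConceptRecord] = (),
    relations: Iterable[RelationRecord] = (),
    attributes: Iterable[AttributeRecord] = (),
    external_links: Iterable[ExternalLinkRecord] = (),
    registry: Optional[dict] = None,
    report: Optional[LoadReport] = None,
) -> tuple:
    """Assemble a :class:`KnowledgeGraph` from parsed records.

    Deterministic: identical inputs give identical graphs.  Returns
    ``(graph, report)``.
    """
    graph = KnowledgeGraph(registry=registry)
    report = report if report is not None else LoadReport()

    c_counts = report.source("MRCONSO")
    for rec in concepts:
        graph.ensure_entity(rec.cui, rec.label)
        c_counts.annotations += 1

    r_counts = report.source("MRREL")
    for rec in relations:
        predicate = normalize_relation(rec.rel, rec.rela)
        graph.add_triple(rec.cui1, predicate, rec.cui2, "MRREL")
        r_counts.triples += 1

    a_counts = report.source("MRSAT")
    for rec in attributes:
        atn = rec.attribute_name.upper()
        if atn == "SEMTYPE":
            graph.ensure_entity(rec.cui).semantic_types.add(rec.attribute_value.upper())
            a_counts.annotations += 1
        elif atn in ATTRIBUTE_PREDICATES:
            graph.add_triple(
                rec.cui, ATTRIBUTE_PREDICATES[atn], rec.attribute_value, "MRSAT"
            )
            a_counts.triples += 1
        else:
            a_counts.ignored += 1

    # shared-identifier resolution: links that carry both an external id
    # and a CUI register an alias so later rows by external id alone
    # resolve to the same concept.
    aliases: dict = {}
    for rec in external_links:
        if rec.cui:
            aliases.setdefault((rec.external_source, rec.external_id), rec.cui)

    l_counts = report.source("LINKS")
    for rec in external_links:
        prefix, provenance = EXTERNAL_SOURCES[rec.external_source]
        subject = rec.cui or aliases.get((rec.external_source, rec.external_id))
        if subject is None:
            subject = f"{prefix}:{rec.external_id}"
            report.unresolved_links.append(
                {
                    "external_id": rec.external_id,
                    "external_source": rec.external_source,
                    "stored_as": subject,
                    "relation": rec.relation,
                }
            )
        spec = graph.registry.get(rec.relation)
        is_lit = graph.object_is_literal(rec.relation, rec.target)
        if not is_lit and not is_concept_id(rec.target):
            # concept-valued relation with a malformed target: report, keep
            report.unresolved_links.append(
                {
                    "external_id": rec.external_id,
                    "external_source": rec.external_source,
                    "stored_as": subject,
                    "relation": rec.relation,
                    "bad_target": rec.target,
                }
            )
            l_counts.ignored += 1
            continue
        graph.add_triple(subject, rec.relation, rec.target, provenance, object_is_literal=is_lit)
        l_counts.triples += 1

    return graph, report


def normalize_relation(rel: str, rela: Optional[str]) -> str:
    """Predicate for an MRREL record: lowercase RELA when present, else a
    normalized coarse REL code."""
    if rela:
        return rela.strip().lower()
    code = (rel or "").strip().upper()
    return REL_MAP.get(code, code.lower() or "related_to")


def load_sources(
    mrconso=None,
    mrrel=None,
    mrsat=None,
    links=None,
    registry: Optional[dict] = None,
) -> tuple:
    """Full extract+transform from file paths to ``(graph, report)``."""
    report = LoadReport()
    concepts = read_rrf(mrconso, "MRCONSO", report) if mrconso else []
    relations = read_rrf(mrrel, "MRREL", report) if mrrel else []
    attributes = read_rrf(mrsat, "MRSAT", report) if mrsat else []
    link_records = read_links(links, report) if links else []
    return build_graph(concepts, relations, attributes, link_records, registry, report)
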