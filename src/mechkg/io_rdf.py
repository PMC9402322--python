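"""Graph serialization.

Three formats are supported, all lossless for triples (including
provenance tags and the literal/concept distinction) and entity
annotations:

* ``json`` — a plain dump ``{"entities": [...], "triples": [...]}`` with
  stable key ordering; the native exchange format.
* ``ntriples`` / ``turtle`` — RDF exports via :mod:`rdflib`.  Concept ids
  map to IRIs under a fixed namespace, entity annotations become
  annotation triples, and per-triple provenance is carried by one
  deterministic reified statement node per fact.
"""

from __future__ import annotations

import hashlib
import json
from urllib.parse import quote, unquote

import rdflib
from rdflib import Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS

from .kgraph import EntityRecord, KnowledgeGraph

FORMATS = ("ntriples", "turtle", "json")

BASE = "http://mechkg.example.org/"
CONCEPT = Namespace(BASE + "concept/")
REL = Namespace(BASE + "rel/")
MKG = Namespace(BASE + "meta/")
STMT = Namespace(BASE + "stmt/")


class SerializationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# JSON


def graph_to_dict(graph: KnowledgeGraph) -> dict:
    entities = [
        {"id": cid, **rec.as_dict()} for cid, rec in sorted(graph.entities.items())
    ]
    triples = [
        {
            "subject": t.subject,
            "predicate": t.predicate,
            "object": t.object,
            "object_is_literal": t.object_is_literal,
            "provenance": list(t.provenance),
        }
        for t in sorted(graph.triples(), key=lambda t: t.key())
    ]
    return {"entities": entities, "triples": triples}


def graph_from_dict(data: dict, registry=None) -> KnowledgeGraph:
    g = KnowledgeGraph(registry=registry)
    for ent in data.get("entities", []):
        rec = g.ensure_entity(ent["id"])
        for label in ent.get("labels", []):
            rec.add_label(label)
        rec.semantic_types = set(ent.get("semantic_types", []))
        rec.core_class = ent.get("core_class")
        rec.subclass = ent.get("subclass")
        rec.subclass_candidates = set(ent.get("subclass_candidates", []))
    for t in data.get("triples", []):
        for tag in t.get("provenance") or ["FIXTURE"]:
            g.add_triple(
                t["subject"],
                t["predicate"],
                t["object"],
                tag,
                object_is_literal=t.get("object_is_literal"),
            )
    return g


# ---------------------------------------------------------------------------
# RDF


def _concept_uri(cid: str) -> URIRef:
    return CONCEPT[quote(cid, safe="")]


def _uri_concept(uri: URIRef) -> str:
    return unquote(str(uri)[len(str(CONCEPT)):])


def _stmt_uri(s: str, p: str, o: str, lit: bool) -> URIRef:
    digest = hashlib.sha1(
        "\x1f".join((s, p, o, "L" if lit else "C")).encode()
    ).hexdigest()
    return STMT[digest]


def _to_rdflib(graph: KnowledgeGraph) -> rdflib.Graph:
    g = rdflib.Graph()
    g.bind("mkg", MKG)
    g.bind("rel", REL)
    g.bind("c", CONCEPT)
    for cid, rec in sorted(graph.entities.items()):
        node = _concept_uri(cid)
        g.add((node, RDF.type, MKG.Concept))
        for label in rec.labels:
            g.add((node, RDFS.label, Literal(label)))
        for st in sorted(rec.semantic_types):
            g.add((node, MKG.semanticType, Literal(st)))
        if rec.core_class:
            g.add((node, MKG.coreClass, Literal(rec.core_class)))
        if rec.subclass:
            g.add((node, MKG.subclass, Literal(rec.subclass)))
        for cand in sorted(rec.subclass_candidates):
            g.add((node, MKG.subclassCandidate, Literal(cand)))
    for t in sorted(graph.triples(), key=lambda t: t.key()):
        s = _concept_uri(t.subject)
        p = REL[t.predicate]
        o = Literal(t.object) if t.object_is_literal else _concept_uri(t.object)
        g.add((s, p, o))
        stmt = _stmt_uri(*t.key())
        g.add((stmt, RDF.type, RDF.Statement))
        g.add((stmt, RDF.subject, s))
        g.add((stmt, RDF.predicate, p))
        g.add((stmt, RDF.object, o))
        for tag in t.provenance:
            g.add((stmt, MKG.provenance, Literal(tag)))
    return g


def _from_rdflib(g: rdflib.Graph, registry=None) -> KnowledgeGraph:
    kg = KnowledgeGraph(registry=registry)
    rel_prefix = str(REL)
    # entities and annotations
    for node in g.subjects(RDF.type, MKG.Concept):
        cid = _uri_concept(node)
        rec = kg.ensure_entity(cid)
        for label in g.objects(node, RDFS.label):
            rec.add_label(str(label))
        rec.semantic_types = {str(v) for v in g.objects(node, MKG.semanticType)}
        for v in g.objects(node, MKG.coreClass):
            rec.core_class = str(v)
        for v in g.objects(node, MKG.subclass):
            rec.subclass = str(v)
        rec.subclass_candidates = {
            str(v) for v in g.objects(node, MKG.subclassCandidate)
        }
    # provenance per reified statement
    prov: dict = {}
    for stmt in g.subjects(RDF.type, RDF.Statement):
        s = next(g.objects(stmt, RDF.subject))
        p = next(g.objects(stmt, RDF.predicate))
        o = next(g.objects(stmt, RDF.object))
        tags = sorted(str(v) for v in g.objects(stmt, MKG.provenance))
        prov[(s, p, o)] = tags
    # data triples
    for s, p, o in g:
        ps = str(p)
        if not ps.startswith(rel_prefix):
            continue
        pred = unquote(ps[len(rel_prefix):])
        subj = _uri_concept(s)
        if isinstance(o, Literal):
            obj, lit = str(o), True
        else:
            obj, lit = _uri_concept(o), False
        tags = prov.get((s, p, o)) or ["FIXTURE"]
        for tag in tags:
            kg.add_triple(subj, pred, obj, tag, object_is_literal=lit)
    return kg


# ---------------------------------------------------------------------------
# public API


def serialize(graph: KnowledgeGraph, format: str = "json") -> bytes:
    """Serialize *graph* to bytes in ``ntriples``, ``turtle`` or ``json``."""
    if format == "json":
        return (
            json.dumps(graph_to_dict(graph), indent=1, sort_keys=True) + "\n"
        ).encode()
    if format in ("ntriples", "turtle"):
        rg = _to_rdflib(graph)
        fmt = "nt" if format == "ntriples" else "turtle"
        data = rg.serialize(format=fmt)
        if format == "ntriples":
            # rdflib's nt output order is not guaranteed; sort lines for
            # byte-identical output across runs.
            data = "\n".join(sorted(line for line in data.splitlines() if line)) + "\n"
        return data.encode() if isinstance(data, str) else data
    raise SerializationError(f"unknown format {format!r}; expected one of {FORMATS}")


def deserialize(data: bytes, format: str = "json", registry=None) -> KnowledgeGraph:
    """Inverse of :func:`serialize`."""
    if isinstance(data, bytes):
        text = data.decode()
    else:
        text = data
    if format == "json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SerializationError(f"malformed JSON graph dump: {exc}") from exc
        return graph_from_dict(payload, registry=registry)
    if format in ("ntriples", "turtle"):
        rg = rdflib.Graph()
        fmt = "nt" if format == "ntriples" else "turtle"
        try:
            rg.parse(data=text, format=fmt)
        except Exception as exc:
            raise SerializationError(f"malformed {format} input: {exc}") from exc
        return _from_rdflib(rg, registry=registry)
    raise SerializationError(f"unknown format {format!r}; expected one of {FORMATS}")


_EXT_FORMAT = {".nt": "ntriples", ".ttl": "turtle", ".json": "json"}


def format_for_path(path) -> str:
    """Pick a serialization format from a file extension (default json)."""
    from pathlib import Path

    return _EXT_FORMAT.get(Path(path).suffix.lower(), "json")


def save_graph(graph: KnowledgeGraph, path) -> None:
    from pathlib import Path

    p = Path(path)
    p.write_bytes(serialize(graph, format_for_path(p)))


def load_graph(path, registry=None) -> KnowledgeGraph:
    from pathlib import Path

    p = Path(path)
    return deserialize(p.read_bytes(), format_for_path(p), registry=registry)
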