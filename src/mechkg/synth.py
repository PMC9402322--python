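"""Fixture and synthetic-source generation.

Two generators, both writing the same RRF-dialect and link-CSV files the
ETL consumes, so the full pipeline can be exercised end-to-end without
any licensed terminology downloads:

* :func:`canonical_fixture` — the irinotecan-levofloxacin case study at
  desk scale: levofloxacin inhibits CYP3A4 (metabolizing enzyme) and
  ABCB1 (transporter), irinotecan is a substrate of both, and the pair
  shares features at three similarity levels (contraindication on allergy
  to either agent, the physiological effect "decreased DNA integrity",
  and fourteen substructure classes).  All concept ids are stable
  pseudo-CUIs (C9000001...), not real UMLS identifiers.

* :func:`simulate` — parameterized random graphs with planted DDI
  mechanisms.  The accompanying truth file records every rule-satisfying
  pair (computed by exhaustive enumeration over the generated facts, not
  by the inference engine), so chance-formed DDIs never read as false
  positives.

* :func:`plant_defect` — controlled single-defect mutations of a graph
  for exercising the consistency checker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .etl import load_sources
from .kgraph import KnowledgeGraph
from .vocab import FEATURE_LEVELS

#: the fourteen substructure classes both case-study drugs carry
SUBSTRUCTURE_CLASSES = [
    "hydroxy compounds",
    "heterocyclic compounds",
    "aromatic compounds",
    "phenols and derivatives",
    "pyridines and derivatives",
    "benzene and derivatives",
    "carboxylic acids and derivatives",
    "acetates",
    "ethers",
    "aliphatic and aryl amines",
    "phenyl esters",
    "anisoles",
    "quinolines and derivatives",
    "hydroxyquinolines",
]

# canonical fixture concept ids
IRINOTECAN = "C9000001"
LEVOFLOXACIN = "C9000002"
CYP3A4 = "C9000003"
ABCB1 = "C9000004"
ALLERGY_IRINOTECAN = "C9000005"
ALLERGY_LEVOFLOXACIN = "C9000006"
DECREASED_DNA_INTEGRITY = "C9000007"
MOA_TOPO_I = "C9000008"
MOA_GYRASE = "C9000009"
GENE_UGT1A1 = "C9000010"
GENE_GYRA = "C9000011"
PROC_DNA_DAMAGE = "C9000012"
CLASS_ANTINEOPLASTIC = "C9000013"
CLASS_QUINOLONE = "C9000014"

FIXTURE_FILES = ("mrconso.rrf", "mrrel.rrf", "mrsat.rrf", "links.csv")


def canonical_fixture(outdir) -> dict:
    """Write the case-study fixture into *outdir*; returns the manifest
    (also written as ``manifest.json``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    concepts = [
        (IRINOTECAN, "NCI", "C62040", "irinotecan"),
        (LEVOFLOXACIN, "NCI", "C1586", "levofloxacin"),
        (CYP3A4, "NCI", "C17358", "CYP3A4"),
        (ABCB1, "NCI", "C17765", "ABCB1"),
        (ALLERGY_IRINOTECAN, "NDFRT", "N0001", "allergy to irinotecan"),
        (ALLERGY_LEVOFLOXACIN, "NDFRT", "N0002", "allergy to levofloxacin"),
        (DECREASED_DNA_INTEGRITY, "NDFRT", "N0003", "decreased DNA integrity"),
        (MOA_TOPO_I, "NCI", "C2192", "topoisomerase I inhibition"),
        (MOA_GYRASE, "NCI", "C2193", "DNA gyrase inhibition"),
        (GENE_UGT1A1, "NCI", "C18320", "UGT1A1 gene"),
        (GENE_GYRA, "NCI", "C18321", "gyrA gene"),
        (PROC_DNA_DAMAGE, "GO", "GO:0006974", "cellular response to DNA damage"),
        (CLASS_ANTINEOPLASTIC, "NCI", "C274", "antineoplastic agents"),
        (CLASS_QUINOLONE, "NCI", "C791", "quinolone antibiotics"),
    ]
    relations = [
        (IRINOTECAN, "RO", "has_effect", DECREASED_DNA_INTEGRITY, "NDFRT"),
        (LEVOFLOXACIN, "RO", "has_effect", DECREASED_DNA_INTEGRITY, "NDFRT"),
        (IRINOTECAN, "RO", "contraindicated_if", ALLERGY_IRINOTECAN, "NDFRT"),
        (IRINOTECAN, "RO", "contraindicated_if", ALLERGY_LEVOFLOXACIN, "NDFRT"),
        (LEVOFLOXACIN, "RO", "contraindicated_if", ALLERGY_IRINOTECAN, "NDFRT"),
        (LEVOFLOXACIN, "RO", "contraindicated_if", ALLERGY_LEVOFLOXACIN, "NDFRT"),
        (IRINOTECAN, "RO", "has_mechanism_of_action", MOA_TOPO_I, "NCI"),
        (LEVOFLOXACIN, "RO", "has_mechanism_of_action", MOA_GYRASE, "NCI"),
        (IRINOTECAN, "RO", "participates_in", PROC_DNA_DAMAGE, "GO"),
        (IRINOTECAN, "CHD", "", CLASS_ANTINEOPLASTIC, "NCI"),
        (LEVOFLOXACIN, "CHD", "", CLASS_QUINOLONE, "NCI"),
    ]
    attributes = [
        (IRINOTECAN, "SEMTYPE", "T121"),
        (IRINOTECAN, "SEMTYPE", "T109"),
        (LEVOFLOXACIN, "SEMTYPE", "T121"),
        (LEVOFLOXACIN, "SEMTYPE", "T109"),
        (CYP3A4, "SEMTYPE", "T126"),
        (ABCB1, "SEMTYPE", "T126"),
        (ALLERGY_IRINOTECAN, "SEMTYPE", "T046"),
        (ALLERGY_LEVOFLOXACIN, "SEMTYPE", "T046"),
        (DECREASED_DNA_INTEGRITY, "SEMTYPE", "T046"),
        (MOA_TOPO_I, "SEMTYPE", "T044"),
        (MOA_GYRASE, "SEMTYPE", "T044"),
        (GENE_UGT1A1, "SEMTYPE", "T028"),
        (GENE_GYRA, "SEMTYPE", "T028"),
        (PROC_DNA_DAMAGE, "SEMTYPE", "T043"),
        (CLASS_ANTINEOPLASTIC, "SEMTYPE", "T121"),
        (CLASS_QUINOLONE, "SEMTYPE", "T121"),
        (CYP3A4, "ROLE", "metabolizing_enzyme"),
        (ABCB1, "ROLE", "transporter"),
    ]
    links = [
        ("DB00762", "DRUGBANK_LIKE", IRINOTECAN, "substrate_of", CYP3A4),
        ("DB00762", "DRUGBANK_LIKE", IRINOTECAN, "substrate_of", ABCB1),
        ("DB01137", "DRUGBANK_LIKE", LEVOFLOXACIN, "inhibits", CYP3A4),
        ("DB01137", "DRUGBANK_LIKE", LEVOFLOXACIN, "inhibits", ABCB1),
        ("PA450085", "PHARMGKB_LIKE", IRINOTECAN, "gene_association", GENE_UGT1A1),
        ("PA450214", "PHARMGKB_LIKE", LEVOFLOXACIN, "gene_association", GENE_GYRA),
    ]
    # substructure records resolve through the shared-identifier aliases
    # registered by the rows above (no explicit CUI on the row)
    for ext_id in ("DB00762", "DB01137"):
        for cls in SUBSTRUCTURE_CLASSES:
            links.append((ext_id, "DRUGBANK_LIKE", "", "has_substructure_class", cls))

    _write_sources(out, concepts, relations, attributes, links)
    manifest = {
        "files": {
            "mrconso.rrf": len(concepts),
            "mrrel.rrf": len(relations),
            "mrsat.rrf": len(attributes),
            "links.csv": len(links),
        },
        "expected": {
            "entities": len(concepts),
            "triples": (
                len(relations)
                + sum(1 for a in attributes if a[1] != "SEMTYPE")
                + len(links)
            ),
            "drugs": [IRINOTECAN, LEVOFLOXACIN],
            "substructure_classes": len(SUBSTRUCTURE_CLASSES),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def load_fixture_graph(outdir) -> tuple:
    """ETL over an emitted fixture/simulation directory -> (graph, report)."""
    out = Path(outdir)
    return load_sources(
        mrconso=out / "mrconso.rrf",
        mrrel=out / "mrrel.rrf",
        mrsat=out / "mrsat.rrf",
        links=out / "links.csv",
    )


def _write_sources(out: Path, concepts, relations, attributes, links) -> None:
    (out / "mrconso.rrf").write_text(
        "".join("|".join(c) + "\n" for c in concepts)
    )
    (out / "mrrel.rrf").write_text(
        "".join("|".join(r) + "\n" for r in relations)
    )
    (out / "mrsat.rrf").write_text(
        "".join("|".join(a) + "\n" for a in attributes)
    )
    lines = ["external_id,external_source,cui,relation,target"]
    for row in links:
        lines.append(",".join(_csv_cell(c) for c in row))
    (out / "links.csv").write_text("\n".join(lines) + "\n")


def _csv_cell(value: str) -> str:
    if any(ch in value for ch in ',"\n'):
        return '"' + value.replace('"', '""') + '"'
    return value


# ---------------------------------------------------------------------------
# parameterized simulation


class SimParams(BaseModel):
    """Simulation conditions for random graphs with planted DDIs."""

    n_drugs: int = Field(8, ge=2)
    n_enzymes: int = Field(3, ge=0)
    n_transporters: int = Field(2, ge=0)
    #: feature values available per similarity level
    n_feature_values: int = Field(4, ge=0)
    p_inhibits: float = Field(0.08, ge=0.0, le=1.0)
    p_induces: float = Field(0.04, ge=0.0, le=1.0)
    p_substrate: float = Field(0.15, ge=0.0, le=1.0)
    p_feature: float = Field(0.15, ge=0.0, le=1.0)
    n_planted_ddi: int = Field(2, ge=0)
    theta: int = Field(1, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self):
        n_pairs = self.n_drugs * (self.n_drugs - 1) // 2
        if self.n_planted_ddi > n_pairs:
            raise ValueError(
                f"cannot plant {self.n_planted_ddi} DDIs among {n_pairs} pairs"
            )
        if self.n_planted_ddi > 0 and self.n_enzymes + self.n_transporters == 0:
            raise ValueError("planting a DDI mechanism requires at least one target")
        if self.n_planted_ddi > 0 and self.theta > 0 and self.n_feature_values == 0:
            raise ValueError("planting shared features requires feature values")
        return self


@dataclass
class PlantedTruth:
    """Generation-time ground truth: the planted pairs and, separately,
    every pair that satisfies the rules (planted or chance-formed)."""

    planted: list
    rule_satisfying: list  # [{drug_a, drug_b, mechanisms, shared_levels}]
    theta: int

    def positive_pairs(self) -> set:
        return {tuple(sorted((e["drug_a"], e["drug_b"]))) for e in self.rule_satisfying}

    def as_dict(self) -> dict:
        return {
            "theta": self.theta,
            "planted": self.planted,
            "rule_satisfying": self.rule_satisfying,
        }


def simulate(params: SimParams, outdir) -> PlantedTruth:
    """Emit synthetic source files under *outdir* plus ``truth.json``.

    Byte-identical for a fixed seed.  Background mechanism and feature
    facts are drawn independently at the configured rates; planted pairs
    are guaranteed a mechanism and ``theta`` shared similarity levels.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    drugs = [f"C8{i:06d}" for i in range(1, params.n_drugs + 1)]
    enzymes = [f"C8{i:06d}" for i in range(101, 101 + params.n_enzymes)]
    transporters = [f"C8{i:06d}" for i in range(201, 201 + params.n_transporters)]
    targets = enzymes + transporters
    # feature value concepts per level; substructure values are literals
    level_values: dict = {}
    next_id = 301
    for level in FEATURE_LEVELS:
        if level == "substructure":
            level_values[level] = [
                f"substructure class {i}" for i in range(1, params.n_feature_values + 1)
            ]
        else:
            level_values[level] = [
                f"C8{j:06d}" for j in range(next_id, next_id + params.n_feature_values)
            ]
            next_id += params.n_feature_values

    inhibits: set = set()
    induces: set = set()
    substrate: set = set()
    features: set = set()  # (drug, level, value)

    for d in drugs:
        for t in targets:
            if rng.random() < params.p_inhibits:
                inhibits.add((d, t))
            if rng.random() < params.p_induces:
                induces.add((d, t))
            if rng.random() < params.p_substrate:
                substrate.add((d, t))
        for level in FEATURE_LEVELS:
            for v in level_values[level]:
                if rng.random() < params.p_feature:
                    features.add((d, level, v))

    all_pairs = list(combinations(drugs, 2))
    planted_idx = rng.choice(len(all_pairs), size=params.n_planted_ddi, replace=False)
    planted = []
    for idx in sorted(int(i) for i in planted_idx):
        a, b = all_pairs[idx]
        perp, victim = (a, b) if rng.random() < 0.5 else (b, a)
        target = targets[int(rng.integers(len(targets)))]
        mode = "inhibition" if rng.random() < 0.75 else "induction"
        (inhibits if mode == "inhibition" else induces).add((perp, target))
        substrate.add((victim, target))
        shared_levels = [
            FEATURE_LEVELS[int(i)]
            for i in rng.choice(len(FEATURE_LEVELS), size=max(params.theta, 1), replace=False)
        ]
        for level in shared_levels:
            v = level_values[level][int(rng.integers(len(level_values[level])))]
            features.add((a, level, v))
            features.add((b, level, v))
        planted.append(
            {
                "drug_a": min(a, b),
                "drug_b": max(a, b),
                "perpetrator": perp,
                "victim": victim,
                "target": target,
                "mode": mode,
                "shared_levels": sorted(set(shared_levels)),
            }
        )

    truth = PlantedTruth(
        planted=planted,
        rule_satisfying=_enumerate_truth(
            drugs, enzymes, transporters, inhibits, induces, substrate, features, params.theta
        ),
        theta=params.theta,
    )
    _emit_simulation(
        out, drugs, enzymes, transporters, level_values, inhibits, induces, substrate, features
    )
    (out / "truth.json").write_text(json.dumps(truth.as_dict(), indent=1, sort_keys=True) + "\n")
    return truth


def _enumerate_truth(
    drugs, enzymes, transporters, inhibits, induces, substrate, features, theta
) -> list:
    """Exhaustive enumeration of rule-satisfying pairs, independent of the
    inference engine."""
    roles = {e: "metabolizing_enzyme" for e in enzymes}
    roles.update({t: "transporter" for t in transporters})
    by_drug_level: dict = {}
    for d, level, v in features:
        by_drug_level.setdefault(d, {}).setdefault(level, set()).add(v)
    out = []
    for a, b in combinations(sorted(drugs), 2):
        mechanisms = []
        for perp, victim in ((a, b), (b, a)):
            for rel, mode in ((inhibits, "inhibition"), (induces, "induction")):
                for target, kind in roles.items():
                    if (perp, target) in rel and (victim, target) in substrate:
                        mechanisms.append(
                            {
                                "perpetrator": perp,
                                "victim": victim,
                                "target": target,
                                "target_kind": kind,
                                "mode": mode,
                            }
                        )
        fa = by_drug_level.get(a, {})
        fb = by_drug_level.get(b, {})
        shared_levels = sorted(
            level for level in fa if fa[level] & fb.get(level, set())
        )
        if mechanisms and len(shared_levels) >= theta:
            out.append(
                {
                    "drug_a": a,
                    "drug_b": b,
                    "mechanisms": mechanisms,
                    "shared_levels": shared_levels,
                }
            )
    return out


_LEVEL_EMISSION = {
    # how feature facts reach the source files, mirroring the ETL dialects
    "physiological": ("MRREL", "has_effect"),
    "contraindication": ("MRREL", "contraindicated_if"),
    "pharmacological": ("MRREL", "has_mechanism_of_action"),
    "biomolecular": ("MRREL", "participates_in"),
    "genetic": ("LINKS_PGKB", "gene_association"),
    "substructure": ("LINKS_DB", "has_substructure_class"),
}

_LEVEL_SEMTYPE = {
    "physiological": "T046",
    "contraindication": "T046",
    "pharmacological": "T044",
    "biomolecular": "T043",
    "genetic": "T028",
}


def _emit_simulation(
    out, drugs, enzymes, transporters, level_values, inhibits, induces, substrate, features
) -> None:
    concepts = []
    attributes = []
    for d in drugs:
        concepts.append((d, "SIM", d, f"drug {d}"))
        attributes.append((d, "SEMTYPE", "T121"))
    for e in enzymes:
        concepts.append((e, "SIM", e, f"enzyme {e}"))
        attributes.append((e, "SEMTYPE", "T126"))
        attributes.append((e, "ROLE", "metabolizing_enzyme"))
    for t in transporters:
        concepts.append((t, "SIM", t, f"transporter {t}"))
        attributes.append((t, "SEMTYPE", "T126"))
        attributes.append((t, "ROLE", "transporter"))
    for level in sorted(_LEVEL_SEMTYPE):
        for v in level_values.get(level, []):
            concepts.append((v, "SIM", v, f"{level} value {v}"))
            attributes.append((v, "SEMTYPE", _LEVEL_SEMTYPE[level]))

    relations = []
    links = []
    for d, t in sorted(inhibits):
        links.append((f"X{d}", "DRUGBANK_LIKE", d, "inhibits", t))
    for d, t in sorted(induces):
        links.append((f"X{d}", "DRUGBANK_LIKE", d, "induces", t))
    for d, t in sorted(substrate):
        links.append((f"X{d}", "DRUGBANK_LIKE", d, "substrate_of", t))
    for d, level, v in sorted(features):
        channel, predicate = _LEVEL_EMISSION[level]
        if channel == "MRREL":
            relations.append((d, "RO", predicate, v, "SIM"))
        elif channel == "LINKS_PGKB":
            links.append((f"P{d}", "PHARMGKB_LIKE", d, predicate, v))
        else:
            links.append((f"X{d}", "DRUGBANK_LIKE", d, predicate, v))

    _write_sources(out, concepts, relations, attributes, links)


# ---------------------------------------------------------------------------
# random graphs for engine fuzzing


def random_graph(rng: np.random.Generator, max_triples: int = 60) -> KnowledgeGraph:
    """A small random graph over the DDI vocabulary, for property tests of
    the inference engine.  Drugs, targets (some lacking a role annotation),
    and feature facts across all similarity levels are drawn uniformly."""
    g = KnowledgeGraph()
    drugs = [f"C7{i:06d}" for i in range(1, int(rng.integers(2, 6)) + 1)]
    targets = [f"C7{i:06d}" for i in range(101, 101 + int(rng.integers(1, 4)))]
    values = [f"C7{i:06d}" for i in range(201, 201 + int(rng.integers(1, 4)))]
    for d in drugs:
        g.ensure_entity(d, f"drug {d}")
    for t in targets:
        g.ensure_entity(t, f"target {t}")
        r = rng.random()
        if r < 0.4:
            g.add_triple(t, "has_role", "metabolizing_enzyme", "FIXTURE")
        elif r < 0.8:
            g.add_triple(t, "has_role", "transporter", "FIXTURE")
        # else: no role annotation; R1-R4 must not fire on this target
    feature_preds = ["has_effect", "contraindicated_if", "gene_association",
                     "participates_in", "has_mechanism_of_action", "has_substructure_class"]
    n = int(rng.integers(0, max_triples - len(g) + 1))
    for _ in range(n):
        if len(g) >= max_triples:
            break
        kind = rng.random()
        d = drugs[int(rng.integers(len(drugs)))]
        if kind < 0.45:
            p = ("inhibits", "induces", "substrate_of")[int(rng.integers(3))]
            t = targets[int(rng.integers(len(targets)))]
            g.add_triple(d, p, t, "FIXTURE")
        else:
            p = feature_preds[int(rng.integers(len(feature_preds)))]
            if p == "has_substructure_class":
                g.add_triple(d, p, f"class {int(rng.integers(3))}", "FIXTURE")
            else:
                v = values[int(rng.integers(len(values)))]
                g.add_triple(d, p, v, "FIXTURE")
    return g


# ---------------------------------------------------------------------------
# defect planting

DEFECT_KINDS = (
    "MULTI_CLASS_CONFLICT",
    "DOMAIN_VIOLATION",
    "RANGE_VIOLATION",
    "UNKNOWN_PREDICATE",
)


def plant_defect(graph: KnowledgeGraph, kind: str, rng: Optional[np.random.Generator] = None) -> dict:
    """Mutate *graph* in place with exactly one defect of *kind*; returns
    a description of what was planted.  The graph must already contain at
    least one drug and one enzyme entity for the relational kinds."""
    rng = rng if rng is not None else np.random.default_rng(0)

    def pick(subclass):
        ids = sorted(
            cid
            for cid, rec in graph.entities.items()
            if subclass in _candidates(rec)
        )
        if not ids:
            raise ValueError(f"no {subclass} entity available to plant {kind}")
        return ids[int(rng.integers(len(ids)))]

    if kind == "MULTI_CLASS_CONFLICT":
        cid = "C9999999"
        rec = graph.ensure_entity(cid, "conflicted instance")
        rec.semantic_types |= {"T121", "T086"}  # drugs vs snps: two cores
        return {"kind": kind, "entity": cid}
    if kind == "DOMAIN_VIOLATION":
        subject = pick("enzymes")  # inhibits demands a drugs subject
        obj = pick("enzymes")
        graph.add_triple(subject, "inhibits", obj, "FIXTURE")
        return {"kind": kind, "triple": [subject, "inhibits", obj]}
    if kind == "RANGE_VIOLATION":
        subject = pick("drugs")
        obj = pick("drugs")  # inhibits demands an enzymes object
        graph.add_triple(subject, "inhibits", obj, "FIXTURE")
        return {"kind": kind, "triple": [subject, "inhibits", obj]}
    if kind == "UNKNOWN_PREDICATE":
        subject = pick("drugs")
        obj = pick("drugs")
        graph.add_triple(subject, "frobnicates", obj, "FIXTURE", object_is_literal=False)
        return {"kind": kind, "triple": [subject, "frobnicates", obj]}
    raise ValueError(f"unknown defect kind {kind!r}")


def _candidates(rec) -> set:
    if rec.subclass_candidates:
        return set(rec.subclass_candidates)
    from .schema import DEFAULT_SEMTYPE_MAP

    return {DEFAULT_SEMTYPE_MAP[t] for t in rec.semantic_types if t in DEFAULT_SEMTYPE_MAP}
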