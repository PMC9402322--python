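"""The six-rule two-layer DDI framework on the case study and on
synthetic graphs."""

import numpy as np
import pytest

from mechkg.engine import AtLeast, forward_closure
from mechkg.kgraph import KnowledgeGraph
from mechkg.rules import (
    UnknownDrugError,
    assess_ddi,
    default_rulebase,
    pharmacological_effect_layer,
    rank_pairs,
    shared_feature_layer,
)
from mechkg.synth import (
    ABCB1,
    CYP3A4,
    IRINOTECAN,
    LEVOFLOXACIN,
    SUBSTRUCTURE_CLASSES,
    random_graph,
)


def test_default_rulebase_has_exactly_six_rules(rulebase):
    assert len(rulebase) == 6


def test_rule_layers_four_one_one(rulebase):
    layers = sorted(r.layer for r in rulebase.rules)
    assert layers == [0, 1, 1, 1, 1, 2]  # 4 mechanism rules, 1 shared-feature, 1 combination


def test_every_rule_is_range_restricted(rulebase):
    for rule in rulebase.rules:
        rule.validate()  # raises on violation


def test_threshold_is_wired_into_the_combination_rule():
    rb = default_rulebase(theta=3)
    (r6,) = rb.rules_for("potential_ddi")
    (agg,) = [b for b in r6.body if isinstance(b, AtLeast)]
    assert agg.n == 3


def test_case_study_mechanism_matches(fixture_graph, rulebase):
    matches = pharmacological_effect_layer(fixture_graph, IRINOTECAN, LEVOFLOXACIN, rulebase)
    assert len(matches) == 2
    by_target = {m.target: m for m in matches}
    assert set(by_target) == {CYP3A4, ABCB1}
    assert by_target[CYP3A4].target_kind == "metabolizing_enzyme"
    assert by_target[ABCB1].target_kind == "transporter"
    for m in matches:
        assert m.perpetrator == LEVOFLOXACIN and m.perpetrator_role == "inhibitor"
        assert m.victim == IRINOTECAN
        assert m.proof is not None


def test_mechanism_layer_matches_brute_force_enumeration(rulebase):
    rng = np.random.default_rng(17)
    for _ in range(20):
        g = random_graph(rng)
        drugs = [c for c in sorted(g.entities) if c < "C7000100"]
        if len(drugs) < 2:
            continue
        a, b = drugs[0], drugs[1]
        got = {
            (m.perpetrator, m.victim, m.target, m.perpetrator_role)
            for m in pharmacological_effect_layer(g, a, b, rulebase)
        }
        expected = set()
        roles = {}
        for t in g.triples():
            if t.predicate == "has_role":
                roles[t.subject] = t.object
        for perp, victim in ((a, b), (b, a)):
            for t in g.triples():
                if t.subject != perp or t.predicate not in ("inhibits", "induces"):
                    continue
                if t.object in roles and g.has(victim, "substrate_of", t.object):
                    role = "inhibitor" if t.predicate == "inhibits" else "inducer"
                    expected.add((perp, victim, t.object, role))
        assert got == expected


def test_drugs_with_no_shared_targets_have_no_mechanism(rulebase):
    g = KnowledgeGraph()
    g.add_triple("C0000001", "inhibits", "C0000010")
    g.add_triple("C0000010", "has_role", "metabolizing_enzyme")
    g.add_triple("C0000002", "substrate_of", "C0000011")
    g.add_triple("C0000011", "has_role", "transporter")
    assert pharmacological_effect_layer(g, "C0000001", "C0000002", rulebase) == []


def test_case_study_shared_levels_and_substructures(fixture_graph, rulebase):
    matches, n_levels = shared_feature_layer(fixture_graph, IRINOTECAN, LEVOFLOXACIN, rulebase)
    assert n_levels == 3
    assert {m.level for m in matches} == {"contraindication", "physiological", "substructure"}
    substructures = {m.shared_value for m in matches if m.level == "substructure"}
    assert substructures == set(SUBSTRUCTURE_CLASSES)
    assert len(substructures) == 14
    # every match cites one leaf triple per drug
    for m in matches:
        subjects = {e[0] for e in m.evidence}
        assert subjects == {IRINOTECAN, LEVOFLOXACIN}


def test_self_pair_shares_nothing(fixture_graph, rulebase):
    matches, n = shared_feature_layer(fixture_graph, IRINOTECAN, IRINOTECAN, rulebase)
    assert matches == [] and n == 0


def test_unknown_drug_raises_naming_the_id(fixture_graph, rulebase):
    with pytest.raises(UnknownDrugError, match="C1234567"):
        pharmacological_effect_layer(fixture_graph, "C1234567", LEVOFLOXACIN, rulebase)
    with pytest.raises(UnknownDrugError):
        assess_ddi(fixture_graph, IRINOTECAN, "C1234567")


def test_case_study_assessment(fixture_graph):
    a = assess_ddi(fixture_graph, IRINOTECAN, LEVOFLOXACIN, theta=1)
    assert a.verdict == "POTENTIAL_DDI"
    assert len(a.mechanism_matches) == 2
    assert a.shared_level_count == 3
    assert a.verdict == "POTENTIAL_DDI" and a.proof_results


def test_assessment_is_symmetric_up_to_role_labeling(fixture_graph):
    ab = assess_ddi(fixture_graph, IRINOTECAN, LEVOFLOXACIN)
    ba = assess_ddi(fixture_graph, LEVOFLOXACIN, IRINOTECAN)
    assert ab.verdict == ba.verdict
    assert {m.identity() for m in ab.mechanism_matches} == {m.identity() for m in ba.mechanism_matches}
    assert {m.identity() for m in ab.feature_matches} == {m.identity() for m in ba.feature_matches}


def test_removing_layer1_facts_gives_no_evidence(fixture_graph):
    g = KnowledgeGraph()
    for t in fixture_graph.triples():
        if t.predicate not in ("inhibits", "induces", "substrate_of"):
            g.add(t)
    for cid in fixture_graph.entities:
        g.ensure_entity(cid)
    a = assess_ddi(g, IRINOTECAN, LEVOFLOXACIN)
    assert a.verdict == "NO_EVIDENCE"
    assert a.shared_level_count == 3  # features alone never suffice


def test_threshold_above_shared_levels_gives_no_evidence(fixture_graph):
    assert assess_ddi(fixture_graph, IRINOTECAN, LEVOFLOXACIN, theta=4).verdict == "NO_EVIDENCE"
    assert assess_ddi(fixture_graph, IRINOTECAN, LEVOFLOXACIN, theta=3).verdict == "POTENTIAL_DDI"


def test_adding_feature_facts_never_lowers_shared_level_count(fixture_graph, rulebase):
    _, before = shared_feature_layer(fixture_graph, IRINOTECAN, LEVOFLOXACIN, rulebase)
    fixture_graph.add_triple(IRINOTECAN, "gene_association", "C9000011", "FIXTURE")
    _, after = shared_feature_layer(fixture_graph, IRINOTECAN, LEVOFLOXACIN, rulebase)
    assert after >= before
    assert after == before + 1  # gyrA now shared at the genetic level


def test_verdicts_match_forward_closure_over_all_pairs(rulebase):
    rng = np.random.default_rng(23)
    for _ in range(15):
        g = random_graph(rng)
        drugs = [c for c in sorted(g.entities) if c < "C7000100"]
        cl = forward_closure(g, rulebase)
        oracle = {a[1] for a in cl.derived if a[0] == "potential_ddi"}
        for i, a in enumerate(drugs):
            for b in drugs[i + 1:]:
                verdict = assess_ddi(g, a, b, rulebase=rulebase).verdict
                expected = (a, b) in oracle or (b, a) in oracle
                assert (verdict == "POTENTIAL_DDI") == expected


def test_rank_pairs_orders_by_planted_level_counts():
    g = KnowledgeGraph()
    enzyme = "C0000100"
    g.add_triple(enzyme, "has_role", "metabolizing_enzyme")
    level_preds = ["has_effect", "gene_association", "has_mechanism_of_action"]
    pairs = []
    for i, n_levels in enumerate((3, 2, 1)):
        a, b = f"C000000{2 * i + 1}", f"C000000{2 * i + 2}"
        g.add_triple(a, "inhibits", enzyme)
        g.add_triple(b, "substrate_of", enzyme)
        for j, pred in enumerate(level_preds[:n_levels]):
            value = f"C90{i}{j:02d}11"
            g.add_triple(a, pred, value)
            g.add_triple(b, pred, value)
        pairs.append((a, b))
    ranked = rank_pairs(g, pairs, theta=1)
    assert [x.shared_level_count for x in ranked] == [3, 2, 1]
    assert all(x.verdict == "POTENTIAL_DDI" for x in ranked)


def test_rank_pairs_breaks_ties_lexicographically(fixture_graph):
    ranked = rank_pairs(
        fixture_graph,
        [(LEVOFLOXACIN, IRINOTECAN), (IRINOTECAN, LEVOFLOXACIN)],
        theta=1,
    )
    # identical counts for the same pair queried both ways: pair-id order
    assert len(ranked) == 2
    assert (ranked[0].drug_a, ranked[0].drug_b) in (
        (IRINOTECAN, LEVOFLOXACIN),
        (LEVOFLOXACIN, IRINOTECAN),
    )
    k = lambda x: (x.shared_level_count, len(x.feature_matches), len(x.mechanism_matches))
    assert k(ranked[0]) == k(ranked[1])


def test_single_candidate_pair_gives_singleton_list(fixture_graph):
    ranked = rank_pairs(fixture_graph, [(IRINOTECAN, LEVOFLOXACIN)])
    assert len(ranked) == 1
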