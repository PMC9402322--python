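"""Inference engine: rule loading, backward chaining vs the forward
closure oracle, proof structure, termination on recursive rules."""

import numpy as np
import pytest

from mechkg.engine import (
    Atom,
    Neq,
    AtLeast,
    Rule,
    RuleBase,
    RuleError,
    backward_chain,
    count_solutions,
    forward_closure,
    inference_layers,
    load_rulebase,
    parse_atom,
    parse_body_item,
    proof_canonical,
)
from mechkg.kgraph import KnowledgeGraph, Variable
from mechkg.rules import default_rulebase
from mechkg.synth import random_graph


# -- parsing and validation -------------------------------------------------


def test_parse_atom_terms():
    a = parse_atom('mech(A, C0000001, "a literal, with comma", inhibition)')
    assert a.pred == "mech"
    assert a.args[0] == Variable("A") and isinstance(a.args[0], Variable)
    assert a.args[1] == "C0000001" and not isinstance(a.args[1], Variable)
    assert a.args[2] == "a literal, with comma"
    assert a.args[3] == "inhibition"


def test_parse_builtins():
    assert parse_body_item("A != B") == Neq(Variable("A"), Variable("B"))
    item = parse_body_item("atleast(2; L; shared(A, B, L, V))")
    assert isinstance(item, AtLeast) and item.n == 2
    assert item.count_vars == (Variable("L"),)


def test_non_range_restricted_rule_rejected_at_load():
    rule = Rule("bad", parse_atom("p(X, Y)"), (parse_atom("q(X, X)"),))
    with pytest.raises(RuleError, match="range-restricted"):
        RuleBase([rule])


def test_empty_body_rejected():
    with pytest.raises(RuleError, match="empty body"):
        RuleBase([Rule("bad", parse_atom("p(a, b)"), ())])


def test_aggregate_over_aggregate_head_rejected():
    rules = [
        Rule("r1", parse_atom("p(X, Y)"), (parse_atom("e(X, Y)"), AtLeast(1, (Variable("Z"),), parse_atom("p(X, Z)")))),
    ]
    with pytest.raises(RuleError, match="aggregate"):
        RuleBase(rules)


def test_yaml_rulebase_load_with_parameter():
    rb = load_rulebase(
        [
            {"id": "r1", "layer": 1, "head": "p(X, Y)", "body": ["e(X, Y)"]},
            {"id": "r2", "layer": 2, "head": "q(X)", "body": ["p(X, Y)", "atleast($k; Y; p(X, Y))"]},
        ],
        params={"k": 2},
    )
    assert len(rb) == 2
    (r2,) = rb.rules_for("q")
    assert any(isinstance(b, AtLeast) and b.n == 2 for b in r2.body)


# -- closure properties -----------------------------------------------------


def test_closure_of_empty_graph_is_empty(rulebase):
    cl = forward_closure(KnowledgeGraph(), rulebase)
    assert cl.atoms == set() and cl.derived == set()


def test_closure_is_idempotent(rulebase):
    g = random_graph(np.random.default_rng(3))
    cl1 = forward_closure(g, rulebase)
    cl2 = forward_closure(cl1.graph, rulebase)
    assert cl2.derived >= cl1.derived
    assert {a for a in cl2.atoms if a[0] not in ("mech", "shared", "potential_ddi", "feature")} >= \
           {a for a in cl1.atoms if a[0] not in ("mech", "shared", "potential_ddi", "feature")}
    # no new derived facts appear on the second pass
    assert cl2.derived == cl1.derived


def test_closure_is_monotone(rulebase):
    rng = np.random.default_rng(11)
    for _ in range(10):
        g2 = random_graph(rng)
        triples = sorted(g2.triples(), key=lambda t: t.key())
        g1 = KnowledgeGraph()
        for cid in g2.entities:
            g1.ensure_entity(cid)
        for t in triples[: len(triples) // 2]:
            g1.add(t)
        c1 = forward_closure(g1, rulebase)
        c2 = forward_closure(g2, rulebase)
        assert c1.atoms <= c2.atoms


# -- backward chaining ------------------------------------------------------


def test_any_goal_on_empty_graph_is_rejected(rulebase):
    r = backward_chain(KnowledgeGraph(), rulebase, Atom("potential_ddi", ("C0000001", "C0000002")))
    assert r.status == "REJECTED" and r.proofs == []


def test_acceptance_iff_proofs_nonempty(fixture_graph, rulebase):
    acc = backward_chain(fixture_graph, rulebase, Atom("potential_ddi", ("C9000002", "C9000001")))
    rej = backward_chain(fixture_graph, rulebase, Atom("potential_ddi", ("C9000003", "C9000001")))
    assert acc.status == "ACCEPTED" and acc.proofs
    assert rej.status == "REJECTED" and not rej.proofs


def test_backward_agrees_with_closure_on_random_graphs(rulebase):
    rng = np.random.default_rng(20)
    for _ in range(150):
        g = random_graph(rng)
        cl = forward_closure(g, rulebase)
        entities = sorted(g.entities)
        goals = list(cl.derived)
        goals.append(("potential_ddi", (entities[0], entities[-1])))
        goals.append(("mech", (entities[0], entities[-1], entities[0], "inhibition")))
        for pred, args in goals:
            res = backward_chain(g, rulebase, Atom(pred, args))
            assert (res.status == "ACCEPTED") == ((pred, args) in cl.atoms), (pred, args)


def test_proof_leaves_are_graph_facts(fixture_graph, rulebase):
    res = backward_chain(fixture_graph, rulebase, Atom("potential_ddi", ("C9000002", "C9000001")))

    def leaves(node):
        if hasattr(node, "children"):
            for c in node.children:
                yield from leaves(c)
        else:
            yield node

    for proof in res.proofs:
        for leaf in leaves(proof):
            if leaf.source is not None:
                s, p, o = leaf.source
                assert fixture_graph.has(s, p, o)


def test_monotonicity_adding_facts_never_flips_accept_to_reject(rulebase):
    rng = np.random.default_rng(5)
    g = random_graph(rng)
    cl = forward_closure(g, rulebase)
    accepted = sorted(cl.derived)[:10]
    g.add_triple("C7000001", "has_effect", "C7000201", "FIXTURE")
    g.add_triple("C7000002", "inhibits", "C7000101", "FIXTURE")
    for pred, args in accepted:
        assert backward_chain(g, rulebase, Atom(pred, args)).status == "ACCEPTED"


def test_results_are_byte_identical_across_runs(fixture_graph, rulebase):
    import json

    goal = Atom("shared", ("C9000001", "C9000002", Variable("L"), Variable("V")))
    r1 = json.dumps(backward_chain(fixture_graph, rulebase, goal).to_dict(), sort_keys=True)
    r2 = json.dumps(backward_chain(fixture_graph, rulebase, goal).to_dict(), sort_keys=True)
    assert r1 == r2


def test_count_solutions_equals_closure_match(rulebase):
    rng = np.random.default_rng(8)
    for _ in range(20):
        g = random_graph(rng)
        cl = forward_closure(g, rulebase)
        for pred, arity in (("mech", 4), ("shared", 4), ("potential_ddi", 2)):
            pattern = Atom(pred, tuple(Variable(f"X{i}") for i in range(arity)))
            expected = sum(1 for a in cl.derived if a[0] == pred)
            assert count_solutions(g, rulebase, pattern) == expected


def test_no_solution_pattern_counts_zero(rulebase):
    assert count_solutions(KnowledgeGraph(), rulebase, Atom("mech", (Variable("A"), Variable("B"), Variable("T"), Variable("M")))) == 0


def test_recursive_rules_terminate_with_correct_answers():
    rb = load_rulebase(
        [
            {"id": "a1", "layer": 1, "head": "ancestor(X, Y)", "body": ["parent_of(X, Y)"]},
            {"id": "a2", "layer": 1, "head": "ancestor(X, Z)", "body": ["parent_of(X, Y)", "ancestor(Y, Z)"]},
        ]
    )
    g = KnowledgeGraph()
    # chain plus a cycle
    g.add_triple("C0000001", "parent_of", "C0000002")
    g.add_triple("C0000002", "parent_of", "C0000003")
    g.add_triple("C0000003", "parent_of", "C0000001")
    res = backward_chain(g, rb, Atom("ancestor", ("C0000001", Variable("Z"))))
    found = {a.atom[1][1] for a in res.answers}
    assert found == {"C0000001", "C0000002", "C0000003"}
    cl = forward_closure(g, rb)
    assert {a for a in cl.derived if a[0] == "ancestor"} == {
        ("ancestor", (x, y))
        for x in ("C0000001", "C0000002", "C0000003")
        for y in ("C0000001", "C0000002", "C0000003")
    }


def test_inference_layers_of_the_case_study_proof(fixture_graph, rulebase):
    res = backward_chain(fixture_graph, rulebase, Atom("potential_ddi", ("C9000002", "C9000001")))
    layers = set()
    for proof in res.proofs:
        layers |= inference_layers(proof)
    assert layers == {1, 2}
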