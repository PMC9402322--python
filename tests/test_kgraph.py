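"""Knowledge-graph data model: identifiers, set semantics, pattern matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechkg.kgraph import (
    ConceptIdError,
    KnowledgeGraph,
    TriplePattern,
    Variable,
    validate_concept_id,
)

C_LEVO = "C9000002"
C_CYP = "C9000003"


@pytest.mark.parametrize("token", ["C0000001", "C9999999", "DB:00762", "PGKB:PA450214"])
def test_valid_concept_ids(token):
    assert validate_concept_id(token) == token


@pytest.mark.parametrize("token", ["", "C123", "C12345678", "1234567", "C12|4567", ":x", "x:"])
def test_malformed_concept_ids_are_rejected_with_the_token_named(token):
    with pytest.raises(ConceptIdError) as err:
        validate_concept_id(token)
    assert repr(token) in str(err.value)


def test_add_triple_creates_entities_and_is_idempotent():
    g = KnowledgeGraph()
    g.add_triple(C_LEVO, "inhibits", C_CYP, "FIXTURE")
    assert len(g) == 1 and set(g.entities) == {C_LEVO, C_CYP}
    g.add_triple(C_LEVO, "inhibits", C_CYP, "FIXTURE")
    assert len(g) == 1


def test_readding_with_new_source_merges_provenance():
    g = KnowledgeGraph()
    g.add_triple(C_LEVO, "inhibits", C_CYP, "DRUGLINK")
    g.add_triple(C_LEVO, "inhibits", C_CYP, "MRREL")
    (t,) = list(g.triples())
    assert t.provenance == ("DRUGLINK", "MRREL")
    assert len(g) == 1


def test_add_triple_rejects_malformed_subject():
    g = KnowledgeGraph()
    with pytest.raises(ConceptIdError) as err:
        g.add_triple("notacui", "inhibits", C_CYP)
    assert "notacui" in str(err.value)
    assert len(g) == 0


def test_literalness_follows_the_registry():
    g = KnowledgeGraph()
    t1 = g.add_triple(C_CYP, "has_role", "transporter")
    t2 = g.add_triple(C_LEVO, "inhibits", C_CYP)
    assert t1.object_is_literal and not t2.object_is_literal
    # literal-valued predicate objects do not create entities
    assert "transporter" not in g.entities


def test_ground_pattern_is_a_membership_test():
    g = KnowledgeGraph()
    g.add_triple(C_LEVO, "inhibits", C_CYP)
    assert g.match(TriplePattern(C_LEVO, "inhibits", C_CYP)) == [{}]
    assert g.match(TriplePattern(C_CYP, "inhibits", C_LEVO)) == []


def test_match_binds_variables_on_the_fixture(fixture_graph):
    hits = fixture_graph.match(TriplePattern.parse("?x", "inhibits", C_CYP))
    assert hits == [{"x": C_LEVO}]


def test_repeated_variable_must_unify_to_one_value():
    g = KnowledgeGraph()
    g.add_triple("C0000001", "related_to", "C0000001")
    g.add_triple("C0000001", "related_to", "C0000002")
    v = Variable("x")
    assert g.match(TriplePattern(v, "related_to", v)) == [{"x": "C0000001"}]


def _brute_force_match(triples, pattern):
    out = []
    for s, p, o in triples:
        binding = {}
        ok = True
        for term, val in ((pattern.subject, s), (pattern.predicate, p), (pattern.object, o)):
            if isinstance(term, Variable):
                if str(term) in binding and binding[str(term)] != val:
                    ok = False
                    break
                binding[str(term)] = val
            elif term != val:
                ok = False
                break
        if ok and binding not in out:
            out.append(binding)
    return sorted(out, key=lambda b: tuple(sorted(b.items())))


_ids = st.sampled_from([f"C000000{i}" for i in range(1, 6)])
_preds = st.sampled_from(["related_to", "parent_of", "inhibits"])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    triples=st.lists(st.tuples(_ids, _preds, _ids), max_size=25),
    s=st.one_of(_ids, st.just(Variable("s"))),
    p=st.one_of(_preds, st.just(Variable("p"))),
    o=st.one_of(_ids, st.just(Variable("o")), st.just(Variable("s"))),
)
def test_match_equals_exhaustive_scan_oracle(triples, s, p, o):
    g = KnowledgeGraph()
    for t in triples:
        g.add_triple(*t)
    pattern = TriplePattern(s, p, o)
    stored = [(t.subject, t.predicate, t.object) for t in g.triples()]
    assert g.match(pattern) == _brute_force_match(stored, pattern)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(triples=st.lists(st.tuples(_ids, _preds, _ids), max_size=30))
def test_triple_count_never_decreases_and_readd_is_noop(triples):
    g = KnowledgeGraph()
    sizes = [len(g)]
    for t in triples:
        g.add_triple(*t)
        sizes.append(len(g))
    assert all(b >= a for a, b in zip(sizes, sizes[1:]))
    n = len(g)
    for t in triples:
        g.add_triple(*t)
    assert len(g) == n


def test_entity_records_cover_every_concept_in_triples(fixture_graph):
    ids = set()
    for t in fixture_graph.triples():
        ids.add(t.subject)
        if not t.object_is_literal:
            ids.add(t.object)
    assert ids <= set(fixture_graph.entities)
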