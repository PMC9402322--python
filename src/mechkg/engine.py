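"""Horn-rule inference over the knowledge graph.

The engine answers goals by tabled (memoized) backward chaining: starting
from the goal predicate it evaluates only the rules reachable from it,
recording answers per predicate in tables and iterating to a fixpoint, so
recursive rule sets (terminology hierarchies) terminate.  Accepted goals
come with proof trees: rule applications with their variable bindings
down to leaf facts of the graph.

A semi-naive forward closure over the same rule language is provided as
an independent correctness oracle: a ground goal is accepted by the
backward chainer exactly when it is in the least-fixpoint closure.

Rule bodies are conjunctions of:

* relational atoms ``pred(t1, ..., tn)`` — terms are variables
  (capitalized identifiers) or constants;
* the disequality builtin ``X != Y``;
* the aggregate builtin ``atleast(n; V1, ...; atom)`` — true when the
  number of distinct bindings of the count variables satisfying ``atom``
  is at least ``n``.  Aggregate subgoals must not depend on the heads of
  aggregate rules (checked at load), which keeps the semantics monotone.

Rules must be range-restricted (every head variable occurs in a
relational body atom); violations are rejected when the rule base is
loaded, not at query time.  Negation is not supported: absence of
evidence yields a REJECTED status, never a derived fact.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import yaml

from .kgraph import CUI_PATTERN, KnowledgeGraph, Variable

#: retained distinct proofs per derived fact (alternative derivations
#: beyond this are dropped; answers themselves are never dropped)
PROOF_CAP = 64
_PROOF_PASSES = 4

_VAR_RE = re.compile(r"^[A-Z][A-Za-z0-9_]*$")


class RuleError(ValueError):
    """A rule or rule base failed load-time validation."""


# ---------------------------------------------------------------------------
# terms, atoms, builtins


def make_term(token: str):
    token = token.strip()
    if token.startswith('"') and token.endswith('"') and len(token) >= 2:
        return token[1:-1]
    if CUI_PATTERN.match(token):
        return token  # concept ids are constants despite the capital C
    if _VAR_RE.match(token):
        return Variable(token)
    return token


@dataclass(frozen=True)
class Atom:
    pred: str
    args: tuple

    @property
    def arity(self) -> int:
        return len(self.args)

    def is_ground(self) -> bool:
        return not any(isinstance(a, Variable) for a in self.args)

    def variables(self) -> set:
        return {a for a in self.args if isinstance(a, Variable)}

    def substitute(self, binding: dict) -> "Atom":
        return Atom(
            self.pred,
            tuple(
                binding.get(str(a), a) if isinstance(a, Variable) else a
                for a in self.args
            ),
        )

    def render(self) -> str:
        def fmt(a):
            if isinstance(a, Variable):
                return str(a)
            return f'"{a}"' if re.search(r"[,()\s]", a) or not a else a

        return f"{self.pred}({', '.join(fmt(a) for a in self.args)})"


@dataclass(frozen=True)
class Neq:
    left: object
    right: object

    def variables(self) -> set:
        return {a for a in (self.left, self.right) if isinstance(a, Variable)}

    def render(self) -> str:
        return f"{self.left} != {self.right}"


@dataclass(frozen=True)
class AtLeast:
    n: int
    count_vars: tuple
    subgoal: Atom

    def outer_variables(self) -> set:
        """Non-count subgoal variables; those also occurring elsewhere in
        the rule body are correlated, the rest are local existentials."""
        return self.subgoal.variables() - set(self.count_vars)

    def render(self) -> str:
        vars_ = ", ".join(str(v) for v in self.count_vars)
        return f"atleast({self.n}; {vars_}; {self.subgoal.render()})"


# ---------------------------------------------------------------------------
# parsing


def _split_top(text: str, sep: str) -> list:
    """Split on *sep* outside quotes and parentheses."""
    parts, depth, quoted, cur = [], 0, False, []
    for ch in text:
        if ch == '"':
            quoted = not quoted
            cur.append(ch)
        elif quoted:
            cur.append(ch)
        elif ch == "(":
            depth += 1
            cur.append(ch)
        elif ch == ")":
            depth -= 1
            cur.append(ch)
        elif ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def parse_atom(text: str) -> Atom:
    text = text.strip()
    m = re.match(r"^([a-z_][A-Za-z0-9_]*)\((.*)\)$", text, re.S)
    if not m:
        raise RuleError(f"cannot parse atom: {text!r}")
    pred, argstr = m.group(1), m.group(2).strip()
    if not argstr:
        raise RuleError(f"atom with no arguments: {text!r}")
    args = tuple(make_term(a) for a in _split_top(argstr, ","))
    return Atom(pred, args)


def parse_body_item(text: str):
    text = text.strip()
    if "!=" in text and not text.startswith("atleast("):
        left, right = (make_term(p) for p in text.split("!=", 1))
        return Neq(left, right)
    if text.startswith("atleast("):
        inner = text[len("atleast("):-1]
        parts = _split_top(inner, ";")
        if len(parts) != 3:
            raise RuleError(f"atleast needs 'n; vars; atom': {text!r}")
        n = int(parts[0].strip())
        count_vars = tuple(make_term(v) for v in _split_top(parts[1], ","))
        if not all(isinstance(v, Variable) for v in count_vars):
            raise RuleError(f"atleast count terms must be variables: {text!r}")
        return AtLeast(n, count_vars, parse_atom(parts[2]))
    return parse_atom(text)


# ---------------------------------------------------------------------------
# rules


@dataclass(frozen=True)
class Rule:
    id: str
    head: Atom
    body: tuple
    layer: int = 1

    def relational_atoms(self) -> list:
        return [b for b in self.body if isinstance(b, Atom)]

    def validate(self) -> None:
        if not self.body:
            raise RuleError(f"rule {self.id}: empty body")
        body_vars = set()
        for a in self.relational_atoms():
            body_vars |= a.variables()
        missing = self.head.variables() - body_vars
        if missing:
            raise RuleError(
                f"rule {self.id} is not range-restricted: head variables "
                f"{sorted(map(str, missing))} do not occur in the body"
            )
        for b in self.body:
            if isinstance(b, Neq):
                if b.variables() - body_vars:
                    raise RuleError(f"rule {self.id}: unbound variable in {b.render()}")
            # AtLeast needs no binding check: correlated subgoal variables
            # are bound by the relational atoms before it is evaluated and
            # the rest are local existentials


@dataclass(frozen=True)
class VirtualPredicate:
    """A predicate whose extension is computed from the graph rather than
    stored as triples (e.g. the feature/3 view over feature predicates).

    ``resolver(graph)`` yields ``(args_tuple, evidence_triple)`` pairs.
    """

    name: str
    arity: int
    resolver: Callable


class RuleBase:
    def __init__(self, rules: Iterable[Rule], virtuals: Optional[dict] = None):
        self.rules = list(rules)
        self.virtuals = dict(virtuals or {})
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise RuleError(f"duplicate rule ids: {ids}")
        for r in self.rules:
            r.validate()
        self._by_head: dict = {}
        for r in self.rules:
            self._by_head.setdefault(r.head.pred, []).append(r)
        self._check_aggregate_stratification()

    def __len__(self) -> int:
        return len(self.rules)

    def rules_for(self, pred: str) -> list:
        return self._by_head.get(pred, [])

    @property
    def derived_predicates(self) -> set:
        return set(self._by_head)

    def dependencies(self, pred: str) -> set:
        """Derived predicates reachable from *pred* (inclusive)."""
        seen, stack = set(), [pred]
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            for r in self.rules_for(p):
                for b in r.body:
                    if isinstance(b, Atom) and b.pred in self._by_head:
                        stack.append(b.pred)
                    elif isinstance(b, AtLeast) and b.subgoal.pred in self._by_head:
                        stack.append(b.subgoal.pred)
        return seen

    def _check_aggregate_stratification(self) -> None:
        agg_heads = {
            r.head.pred for r in self.rules if any(isinstance(b, AtLeast) for b in r.body)
        }
        for r in self.rules:
            for b in r.body:
                if isinstance(b, AtLeast):
                    deps = self.dependencies(b.subgoal.pred)
                    if deps & agg_heads:
                        raise RuleError(
                            f"rule {r.id}: aggregate over {b.subgoal.pred!r} depends on "
                            f"aggregate rule heads {sorted(deps & agg_heads)}"
                        )


def load_rulebase(source, params: Optional[dict] = None, virtuals: Optional[dict] = None) -> RuleBase:
    """Load rules from YAML (path, text or parsed list).

    Each entry is ``{id, layer, head: "pred(A, B)", body: ["...", ...]}``.
    ``$name`` placeholders are substituted from *params* before parsing.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read_text"):
        try:
            from pathlib import Path

            text = Path(source).read_text() if not str(source).lstrip().startswith(("-", "rules:")) else str(source)
        except OSError:
            text = str(source)
        data = yaml.safe_load(text)
    else:
        data = source
    if isinstance(data, dict):
        data = data.get("rules", [])
    rules = []
    for entry in data:
        head = _substitute_params(entry["head"], params)
        body = [_substitute_params(b, params) for b in entry["body"]]
        rules.append(
            Rule(
                id=str(entry["id"]),
                layer=int(entry.get("layer", 1)),
                head=parse_atom(head),
                body=tuple(parse_body_item(b) for b in body),
            )
        )
    return RuleBase(rules, virtuals=virtuals)


def _substitute_params(text: str, params: Optional[dict]) -> str:
    if not params:
        return text
    for name, value in params.items():
        text = text.replace(f"${name}", str(value))
    return text


# ---------------------------------------------------------------------------
# proof trees


@dataclass(frozen=True)
class FactLeaf:
    atom: tuple  # (pred, args)
    provenance: tuple = ()
    #: underlying graph triple (s, p, o) — differs from ``atom`` for
    #: virtual predicates, whose facts are views over stored triples
    source: Optional[tuple] = None

    def to_dict(self) -> dict:
        return {
            "type": "fact",
            "atom": _render_key(self.atom),
            "provenance": list(self.provenance),
            "source": list(self.source) if self.source else None,
        }


@dataclass(frozen=True)
class RuleApp:
    rule_id: str
    layer: int
    atom: tuple
    bindings: tuple  # sorted tuple of (var name, value)
    children: tuple

    def to_dict(self) -> dict:
        return {
            "type": "rule",
            "rule": self.rule_id,
            "layer": self.layer,
            "atom": _render_key(self.atom),
            "bindings": {k: v for k, v in self.bindings},
            "children": [c.to_dict() for c in self.children],
        }


@dataclass(frozen=True)
class BuiltinCheck:
    kind: str
    detail: str
    children: tuple = ()

    def to_dict(self) -> dict:
        return {
            "type": "builtin",
            "builtin": self.kind,
            "detail": self.detail,
            "children": [c.to_dict() for c in self.children],
        }


def _render_key(key: tuple) -> str:
    pred, args = key
    return f"{pred}({', '.join(args)})"


def proof_canonical(proof) -> str:
    return json.dumps(proof.to_dict(), sort_keys=True)


def inference_layers(proof) -> set:
    """Distinct positive rule layers applied anywhere in *proof* (layer 0
    marks the combination rule and is not counted as an inference layer)."""
    layers = set()

    def walk(node):
        if isinstance(node, RuleApp):
            if node.layer > 0:
                layers.add(node.layer)
            for c in node.children:
                walk(c)
        elif isinstance(node, BuiltinCheck):
            for c in node.children:
                walk(c)

    walk(proof)
    return layers


@dataclass(frozen=True)
class Answer:
    atom: tuple  # ground (pred, args)
    bindings: tuple  # goal-variable bindings, sorted tuple of pairs
    proofs: tuple

    @property
    def binding_dict(self) -> dict:
        return dict(self.bindings)


@dataclass
class ProofResult:
    status: str  # ACCEPTED | REJECTED
    answers: list = field(default_factory=list)

    @property
    def proofs(self) -> list:
        return [p for a in self.answers for p in a.proofs]

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "answers": [
                {
                    "atom": _render_key(a.atom),
                    "bindings": a.binding_dict,
                    "proofs": [p.to_dict() for p in a.proofs],
                }
                for a in self.answers
            ],
        }


# ---------------------------------------------------------------------------
# shared evaluation machinery


def _graph_facts(graph: KnowledgeGraph, rulebase: RuleBase) -> dict:
    """Base extension: triples as binary atoms plus virtual predicates.

    Returns pred -> dict[args tuple -> list of leaf proofs].
    """
    facts: dict = {}
    for t in sorted(graph.triples(), key=lambda t: t.key()):
        key = (t.subject, t.object)
        facts.setdefault(t.predicate, {}).setdefault(key, []).append(
            FactLeaf((t.predicate, key), t.provenance, (t.subject, t.predicate, t.object))
        )
    for name, vp in rulebase.virtuals.items():
        table = facts.setdefault(name, {})
        for args, evidence in vp.resolver(graph):
            args = tuple(args)
            leaf = FactLeaf(
                (name, args),
                evidence.provenance if evidence is not None else (),
                (evidence.subject, evidence.predicate, evidence.object)
                if evidence is not None
                else None,
            )
            entry = table.setdefault(args, [])
            if leaf not in entry:
                entry.append(leaf)
    return facts


def _unify_args(pattern_args: tuple, ground_args: tuple, binding: dict):
    out = dict(binding)
    for pat, val in zip(pattern_args, ground_args):
        if isinstance(pat, Variable):
            name = str(pat)
            if name in out:
                if out[name] != val:
                    return None
            else:
                out[name] = val
        elif pat != val:
            return None
    return out


class _Evaluator:
    """Answer tables shared by the forward and backward strategies."""

    def __init__(self, graph: KnowledgeGraph, rulebase: RuleBase):
        self.graph = graph
        self.rb = rulebase
        self.facts = _graph_facts(graph, rulebase)
        self.tables: dict = {}  # derived pred -> dict[args -> list proofs]
        self.new_atom = False

    # -- lookup ----------------------------------------------------------

    def extension(self, pred: str) -> dict:
        merged: dict = {}
        for table in (self.facts.get(pred, {}), self.tables.get(pred, {})):
            for args, proofs in table.items():
                entry = merged.setdefault(args, [])
                entry.extend(p for p in proofs if p not in entry)
        return merged

    def solutions(self, atom: Atom, binding: dict):
        """Yield (binding, ground args, proofs) for one body atom."""
        bound = atom.substitute(binding)
        for pred_table in (self.facts.get(atom.pred, {}), self.tables.get(atom.pred, {})):
            # snapshot: recursive rules append to the table mid-iteration
            for args, proofs in list(pred_table.items()):
                nb = _unify_args(bound.args, args, binding)
                if nb is not None:
                    yield nb, args, proofs

    # -- rule evaluation --------------------------------------------------

    def eval_rule(self, rule: Rule) -> None:
        for binding, children_sets in self._join(rule.body, {}, []):
            head_args = tuple(
                binding[str(a)] if isinstance(a, Variable) else a for a in rule.head.args
            )
            self._record(rule, head_args, binding, children_sets)

    def _join(self, items, binding, children):
        if not items:
            # all relational atoms and evaluable builtins consumed
            yield binding, list(children)
            return
        item, rest = items[0], list(items[1:])
        if isinstance(item, Atom):
            for nb, args, proofs in self.solutions(item, binding):
                yield from self._join(rest, nb, children + [list(proofs)])
        elif isinstance(item, Neq):
            left = binding.get(str(item.left), item.left) if isinstance(item.left, Variable) else item.left
            right = binding.get(str(item.right), item.right) if isinstance(item.right, Variable) else item.right
            if isinstance(left, Variable) or isinstance(right, Variable):
                if any(isinstance(x, Atom) for x in rest):
                    # defer until the remaining atoms bind the variables
                    yield from self._join(rest + [item], binding, children)
                return
            if left != right:
                node = BuiltinCheck("neq", f"{left} != {right}")
                yield from self._join(rest, binding, children + [[node]])
        elif isinstance(item, AtLeast):
            if any(isinstance(x, Atom) for x in rest):
                # evaluate after the relational atoms have bound the
                # correlated variables
                yield from self._join(rest + [item], binding, children)
                return
            node = self._eval_atleast(item, binding)
            if node is not None:
                yield from self._join(rest, binding, children + [[node]])

    def _eval_atleast(self, item: AtLeast, binding: dict):
        witnesses: dict = {}
        for nb, args, proofs in self.solutions(item.subgoal, binding):
            key = tuple(nb[str(v)] for v in item.count_vars)
            if key not in witnesses and proofs:
                witnesses[key] = proofs[0]
        if len(witnesses) < item.n:
            return None
        children = tuple(witnesses[k] for k in sorted(witnesses))
        detail = (
            f"atleast({item.n}; {', '.join(map(str, item.count_vars))}; "
            f"{item.subgoal.substitute(binding).render()}): {len(witnesses)} distinct"
        )
        return BuiltinCheck("atleast", detail, children)

    def _record(self, rule: Rule, head_args: tuple, binding: dict, children_sets: list) -> None:
        table = self.tables.setdefault(rule.head.pred, {})
        if head_args not in table:
            table[head_args] = []
            self.new_atom = True
        proofs = table[head_args]
        if len(proofs) >= PROOF_CAP:
            return
        ground_binding = tuple(sorted((k, v) for k, v in binding.items()))
        # one proof per combination of the first proof of each child (full
        # cartesian products explode; alternatives surface as distinct
        # bindings, which is what matters for explanation)
        children = tuple(cs[0] for cs in children_sets)
        proof = RuleApp(rule.id, rule.layer, (rule.head.pred, head_args), ground_binding, children)
        if proof not in proofs:
            proofs.append(proof)

    # -- fixpoints ---------------------------------------------------------

    def saturate(self, preds: Optional[set] = None) -> None:
        """Iterate rule evaluation to the answer fixpoint.

        Aggregate-free rules first (their own fixpoint), then all rules
        including aggregates; load-time stratification makes this sound.
        """
        if preds is None:
            rules = self.rb.rules
        else:
            rules = [r for r in self.rb.rules if r.head.pred in preds]
        plain = [r for r in rules if not any(isinstance(b, AtLeast) for b in r.body)]
        for stage in (plain, rules):
            while True:
                self.new_atom = False
                before = self._proof_signature(stage)
                for rule in stage:
                    self.eval_rule(rule)
                if not self.new_atom and self._proof_signature(stage) == before:
                    break
        # proof-propagation passes: proofs found late may enable deeper
        # alternative proofs; bounded to keep cyclic rule sets terminating
        for _ in range(_PROOF_PASSES):
            before = self._proof_signature(rules)
            for rule in rules:
                self.eval_rule(rule)
            if self._proof_signature(rules) == before:
                break

    def _proof_signature(self, rules) -> tuple:
        return tuple(
            (pred, args, len(proofs))
            for pred in sorted(self.tables)
            for args, proofs in sorted(self.tables[pred].items())
        )


# ---------------------------------------------------------------------------
# public API


def backward_chain(graph: KnowledgeGraph, rulebase: RuleBase, goal: Atom) -> ProofResult:
    """Prove *goal* (ground or with variables) against graph + rules.

    ACCEPTED iff at least one proof exists, i.e. iff the goal instance is
    in the forward closure; REJECTED otherwise.  Answers and proofs are
    enumerated in deterministic (lexicographic) order.
    """
    ev = _Evaluator(graph, rulebase)
    if goal.pred in rulebase.derived_predicates:
        ev.saturate(rulebase.dependencies(goal.pred))
    grouped: dict = {}
    for args, proofs in ev.extension(goal.pred).items():
        binding = _unify_args(goal.args, args, {})
        if binding is None:
            continue
        goal_binding = tuple(sorted((str(v), binding[str(v)]) for v in goal.variables()))
        ordered = tuple(sorted(set(proofs), key=proof_canonical))
        grouped[args] = Answer((goal.pred, args), goal_binding, ordered)
    answers = [grouped[k] for k in sorted(grouped)]
    status = "ACCEPTED" if answers else "REJECTED"
    return ProofResult(status, answers)


def solve(graph: KnowledgeGraph, rulebase: RuleBase, goal: Atom) -> list:
    """All answers for *goal*; convenience wrapper over backward_chain."""
    return backward_chain(graph, rulebase, goal).answers


def count_solutions(graph: KnowledgeGraph, rulebase: RuleBase, goal: Atom) -> int:
    """Number of distinct ground instances proving *goal*."""
    return len(backward_chain(graph, rulebase, goal).answers)


@dataclass
class Closure:
    """Least Horn model of (graph, rules)."""

    graph: KnowledgeGraph  # input triples + inferred binary facts (INFERRED)
    atoms: set  # every ground (pred, args), base and derived, incl. virtuals
    derived: set  # derived ground atoms only

    def holds(self, atom: Atom) -> bool:
        return (atom.pred, atom.args) in self.atoms


def forward_closure(graph: KnowledgeGraph, rulebase: RuleBase) -> Closure:
    """Semi-naive bottom-up evaluation to the least fixpoint.

    Inferred binary facts are added to the returned graph with INFERRED
    provenance; derived facts of other arities are reported in ``atoms``
    (triples cannot carry them).  Idempotent and monotone in the input
    graph.
    """
    ev = _Evaluator(graph, rulebase)
    ev.saturate()
    atoms = set()
    for pred, table in ev.facts.items():
        for args in table:
            atoms.add((pred, args))
    derived = set()
    out = graph.copy()
    for pred, table in ev.tables.items():
        for args in table:
            atoms.add((pred, args))
            derived.add((pred, args))
            if len(args) == 2:
                out.add_triple(args[0], pred, args[1], "INFERRED")
    return Closure(out, atoms, derived)
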