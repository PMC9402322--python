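# Methods

## The model

`mechkg` treats DDI mechanism inference as deduction over a fact base.
The knowledge graph is a set of subject–predicate–object triples over
CUI-identified entities (UMLS-style `C` + 7 digits; external records
that never resolve to a CUI keep a source-prefixed id such as
`DB:DB00762` and remain queryable). Each triple carries the set of
source tags that asserted it (MRCONSO, MRREL, MRSAT, DRUGLINK, GENELINK,
FIXTURE, INFERRED); re-adding a fact merges tags rather than duplicating
the triple.

Whether a predicate's object is a concept or a controlled literal is
declared in a predicate registry (`mechkg.vocab`), together with the
predicate's similarity level (if it contributes to layer-2 feature
matching) and its domain/range constraints. Transporter proteins are
not an eighth ontology subclass: they sit in the `enzymes` subclass and
are distinguished by a `has_role` annotation
(`metabolizing_enzyme`/`transporter`), which preserves the
four-class/seven-subclass ontology while letting the rules separate
metabolism from transport.

## Rule semantics

Rules are range-restricted Horn clauses over n-ary atoms; graph triples
are the binary base atoms. Two builtins are supported: disequality
(`A != B`) and a monotone aggregate `atleast(n; V; atom)` that succeeds
when at least `n` distinct bindings of the count variables satisfy the
subgoal. Aggregate subgoals may not depend (transitively) on the heads
of aggregate rules — checked at load time — so the semantics stay
stratified and monotone. Negation is not supported: absence of evidence
yields a REJECTED status, never a derived fact.

`feature/3` is a *virtual* predicate: `feature(D, L, V)` holds for every
stored triple `(D, p, V)` whose predicate `p` is registered at
similarity level `L`. This keeps the printed rule count at six while
the mapping from concrete predicates to levels remains configuration
(the registry), not extra rules.

The default rule base (YAML, shipped in `mechkg/data/rules_default.yaml`)
has four layer-1 mechanism rules (enzyme/transporter ×
inhibition/induction), one layer-2 shared-feature rule, and one
combination rule with the threshold θ substituted in at load time.
`A != B` appears in the mechanism rules because a perpetrator must
differ from its victim (a drug can be both substrate and inhibitor of
the same enzyme). Induction is flagged "reduced exposure" versus
inhibition's "increased exposure" in the rationale text only; the
verdict logic treats the two modes identically.

## The engine

**Backward chaining** is tabled at predicate granularity: starting from
the goal predicate, only the rules reachable from it are evaluated;
answers are recorded per predicate and evaluation iterates to a
fixpoint, so recursive terminology rules (e.g. ancestor chains over
`parent_of`, including cycles) terminate. A goal is ACCEPTED iff at
least one proof exists, which coincides with membership in the least
Horn model.

**Forward closure** is a bottom-up evaluation of the same rules to the
least fixpoint and serves as the independent correctness oracle: the
central property test fuzzes 1,000 random graphs (≤ 60 triples) and
requires 100% agreement between backward acceptance and closure
membership for every derived ground goal plus negative probes. Inferred
*binary* facts are written back as triples with INFERRED provenance;
derived atoms of other arities (`mech/4`, `shared/4`) cannot be triples
and are reported in the closure's atom set instead — a deliberate
signature choice documented here because a triple store cannot carry
4-ary atoms without reification.

**Proofs.** Every answer carries proof trees: rule applications with
ground bindings down to leaf facts (with provenance and the underlying
source triple). Distinct derivations surface as distinct proofs (this
is what reports both the CYP3A4 and the ABCB1 mechanism); proofs are
deduplicated structurally and capped at 64 per derived fact, with a
bounded number of proof-propagation passes so that cyclic rule sets
cannot enumerate unboundedly deep derivations. The cap bounds
alternative derivations per fact, never answers. `potential_ddi` is
queried in both pair orders, since the perpetrator may be either drug.

Layer counting for explanations: `inference_layers` collects the
distinct positive layer tags of rule applications in a proof; the
combination rule carries layer 0 and is not itself counted, so an
accepted case-study proof decomposes into exactly the two inference
layers (mechanism, shared features).

## ETL and validation choices

* MRCONSO/MRREL/MRSAT dialects are `CUI|SAB|CODE|STR`,
  `CUI1|REL|RELA|CUI2|SAB`, `CUI|ATN|ATV`; links are a headed CSV.
  These are deliberately narrower than released UMLS RRF; the real
  18-column layout is out of scope.
* All MRREL relations are loaded, unfiltered: predicate = lowercase
  RELA when present, else a normalized coarse REL
  (RO→related_to, PAR/CHD→parent_of/child_of, RB/RN→broader/narrower,
  anything else lowercased).
* Semantic types come from MRSAT records with `ATN=SEMTYPE` (not a
  separate MRSTY-style file). Other attribute names map through a small
  table (`ROLE`→`has_role`, `SUBSTRUCTURE`→`has_substructure_class`);
  unknown attribute names are counted as ignored, never silently lost.
* Shared-identifier linking: a link row carrying both an external id and
  a CUI registers an alias, so later rows with the external id alone
  attach to the same concept; rows with no resolvable CUI are stored
  under the prefixed external id *and* listed in the load report's
  unresolved-links section. Nothing is dropped without trace:
  per source, parsed = triples + annotations + ignored.
* Only T028 → genes is fixed by the terminology itself; the rest of the
  default semantic-type map (T121/T109/T200 → drugs, T126/T116 →
  enzymes, T043/T038 → biological processes, T044/T042 → mechanism of
  action, T046/T047/T184 → effect, T086 → SNPs) is this package's
  minimal working set and is fully overridable in the run config.
* Consistency checking is structural, not description-logic reasoning:
  multi-class conflicts (candidate subclasses spanning >1 core class),
  unknown predicates, and domain/range violations. Unclassified
  entities are warnings by default (real terminology loads always
  contain unmapped types); a strict mode promotes them. Range checks
  can be disabled in config.

## Similarity levels and the threshold

Six levels: the four ontology levels (pharmacological/MoA,
biomolecular, physiological, genetic) plus contraindication-on-allergy
and substructure-class sharing, which the case study actually uses.
Substructure sharing is asserted-fact matching on controlled literals
(`has_substructure_class`), not computed chemical fingerprinting — the
evidence consists of named substructure classes, not structures.
θ defaults to 1 (any shared level suffices, given a mechanism); "the
pair sharing the most features" is additionally exposed as a ranking
(`rank_pairs`: shared levels desc, feature matches desc, mechanism
matches desc, lexicographic pair id) rather than baked into the verdict.

## The canonical fixture

Fourteen entities under stable pseudo-CUIs (`C9000001`…, deliberately
not real UMLS identifiers): the two drugs, CYP3A4 and ABCB1 with their
roles, two allergy concepts, the shared physiological effect, plus
unshared per-drug facts (mechanisms of action, gene associations, a GO
process, two drug-class parents) so that the report's NA rows are
meaningful. The mechanism facts arrive through DrugBank-like link rows,
the gene associations through PharmGKB-like rows, effects and
contraindications through MRREL, roles and semantic types through
MRSAT, and the 14 substructure classes through link rows that resolve
via the shared-identifier alias — so a single fixture exercises every
ETL channel. The manifest's declared counts are recomputed in tests by
an independent line count.

## The simulator

`SimParams` defaults describe a small but non-trivial condition:
8 drugs, 3 enzymes, 2 transporters, 4 feature values per level,
background rates p_inhibits = 0.08, p_induces = 0.04, p_substrate = 0.15,
p_feature = 0.15, 2 planted DDIs, θ = 1. Rates are chosen so that
chance-formed mechanisms and feature overlaps occur regularly (several
rule-satisfying pairs per graph beyond the planted ones) without
saturating the pair space — the regime in which exact truth recovery is
a meaningful check. Planted pairs are guaranteed a mechanism and θ
shared levels; everything is emitted through the same source-file
dialects the ETL reads.

Ground truth is *rule-satisfying pairs*, not planted pairs, computed at
generation time by exhaustive enumeration over the generated fact sets
(independent of the inference engine), so chance-formed DDIs never read
as false positives; with deterministic rules, precision = recall = 1.0
is the required outcome, and any deviation is an engine bug.

What the generator does **not** emulate: real UMLS scale (millions of
concepts), vocabulary noise (synonymy, suppressed atoms, cross-source
label conflicts), incomplete or contradictory drug-resource records,
and any dose/exposure quantification. Passing tests therefore
demonstrate correctness of the integration and inference machinery on
well-formed inputs, not robustness to real terminology noise or the
clinical validity of any inferred interaction.

## Determinism and numerics

There are no floating-point computations in the core; the numerical
choices are ordering and identity. All externally visible orders are
lexicographic (serialized entities/triples, match results, answers,
proofs via their canonical JSON, report rows); the engine may use any
internal order. N-Triples output is line-sorted; JSON uses sorted keys.
Per-triple provenance survives RDF export through one deterministic
(SHA-1-keyed) reified statement node per fact, which is what makes
`deserialize(serialize(g))` the identity in all three formats.
Simulation randomness is a single `numpy` generator per run, seeded
from the CLI/script seed; identical seeds give byte-identical files.
Degenerate inputs are defined behavior: empty graphs are consistent and
reject every goal, a pattern with no variables is a membership test,
and a drug assessed against itself shares nothing (`A != B`).

## Problem sizes used

The test suite fuzzes 1,000 random graphs for the engine-equivalence
property, replays 20 simulation seeds for truth recovery, and 100 seeds
× 4 defect kinds for consistency detection. `scripts/acceptance.py`
uses 300 fuzz graphs (~7,000 goals), 20 simulation seeds and 100
consistency seeds in a single ~30 s run; these sizes were chosen as
comfortably past the point where the all-or-nothing properties
stabilize, since the checks are exact rather than statistical.

## Known limitations

* No OWL-DL reasoning; the consistency check is exactly the enumerated
  structural rules.
* No probabilistic weighting or stratified negation in the rule
  language; all evidence counts equally.
* Proof enumeration is capped per fact (answers are never lost, but in
  pathological cyclic rule bases some alternative derivations beyond
  the cap are not materialized).
* The feature similarity is exact value sharing under a common
  predicate level; no graded chemical or semantic similarity is
  computed.
* No persistent triple store, transactions, or SPARQL endpoint; graphs
  are in-memory with file round-trips.
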