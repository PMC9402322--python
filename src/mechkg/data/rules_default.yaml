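# Default two-layer DDI rule base (six rules).
#
# Layer 1 (R1-R4): pharmacological effect at the metabolism/transport
#   level — one drug inhibits or induces a protein the other drug is a
#   substrate of; the protein's has_role annotation separates
#   metabolizing enzymes from transporters.
#   mech(Perpetrator, Victim, Target, Mode)
# Layer 2 (R5): shared biomedical features — both drugs carry the same
#   value under the same similarity level (feature/3 is the registry
#   view over feature predicates).
# Combination (R6, layer tag 0): a pair is a potential DDI when a
#   mechanism exists and at least $theta distinct similarity levels are
#   shared.
rules:
  - id: R1
    layer: 1
    head: mech(A, B, E, inhibition)
    body:
      - inhibits(A, E)
      - substrate_of(B, E)
      - has_role(E, metabolizing_enzyme)
      - A != B
  - id: R2
    layer: 1
    head: mech(A, B, E, induction)
    body:
      - induces(A, E)
      - substrate_of(B, E)
      - has_role(E, metabolizing_enzyme)
      - A != B
  - id: R3
    layer: 1
    head: mech(A, B, T, inhibition)
    body:
      - inhibits(A, T)
      - substrate_of(B, T)
      - has_role(T, transporter)
      - A != B
  - id: R4
    layer: 1
    head: mech(A, B, T, induction)
    body:
      - induces(A, T)
      - substrate_of(B, T)
      - has_role(T, transporter)
      - A != B
  - id: R5
    layer: 2
    head: shared(A, B, L, V)
    body:
      - feature(A, L, V)
      - feature(B, L, V)
      - A != B
  - id: R6
    layer: 0
    head: potential_ddi(A, B)
    body:
      - mech(A, B, T, M)
      - atleast($theta; L; shared(A, B, L, V))
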