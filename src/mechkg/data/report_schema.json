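{
 "type": "object",
 "required": [
  "drug_a",
  "drug_b",
  "verdict",
  "threshold",
  "shared_level_count",
  "shared_levels",
  "pharmacological_effects",
  "biomedical_features",
  "mechanism_matches",
  "feature_matches",
  "rationale",
  "proofs"
 ],
 "properties": {
  "drug_a": {
   "type": "object",
   "required": ["id", "label"],
   "properties": {"id": {"type": "string"}, "label": {"type": "string"}}
  },
  "drug_b": {
   "type": "object",
   "required": ["id", "label"],
   "properties": {"id": {"type": "string"}, "label": {"type": "string"}}
  },
  "verdict": {"type": "string", "enum": ["POTENTIAL_DDI", "NO_EVIDENCE"]},
  "threshold": {"type": "integer"},
  "shared_level_count": {"type": "integer"},
  "shared_levels": {"type": "array", "items": {"type": "string"}},
  "pharmacological_effects": {"type": "object"},
  "biomedical_features": {"type": "object"},
  "mechanism_matches": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["target", "target_kind", "perpetrator", "perpetrator_role", "victim", "rule"],
    "properties": {
     "target": {"type": "string"},
     "target_kind": {"type": "string", "enum": ["metabolizing_enzyme", "transporter"]},
     "perpetrator": {"type": "string"},
     "perpetrator_role": {"type": "string", "enum": ["inhibitor", "inducer"]},
     "victim": {"type": "string"},
     "rule": {"type": "string"},
     "flavor": {"type": "string"}
    }
   }
  },
  "feature_matches": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["level", "shared_value", "evidence"],
    "properties": {
     "level": {"type": "string"},
     "shared_value": {"type": "string"},
     "evidence": {"type": "array"}
    }
   }
  },
  "rationale": {"type": "array", "items": {"type": "string"}},
  "proofs": {"type": "array"}
 }
}
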