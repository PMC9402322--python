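"""Classify fixture entities against the four-class ontology, check
consistency, and print a drug's mechanistic feature profile.

The consistency check enforces the ontology structurally: one subclass
per core class per entity, registered predicates only, and domain/range
constraints.  The profile lists every registered fact about the drug,
grouped by asserting source and by ontology class of the value.
"""

import json
import tempfile

from mechkg import (
    canonical_fixture,
    check_consistency,
    classify,
    default_schema,
    feature_profile,
    load_fixture_graph,
)
from mechkg.synth import LEVOFLOXACIN

with tempfile.TemporaryDirectory() as tmp:
    canonical_fixture(tmp)
    graph, _ = load_fixture_graph(tmp)

schema = default_schema()
classify(graph, schema)
report = check_consistency(graph, schema)
print(f"consistent: {report.is_consistent} "
      f"({len(report.violations)} violations, {len(report.warnings)} warnings)")

by_subclass = {}
for rec in graph.entities.values():
    if rec.subclass:
        by_subclass[rec.subclass] = by_subclass.get(rec.subclass, 0) + 1
print("entities per subclass:", json.dumps(by_subclass, sort_keys=True))

prof = feature_profile(graph, LEVOFLOXACIN)
print(f"\nlevofloxacin profile ({len(prof.facts)} facts):")
for source, facts in sorted(prof.per_source.items()):
    shown = ", ".join(f"{p}={v}" for p, v, _ in facts[:3])
    more = f" (+{len(facts) - 3} more)" if len(facts) > 3 else ""
    print(f"  {source}: {shown}{more}")
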