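"""Reproduce the irinotecan-levofloxacin case study end to end.

Writes the canonical fixture files, runs the ETL, assesses the pair with
the default six-rule base, and prints the interaction report.  The two
mechanism matches say that levofloxacin (perpetrator, inhibitor) acts on
CYP3A4 and ABCB1 while irinotecan is a substrate of both (victim); the
three shared similarity levels (contraindication, physiological,
substructure) satisfy the combination rule, so the verdict is
POTENTIAL_DDI.
"""

import tempfile

from mechkg import assess_ddi, canonical_fixture, load_fixture_graph, render_report
from mechkg.synth import IRINOTECAN, LEVOFLOXACIN

with tempfile.TemporaryDirectory() as tmp:
    canonical_fixture(tmp)
    graph, load_report = load_fixture_graph(tmp)

print(f"graph: {len(graph)} triples over {len(graph.entities)} entities")
assessment = assess_ddi(graph, IRINOTECAN, LEVOFLOXACIN, theta=1)
print(f"verdict: {assessment.verdict}")
print(f"mechanism matches: {len(assessment.mechanism_matches)}")
for m in assessment.mechanism_matches:
    print(
        f"  {assessment.labels[m.perpetrator]} {m.perpetrator_role} of "
        f"{m.target_kind.replace('_', ' ')} {graph.entities[m.target].labels[0]}; "
        f"{assessment.labels[m.victim]} substrate ({m.flavor})"
    )
print(f"shared similarity levels: {assessment.shared_level_count} {assessment.shared_levels}")
print()
print(render_report(assessment, "markdown").decode())
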