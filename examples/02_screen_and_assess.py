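"""Screen a handful of reports against the packaged example knowledge base.

Three multi-drug reports are checked for listed drug-pair interactions;
for each hit we ask whether the reported reaction matches the listed
interaction effect (an *occurred* DDI) and assign the A/B/C group:
A = occurred, B = potential only, C = no listed interaction.
"""

from ddiscreen import (
    DrugEntry, IcsrReport, ReactionEntry,
    assess_reports, assign_groups, screen_reports,
)
from ddiscreen.datasets import example_kb

kb = example_kb()


def report(rid, drug_roles, terms):
    return IcsrReport(
        report_id=rid, serious=True,
        seriousness_criteria=frozenset({"hospitalization"}),
        causality="probable",
        drugs=tuple(DrugEntry(substance_id=s, role=r) for s, r in drug_roles),
        reactions=tuple(ReactionEntry(term_code=t) for t in terms),
    )


reports = [
    # warfarin + lansoprazole with a GI bleed: the listed effect occurred
    report("case-1", [("warfarin", "suspect"), ("lansoprazole", "concomitant")],
           ["GASTROINTESTINAL_HAEMORRHAGE"]),
    # aspirin + clopidogrel but the reaction is unrelated: potential only
    report("case-2", [("aspirin", "suspect"), ("clopidogrel", "suspect")],
           ["RASH"]),
    # no listed interaction between these two
    report("case-3", [("metformin", "suspect"), ("amlodipine", "concomitant")],
           ["DIZZINESS"]),
]

potentials = screen_reports(reports, kb)
occurred, review = assess_reports(reports, potentials)
labels = assign_groups(reports, potentials, occurred)

for r in reports:
    hits = potentials[r.report_id]
    print(f"{r.report_id}: group {labels[r.report_id].value}", end="")
    if hits:
        print(f"  ({hits[0].pair}, severity {hits[0].severity.name})", end="")
    for o in occurred[r.report_id]:
        print(f"  matched terms: {sorted(o.matched_terms)}", end="")
    print()

# Group A means the reaction realises the listed interaction effect;
# group B means the pair is listed but the reported reaction is different;
# group C means no pair in the report is listed at all.
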