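"""Shared fixtures: small hand-constructed report sets and knowledge bases."""

from __future__ import annotations

import pytest

from ddiscreen import (
    DrugEntry,
    IcsrReport,
    KnowledgeBase,
    ReactionEntry,
    ReportSet,
)
from ddiscreen.ddi_kb import DdiRecord, Severity, canonical_pair


def make_report(
    rid: str,
    drugs: list[tuple[str, str]],
    reactions: list[str] = (),
    *,
    serious: bool = True,
    criteria: set[str] = frozenset({"hospitalization"}),
    causality: str = "probable",
    vaccine: bool = False,
    fatal_reaction: bool = False,
    age: float | None = 70.0,
    sex: str = "female",
    reporter: str = "physician",
    flags: dict[str, bool] | None = None,
    ddi_flagged: bool = False,
) -> IcsrReport:
    """Compact report builder: drugs as (substance, role) tuples, reactions
    as term codes."""
    flags = flags or {}
    return IcsrReport(
        report_id=rid,
        age_years=age,
        sex=sex,
        reporter=reporter,
        serious=serious,
        seriousness_criteria=frozenset(criteria) if serious else frozenset(),
        causality=causality,
        is_vaccine_report=vaccine,
        drugs=tuple(
            DrugEntry(
                substance_id=s,
                role=r,
                flagged_interacting=flags.get(s.upper(), False),
            )
            for s, r in drugs
        ),
        reactions=tuple(
            ReactionEntry(term_code=t, fatal_outcome=fatal_reaction and i == 0)
            for i, t in enumerate(reactions)
        ),
        ddi_flagged=ddi_flagged,
    )


def make_kb(rows: list[tuple[str, str, Severity, set[str]]]) -> KnowledgeBase:
    """KB builder from (drug_a, drug_b, severity, effect_terms) rows."""
    kb = KnowledgeBase(version_label="test-kb")
    for a, b, sev, terms in rows:
        kb.add(
            DdiRecord(
                pair=canonical_pair(a, b),
                severity=sev,
                effect_text=f"{a}/{b} effect",
                effect_terms=frozenset(t.upper() for t in terms),
            )
        )
    return kb


@pytest.fixture
def small_kb() -> KnowledgeBase:
    return make_kb(
        [
            ("WARFARIN", "ASPIRIN", Severity.major, {"GI_BLEED", "INR_UP"}),
            ("WARFARIN", "OMEPRAZOLE", Severity.major, {"INR_UP"}),
            ("DIGOXIN", "FUROSEMIDE", Severity.contraindicated, {"BRADYCARDIA"}),
            ("ASPIRIN", "IBUPROFEN", Severity.minor, {"DYSPEPSIA"}),
            ("SERTRALINE", "TRAMADOL", Severity.moderate, set()),  # review-only
        ]
    )


@pytest.fixture
def funnel_reports() -> ReportSet:
    """Twelve hand-labelled reports for the case-selection funnel.

    Exclusions in filter order: r03+r04 vaccine, r05+r06+r07 non-serious,
    r08 causality, r09+r10 single-drug; analyzed: r01, r02, r11, r12.
    """
    r = [
        make_report("r01", [("warfarin", "suspect"), ("aspirin", "concomitant")],
                    ["GI_BLEED"]),
        make_report("r02", [("digoxin", "suspect"), ("furosemide", "concomitant"),
                            ("aspirin", "concomitant")], ["RASH"]),
        make_report("r03", [("warfarin", "suspect"), ("aspirin", "suspect")],
                    ["FEVER"], vaccine=True),
        make_report("r04", [("mmr vaccine", "suspect"), ("aspirin", "concomitant")],
                    ["FEVER"], vaccine=True, serious=False),
        make_report("r05", [("warfarin", "suspect"), ("aspirin", "suspect")],
                    ["GI_BLEED"], serious=False),
        make_report("r06", [("omeprazole", "suspect"), ("warfarin", "concomitant")],
                    ["INR_UP"], serious=False),
        make_report("r07", [("paracetamol", "suspect")], ["RASH"], serious=False),
        make_report("r08", [("warfarin", "suspect"), ("aspirin", "concomitant")],
                    ["GI_BLEED"], causality="unlikely"),
        make_report("r09", [("warfarin", "suspect")], ["GI_BLEED"]),
        make_report("r10", [("digoxin", "suspect"), ("digoxin", "concomitant")],
                    ["NAUSEA"]),  # one distinct drug
        make_report("r11", [("sertraline", "suspect"), ("tramadol", "concomitant")],
                    ["TREMOR"]),
        make_report("r12", [("amlodipine", "suspect"), ("metformin", "concomitant")],
                    ["DIZZINESS"]),
    ]
    return ReportSet(reports=tuple(r), provenance="hand-fixture")
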