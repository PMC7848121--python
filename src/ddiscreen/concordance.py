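"""Concordance assessment: did a potential interaction actually occur?

A potential DDI is judged *occurred* when the report's coded reactions
intersect the knowledge-base record's effect-term set; one matching term
suffices. Records whose effect-term set is empty cannot be machine-matched
and are routed to a review queue for human adjudication (the algorithmic
stand-in for an expert panel) rather than silently dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .ddi_kb import DdiRecord, PairKey, Severity
from .icsr_model import DrugRole, IcsrReport, ReactionEntry
from .screening import PotentialDdi

__all__ = [
    "MatchStatus",
    "MatchResult",
    "OccurredDdi",
    "ReviewItem",
    "match_effect",
    "assess_report",
    "assess_reports",
]


class MatchStatus(str, enum.Enum):
    occurred = "occurred"
    not_occurred = "not_occurred"
    needs_review = "needs_review"


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching a report's reactions against a KB record.

    ``status == occurred`` iff ``matched_terms`` is non-empty;
    ``needs_review`` iff the record listed no effect terms.
    """

    status: MatchStatus
    matched_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.status is MatchStatus.occurred) != bool(self.matched_terms):
            raise ValueError("occurred status iff matched_terms non-empty")


@dataclass(frozen=True)
class OccurredDdi:
    """A potential DDI whose interaction effect was actually reported."""

    report_id: str
    pair: PairKey
    severity: Severity
    record: DdiRecord
    matched_terms: frozenset[str]
    both_drugs_suspect: bool
    flagged_interacting: bool


@dataclass(frozen=True)
class ReviewItem:
    """A potential DDI deferred to human review (empty effect-term set)."""

    report_id: str
    pair: PairKey
    severity: Severity
    effect_text: str
    reaction_terms: frozenset[str]


def match_effect(
    reactions: Iterable[ReactionEntry], record: DdiRecord
) -> MatchResult:
    """Set-intersection match between reaction term codes and the record's
    effect terms. Deterministic; order of reactions is irrelevant."""
    if record.needs_review:
        return MatchResult(status=MatchStatus.needs_review)
    matched = frozenset(r.term_code for r in reactions) & record.effect_terms
    if matched:
        return MatchResult(status=MatchStatus.occurred, matched_terms=matched)
    return MatchResult(status=MatchStatus.not_occurred)


def _pair_roles(report: IcsrReport, pair: PairKey) -> tuple[bool, bool]:
    """(both members suspect, any member carries the interaction flag)."""
    roles: dict[str, set[DrugRole]] = {}
    flags: dict[str, bool] = {}
    for d in report.drugs:
        k = d.identity_key
        roles.setdefault(k, set()).add(d.role)
        flags[k] = flags.get(k, False) or d.flagged_interacting
    both_suspect = all(
        DrugRole.suspect in roles.get(k, set()) for k in (pair.first, pair.second)
    )
    flagged = report.ddi_flagged or any(
        flags.get(k, False) for k in (pair.first, pair.second)
    )
    return both_suspect, flagged


def assess_report(
    report: IcsrReport, potentials: Sequence[PotentialDdi]
) -> tuple[list[OccurredDdi], list[ReviewItem]]:
    """Assess each potential DDI of one report independently.

    Returns the occurred DDIs (with reporter-recognition attributes
    ``both_drugs_suspect`` and ``flagged_interacting`` computed from the
    report) and the review-queue items for unmatched-by-construction records.
    """
    occurred: list[OccurredDdi] = []
    review: list[ReviewItem] = []
    for pot in potentials:
        if pot.report_id != report.report_id:
            raise ValueError(
                f"potential DDI for {pot.report_id!r} assessed against "
                f"report {report.report_id!r}"
            )
        res = match_effect(report.reactions, pot.record)
        if res.status is MatchStatus.occurred:
            both_suspect, flagged = _pair_roles(report, pot.pair)
            occurred.append(
                OccurredDdi(
                    report_id=report.report_id,
                    pair=pot.pair,
                    severity=pot.severity,
                    record=pot.record,
                    matched_terms=res.matched_terms,
                    both_drugs_suspect=both_suspect,
                    flagged_interacting=flagged,
                )
            )
        elif res.status is MatchStatus.needs_review:
            review.append(
                ReviewItem(
                    report_id=report.report_id,
                    pair=pot.pair,
                    severity=pot.severity,
                    effect_text=pot.record.effect_text,
                    reaction_terms=frozenset(r.term_code for r in report.reactions),
                )
            )
    return occurred, review


def assess_reports(
    reports: Iterable[IcsrReport], potentials: dict[str, list[PotentialDdi]]
) -> tuple[dict[str, list[OccurredDdi]], list[ReviewItem]]:
    """Assess every report; map report_id -> occurred DDIs, plus the pooled
    review queue."""
    occurred: dict[str, list[OccurredDdi]] = {}
    review: list[ReviewItem] = []
    for r in reports:
        occ, rev = assess_report(r, potentials.get(r.report_id, []))
        occurred[r.report_id] = occ
        review.extend(rev)
    return occurred, review
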