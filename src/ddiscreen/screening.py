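"""Eligibility filtering, drug-pair enumeration and potential-DDI screening.

The case-selection funnel applies, in fixed order: vaccine exclusion,
seriousness, causality ("definite"/"probable"/"possible" by default), and a
minimum drug count. Every surviving report contributes all unordered pairs
of its distinct drug identity keys (suspect and concomitant pooled); each
pair is looked up in the knowledge base and hits become potential DDIs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ddi_kb import DdiRecord, KnowledgeBase, PairKey, Severity, canonical_pair
from .icsr_model import Causality, IcsrReport, ReportSet

__all__ = [
    "EligibilityCriteria",
    "FlowchartCounts",
    "PotentialDdi",
    "CombinationCensus",
    "apply_eligibility_filters",
    "enumerate_pairs",
    "screen_report",
    "screen_reports",
    "combination_census",
    "ddi_rate_by_polypharmacy",
    "POLYPHARMACY_STRATA",
]

DEFAULT_CAUSALITY = frozenset(
    {Causality.definite, Causality.probable, Causality.possible}
)


@dataclass(frozen=True)
class EligibilityCriteria:
    """Case-selection rules for the serious multi-drug analysis set."""

    require_serious: bool = True
    exclude_vaccines: bool = True
    allowed_causality: frozenset[Causality] = DEFAULT_CAUSALITY
    min_drugs: int = 2

    def __post_init__(self) -> None:
        if self.min_drugs < 2:
            raise ValueError("min_drugs must be >= 2 for a pair analysis")


@dataclass(frozen=True)
class FlowchartCounts:
    """Case-selection funnel counts.

    ``eligible_serious`` is the count after the vaccine, seriousness and
    causality exclusions; removing single-drug reports leaves the analyzed
    multi-drug set: analyzed_multidrug = eligible_serious - excluded_single_drug.
    """

    total: int
    excluded_vaccine: int
    excluded_nonserious: int
    excluded_causality: int
    eligible_serious: int
    excluded_single_drug: int
    analyzed_multidrug: int

    def __post_init__(self) -> None:
        counts = self.__dict__.values()
        if any(c < 0 for c in counts):
            raise ValueError("flowchart counts must be nonnegative")
        if (
            self.eligible_serious
            != self.total
            - self.excluded_vaccine
            - self.excluded_nonserious
            - self.excluded_causality
        ):
            raise ValueError("eligible_serious inconsistent with exclusions")
        if self.analyzed_multidrug != self.eligible_serious - self.excluded_single_drug:
            raise ValueError(
                "analyzed_multidrug must equal eligible_serious - excluded_single_drug"
            )

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class PotentialDdi:
    """A report's drug pair found in the knowledge base."""

    report_id: str
    pair: PairKey
    severity: Severity
    record: DdiRecord


@dataclass(frozen=True)
class CombinationCensus:
    """Counts over all (report, pair) combinations in the analyzed set.

    ``pair_instances`` counts per-report pair occurrences (one report with
    d distinct drugs contributes C(d, 2)); ``distinct_pairs`` counts unique
    pair keys across reports. Both senses of "combinations" are exposed.
    """

    pair_instances: int
    distinct_pairs: int
    potential_instances: int
    distinct_potential_pairs: int
    severity_breakdown: dict[Severity, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.potential_instances > self.pair_instances:
            raise ValueError("potential_instances cannot exceed pair_instances")
        if sum(self.severity_breakdown.values()) != self.potential_instances:
            raise ValueError("severity_breakdown must partition potential_instances")


def apply_eligibility_filters(
    reports: ReportSet, criteria: EligibilityCriteria = EligibilityCriteria()
) -> tuple[ReportSet, FlowchartCounts]:
    """Apply the case-selection funnel in fixed order:
    vaccine -> seriousness -> causality -> drug count."""
    total = len(reports)
    stage = list(reports)

    if criteria.exclude_vaccines:
        kept = [r for r in stage if not r.is_vaccine]
    else:
        kept = stage
    excluded_vaccine = len(stage) - len(kept)
    stage = kept

    if criteria.require_serious:
        kept = [r for r in stage if r.serious]
    else:
        kept = stage
    excluded_nonserious = len(stage) - len(kept)
    stage = kept

    kept = [r for r in stage if r.causality in criteria.allowed_causality]
    excluded_causality = len(stage) - len(kept)
    stage = kept

    eligible_serious = len(stage)
    kept = [r for r in stage if len(r.distinct_drug_keys()) >= criteria.min_drugs]
    excluded_single_drug = eligible_serious - len(kept)

    counts = FlowchartCounts(
        total=total,
        excluded_vaccine=excluded_vaccine,
        excluded_nonserious=excluded_nonserious,
        excluded_causality=excluded_causality,
        eligible_serious=eligible_serious,
        excluded_single_drug=excluded_single_drug,
        analyzed_multidrug=len(kept),
    )
    return ReportSet(reports=tuple(kept), provenance=reports.provenance), counts


def enumerate_pairs(report: IcsrReport) -> list[PairKey]:
    """All unordered pairs of the report's distinct drug identity keys.

    Suspect and concomitant drugs are pooled; duplicate mentions of one
    substance collapse before pairing, so a report with d distinct keys
    yields exactly C(d, 2) pairs. Fewer than two distinct drugs yields [].
    """
    keys = report.distinct_drug_keys()
    return [canonical_pair(a, b) for a, b in combinations(sorted(keys), 2)]


def screen_report(report: IcsrReport, kb: KnowledgeBase) -> list[PotentialDdi]:
    """Potential DDIs for one report: enumerated pairs with a KB hit."""
    out = []
    for pair in enumerate_pairs(report):
        rec = kb.get(pair)
        if rec is not None:
            out.append(
                PotentialDdi(
                    report_id=report.report_id,
                    pair=pair,
                    severity=rec.severity,
                    record=rec,
                )
            )
    return out


def screen_reports(
    reports: Iterable[IcsrReport], kb: KnowledgeBase
) -> dict[str, list[PotentialDdi]]:
    """Screen every report; map report_id -> its potential DDIs (possibly [])."""
    return {r.report_id: screen_report(r, kb) for r in reports}


def combination_census(
    reports: Sequence[IcsrReport], potentials: dict[str, list[PotentialDdi]]
) -> CombinationCensus:
    """Census of pair combinations and KB hits over the analyzed set."""
    pair_instances = 0
    distinct: set[PairKey] = set()
    distinct_hits: set[PairKey] = set()
    breakdown: Counter[Severity] = Counter()
    n_potential = 0
    for r in reports:
        pairs = enumerate_pairs(r)
        pair_instances += len(pairs)
        distinct.update(pairs)
        for p in potentials.get(r.report_id, []):
            n_potential += 1
            distinct_hits.add(p.pair)
            breakdown[p.severity] += 1
    return CombinationCensus(
        pair_instances=pair_instances,
        distinct_pairs=len(distinct),
        potential_instances=n_potential,
        distinct_potential_pairs=len(distinct_hits),
        severity_breakdown=dict(breakdown),
    )


POLYPHARMACY_STRATA = ("2", "3", "4", "5", "6", "7", "8+")


def _stratum(d: int) -> Optional[str]:
    if d < 2:
        return None
    return str(d) if d <= 7 else "8+"


def ddi_rate_by_polypharmacy(
    reports: Sequence[IcsrReport], potentials: dict[str, list[PotentialDdi]]
) -> pd.DataFrame:
    """Share of reports with >=1 potential DDI, by distinct-drug-count stratum.

    Strata are 2..7 and "8+". Returns a DataFrame with columns
    ``stratum, n_reports, n_with_ddi, pct_with_ddi``; an empty stratum has
    n_reports=0 and NaN rate.
    """
    from .characterization import round_pct

    n: Counter[str] = Counter()
    hits: Counter[str] = Counter()
    for r in reports:
        s = _stratum(len(r.distinct_drug_keys()))
        if s is None:
            continue
        n[s] += 1
        if potentials.get(r.report_id):
            hits[s] += 1
    rows = []
    for s in POLYPHARMACY_STRATA:
        rows.append(
            {
                "stratum": s,
                "n_reports": n[s],
                "n_with_ddi": hits[s],
                "pct_with_ddi": round_pct(hits[s] / n[s]) if n[s] else float("nan"),
            }
        )
    return pd.DataFrame(rows)
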