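"""Synthetic ICSR datasets with known ground truth.

The generator emulates the statistical structure of a regional spontaneous
reporting database: an elderly-skewed age mixture, female-majority sex
ratio, physician-dominated reporter mix, a long-tailed per-report drug
count, vaccine and non-serious strata, and a drug-pair knowledge base in
which a configurable fraction of repertoire pairs interact. Reports whose
drugs contain a knowledge-base pair receive, with conditional probability
``p_concordant``, a reaction term drawn from that pair's effect-term set —
planting an *occurred* DDI whose group label is known by construction.

Planted effect terms (prefix ``IX_``) are unique per pair and disjoint from
the background reaction vocabulary (prefix ``BG_``), so pipeline recovery of
the planted group labels is exact; see the recovery utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .characterization import GroupLabel
from .ddi_kb import DdiRecord, KnowledgeBase, PairKey, Severity, canonical_pair
from .icsr_model import (
    Causality,
    DrugEntry,
    DrugRole,
    IcsrReport,
    ReactionEntry,
    Reporter,
    ReportSet,
    SeriousnessCriterion,
    Sex,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "TruthRecord",
    "RecoveryReport",
    "generate_kb",
    "generate_reports",
    "recovery_check",
]

_ATC_LETTERS = "ABCDGHLMNPRSV"  # anatomical main groups, excluding J (J07 = vaccines)


def _default_drug_count_probs() -> dict[int, float]:
    # long-tailed polytherapy: ~45% single-drug among all reports, tail to 12
    raw = {
        1: 0.45, 2: 0.12, 3: 0.10, 4: 0.08, 5: 0.06, 6: 0.05,
        7: 0.04, 8: 0.03, 9: 0.025, 10: 0.02, 11: 0.015, 12: 0.01,
    }
    z = sum(raw.values())
    return {k: v / z for k, v in raw.items()}


def _default_causality_probs() -> dict[Causality, float]:
    return {
        Causality.definite: 0.05,
        Causality.probable: 0.45,
        Causality.possible: 0.44,
        Causality.unlikely: 0.03,
        Causality.unassessable: 0.02,
        Causality.unknown: 0.01,
    }


def _default_reporter_probs() -> dict[Reporter, float]:
    return {
        Reporter.physician: 0.87,
        Reporter.pharmacist: 0.04,
        Reporter.other_hcp: 0.05,
        Reporter.citizen: 0.03,
        Reporter.unknown: 0.01,
    }


def _default_severity_probs() -> dict[Severity, float]:
    # mirrors the skew of compendium hits toward major interactions
    return {
        Severity.major: 0.638,
        Severity.moderate: 0.325,
        Severity.minor: 0.023,
        Severity.contraindicated: 0.014,
    }


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters. Probabilities are in [0, 1]; categorical
    distributions are normalized on construction."""

    n_reports: int = 1000
    n_drugs: int = 40
    p_atc_missing: float = 0.05
    drug_count_probs: dict[int, float] = field(
        default_factory=_default_drug_count_probs
    )
    fraction_vaccine: float = 0.10
    fraction_serious: float = 0.50
    causality_probs: dict[Causality, float] = field(
        default_factory=_default_causality_probs
    )
    # age: two-component normal mixture emphasizing the elderly
    age_young_mean: float = 40.0
    age_young_sd: float = 13.0
    age_old_mean: float = 72.0
    age_old_sd: float = 12.0
    age_old_weight: float = 0.80
    p_age_missing: float = 0.02
    p_female: float = 0.56
    p_sex_unknown: float = 0.01
    reporter_probs: dict[Reporter, float] = field(
        default_factory=_default_reporter_probs
    )
    kb_pair_density: float = 0.12
    severity_probs: dict[Severity, float] = field(
        default_factory=_default_severity_probs
    )
    p_concordant: float = 0.30
    p_fatal_given_occurred: float = 0.045
    p_fatal_base: float = 0.035
    p_both_suspect: float = 0.28
    p_flagged_given_both_suspect: float = 0.66
    p_suspect_role: float = 0.40
    n_background_terms: int = 60

    def __post_init__(self) -> None:
        probs = [
            self.p_atc_missing, self.fraction_vaccine, self.fraction_serious,
            self.kb_pair_density, self.p_concordant, self.p_fatal_given_occurred,
            self.p_fatal_base, self.p_both_suspect,
            self.p_flagged_given_both_suspect, self.p_suspect_role,
            self.p_age_missing, self.p_female, self.p_sex_unknown,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for name in ("drug_count_probs", "causality_probs", "reporter_probs",
                     "severity_probs"):
            d = getattr(self, name)
            z = sum(d.values())
            if z <= 0:
                raise ValueError(f"{name} must have positive mass")
            object.__setattr__(self, name, {k: v / z for k, v in d.items()})


@dataclass(frozen=True)
class TruthRecord:
    """Planted facts for one generated report."""

    report_id: str
    eligible: bool
    potential_pairs: tuple[PairKey, ...]
    concordant_pairs: tuple[PairKey, ...]
    intended_group: Optional[GroupLabel]


@dataclass
class GroundTruth:
    """Per-report planted structure; consistent with the emitted reports by
    construction."""

    records: dict[str, TruthRecord]

    def intended_groups(self) -> dict[str, GroupLabel]:
        return {
            rid: t.intended_group
            for rid, t in self.records.items()
            if t.intended_group is not None
        }


def _drug_catalog(config: SimConfig) -> list[tuple[str, Optional[str]]]:
    """Deterministic repertoire of (substance, atc) pairs. ATC codes follow
    the grammar and avoid the vaccine group."""
    catalog = []
    for i in range(config.n_drugs):
        name = f"DRUG{i:03d}"
        letter = _ATC_LETTERS[i % len(_ATC_LETTERS)]
        atc = f"{letter}{(i // len(_ATC_LETTERS)) % 100:02d}AB{i % 100:02d}"
        catalog.append((name, atc))
    return catalog


def _identity_keys(config: SimConfig) -> list[str]:
    # identity key = level-5 ATC (always present in the catalog)
    return [atc for _, atc in _drug_catalog(config)]


def generate_kb(config: SimConfig, seed: int) -> KnowledgeBase:
    """Random pair-based KB over the drug repertoire.

    Each of the C(n_drugs, 2) repertoire pairs is included independently
    with probability ``kb_pair_density``; severity follows
    ``severity_probs``; each record gets two pair-specific effect terms
    (prefix ``IX_``). Deterministic given the seed.
    """
    if config.n_drugs < 2:
        raise ValueError("need a repertoire of at least 2 drugs")
    rng = np.random.default_rng([int(seed), 1])
    keys = _identity_keys(config)
    sev_items = sorted(config.severity_probs.items(), key=lambda kv: kv[0].name)
    sev_values = [s for s, _ in sev_items]
    sev_probs = [p for _, p in sev_items]
    kb = KnowledgeBase(version_label=f"synthetic-kb-seed{seed}")
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if rng.random() < config.kb_pair_density:
                pair = canonical_pair(keys[i], keys[j])
                sev = sev_values[rng.choice(len(sev_values), p=sev_probs)]
                terms = frozenset(
                    {f"IX_{pair.first}_{pair.second}_A", f"IX_{pair.first}_{pair.second}_B"}
                )
                kb.add(
                    DdiRecord(
                        pair=pair,
                        severity=sev,
                        effect_text=f"synthetic interaction effect of {pair}",
                        effect_terms=terms,
                    )
                )
    return kb


def _sample_categorical(rng: np.random.Generator, probs: dict) -> object:
    items = list(probs.items())
    idx = rng.choice(len(items), p=[p for _, p in items])
    return items[idx][0]


def _sample_age(rng: np.random.Generator, c: SimConfig) -> Optional[float]:
    if rng.random() < c.p_age_missing:
        return None
    if rng.random() < c.age_old_weight:
        a = rng.normal(c.age_old_mean, c.age_old_sd)
    else:
        a = rng.normal(c.age_young_mean, c.age_young_sd)
    return float(np.clip(round(a, 1), 0.0, 105.0))


def _eligible(r: IcsrReport) -> bool:
    return (
        not r.is_vaccine
        and r.serious
        and r.causality in (Causality.definite, Causality.probable, Causality.possible)
        and len(r.distinct_drug_keys()) >= 2
    )


def generate_reports(
    config: SimConfig, kb: KnowledgeBase, seed: int
) -> tuple[ReportSet, GroundTruth]:
    """Generate a report set with planted potential and occurred DDIs.

    One root seed governs a counter-based substream per report (the i-th
    report draws from ``default_rng([seed, 2, i])``), so output is
    reproducible independent of generation order. Every planted concordant
    pair's report contains a reaction term from that pair's effect-term set.
    """
    if config.p_concordant > 0 and len(kb) == 0:
        raise ValueError("p_concordant > 0 requires a non-empty knowledge base")
    catalog = _drug_catalog(config)
    counts = sorted(config.drug_count_probs.items())
    count_values = [k for k, _ in counts]
    count_probs = [p for _, p in counts]
    reports: list[IcsrReport] = []
    truth: dict[str, TruthRecord] = {}

    for i in range(config.n_reports):
        rng = np.random.default_rng([int(seed), 2, i])
        rid = f"R{i:06d}"
        is_vaccine = rng.random() < config.fraction_vaccine
        serious = rng.random() < config.fraction_serious
        causality = _sample_categorical(rng, config.causality_probs)
        age = _sample_age(rng, config)
        u = rng.random()
        if u < config.p_sex_unknown:
            sex = Sex.unknown
        elif u < config.p_sex_unknown + config.p_female:
            sex = Sex.female
        else:
            sex = Sex.male
        reporter = _sample_categorical(rng, config.reporter_probs)

        n_drugs = count_values[rng.choice(len(count_values), p=count_probs)]
        n_drugs = min(n_drugs, config.n_drugs)
        picked = rng.choice(len(catalog), size=n_drugs, replace=False)
        chosen = [catalog[j] for j in sorted(picked)]
        roles = {
            atc: (
                DrugRole.suspect
                if rng.random() < config.p_suspect_role
                else DrugRole.concomitant
            )
            for _, atc in chosen
        }
        if DrugRole.suspect not in roles.values():
            roles[chosen[0][1]] = DrugRole.suspect
        flagged: dict[str, bool] = {atc: False for _, atc in chosen}

        # planted structure: KB pairs among the chosen drugs
        keys = [atc for _, atc in chosen]
        potential = [
            canonical_pair(keys[a], keys[b])
            for a in range(len(keys))
            for b in range(a + 1, len(keys))
        ]
        potential = [p for p in potential if p in kb]

        reactions: list[ReactionEntry] = []
        concordant: tuple[PairKey, ...] = ()
        if potential and rng.random() < config.p_concordant:
            pick = potential[rng.choice(len(potential))]
            rec = kb.get(pick)
            term = sorted(rec.effect_terms)[rng.choice(len(rec.effect_terms))]
            reactions.append(ReactionEntry(term_code=term))
            concordant = (pick,)
            if rng.random() < config.p_both_suspect:
                roles[pick.first] = DrugRole.suspect
                roles[pick.second] = DrugRole.suspect
                if rng.random() < config.p_flagged_given_both_suspect:
                    flagged[pick.first] = True
                    flagged[pick.second] = True
            else:
                # reporter missed the interaction: keep at most one suspect
                roles[pick.second] = DrugRole.concomitant
                if DrugRole.suspect not in roles.values():
                    roles[chosen[0][1]] = DrugRole.suspect

        n_bg = 1 + int(rng.choice(3))
        for _ in range(n_bg):
            reactions.append(
                ReactionEntry(
                    term_code=f"BG_{int(rng.choice(config.n_background_terms)):03d}"
                )
            )

        p_fatal = (
            config.p_fatal_given_occurred if concordant else config.p_fatal_base
        )
        fatal = serious and rng.random() < p_fatal
        criteria: set[SeriousnessCriterion] = set()
        if serious:
            criteria.add(
                _sample_categorical(
                    rng,
                    {
                        SeriousnessCriterion.hospitalization: 0.55,
                        SeriousnessCriterion.other_medically_important: 0.25,
                        SeriousnessCriterion.life_threatening: 0.12,
                        SeriousnessCriterion.disability: 0.05,
                        SeriousnessCriterion.congenital_anomaly: 0.03,
                    },
                )
            )
            if fatal:
                criteria.add(SeriousnessCriterion.death)

        drugs = tuple(
            DrugEntry(
                substance_id=name,
                atc_code=atc,
                role=roles[atc],
                flagged_interacting=flagged[atc],
            )
            for name, atc in chosen
        )
        report = IcsrReport(
            report_id=rid,
            age_years=age,
            sex=sex,
            reporter=reporter,
            serious=serious,
            seriousness_criteria=frozenset(criteria),
            causality=causality,
            is_vaccine_report=is_vaccine,
            drugs=drugs,
            reactions=tuple(reactions),
            ddi_flagged=any(flagged.values()),
        )
        reports.append(report)

        eligible = _eligible(report)
        if not eligible:
            intended = None
        elif concordant:
            intended = GroupLabel.A
        elif potential:
            intended = GroupLabel.B
        else:
            intended = GroupLabel.C
        truth[rid] = TruthRecord(
            report_id=rid,
            eligible=eligible,
            potential_pairs=tuple(potential),
            concordant_pairs=concordant,
            intended_group=intended,
        )

    return (
        ReportSet(reports=tuple(reports), provenance=f"synthetic-seed{seed}"),
        GroundTruth(records=truth),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Agreement between pipeline group labels and the planted truth."""

    n_compared: int
    n_agree: int
    confusion: dict[tuple[str, str], int]
    intended_occurred_rate: Optional[float]
    recovered_occurred_rate: Optional[float]

    @property
    def agreement(self) -> float:
        return self.n_agree / self.n_compared if self.n_compared else float("nan")

    @property
    def rate_abs_error(self) -> Optional[float]:
        if self.intended_occurred_rate is None or self.recovered_occurred_rate is None:
            return None
        return abs(self.intended_occurred_rate - self.recovered_occurred_rate)


def recovery_check(
    observed: Mapping[str, GroupLabel], truth: GroundTruth
) -> RecoveryReport:
    """Compare pipeline group labels with the planted labels.

    ``observed`` must cover exactly the eligible reports in the truth.
    The occurred/exposed rate is the share of potential-DDI-exposed reports
    (groups A+B) labelled A.
    """
    intended = truth.intended_groups()
    if set(observed) != set(intended):
        missing = set(intended) ^ set(observed)
        raise ValueError(
            f"observed labels do not match eligible truth reports "
            f"({len(missing)} ids differ)"
        )
    confusion: dict[tuple[str, str], int] = {}
    n_agree = 0
    for rid, want in intended.items():
        got = observed[rid]
        confusion[(want.value, got.value)] = (
            confusion.get((want.value, got.value), 0) + 1
        )
        if got is want:
            n_agree += 1

    def rate(labels: Mapping[str, GroupLabel]) -> Optional[float]:
        exposed = [l for l in labels.values() if l in (GroupLabel.A, GroupLabel.B)]
        if not exposed:
            return None
        return sum(1 for l in exposed if l is GroupLabel.A) / len(exposed)

    return RecoveryReport(
        n_compared=len(intended),
        n_agree=n_agree,
        confusion=confusion,
        intended_occurred_rate=rate(intended),
        recovered_occurred_rate=rate(observed),
    )
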