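"""Group partition and descriptive statistics for the analyzed report set.

Reports with at least two drugs are partitioned into three groups:

* **A** — at least one *occurred* DDI (the reported reaction matches a
  listed interaction effect);
* **B** — at least one *potential* DDI but none occurred;
* **C** — no listed interaction among the drug pairs.

Group summaries use the Wilson score interval (no continuity correction)
for proportions and the t interval for means; printed percentages are
rounded half-away-from-zero to one decimal, with full precision kept
internally.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import OccurredDdi
from .icsr_model import IcsrReport, Reporter, Sex
from .screening import PotentialDdi, Severity

__all__ = [
    "GroupLabel",
    "ProportionCI",
    "MeanCI",
    "SummaryTable",
    "assign_group",
    "assign_groups",
    "wilson_ci",
    "mean_ci",
    "round_pct",
    "group_summary",
    "pair_frequency",
    "class_frequency",
    "recognition_rates",
    "AGE_BANDS",
]


class GroupLabel(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"


def round_pct(x: float) -> float:
    """100*x rounded half-away-from-zero to one decimal.

    Accepts any real (differences may be negative); this is presentation
    rounding only — keep full precision in intermediate arithmetic.
    """
    return float(
        Decimal(repr(100.0 * float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its two-sided score interval, in percent."""

    k: int
    n: int
    point_pct: float
    low_pct: float
    high_pct: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")
        if not (
            0.0 <= self.low_pct <= self.point_pct <= self.high_pct <= 100.0
        ):
            raise ValueError("interval must bracket the point estimate in [0, 100]")

    def __str__(self) -> str:
        return f"{self.point_pct} ({self.low_pct}–{self.high_pct})"


@dataclass(frozen=True)
class MeanCI:
    """A sample mean with its two-sided t interval."""

    n: int
    mean: float
    low: float
    high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValueError("interval must bracket the mean")

    def __str__(self) -> str:
        return f"{self.mean:.1f} ({self.low:.1f}–{self.high:.1f})"


def wilson_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Two-sided Wilson score interval for a binomial proportion.

    The score interval inverts the normal test of H0: p = p0 at the given
    level; unlike the Wald interval it stays inside [0, 1] and behaves well
    at small counts. No continuity correction. Bounds are reported in
    percent, rounded to one decimal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = p + z * z / (2.0 * n)
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    low = (centre - half) / denom
    high = (centre + half) / denom
    return ProportionCI(
        k=k,
        n=n,
        point_pct=round_pct(p),
        low_pct=round_pct(max(low, 0.0)),
        high_pct=round_pct(min(high, 1.0)),
        level=level,
    )


def mean_ci(values: Sequence[float], level: float = 0.95) -> MeanCI:
    """Two-sided t-based confidence interval for the mean of a sample."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError("mean_ci needs at least two values")
    m = float(np.mean(x))
    sem = float(stats.sem(x))
    if sem == 0.0:
        return MeanCI(n=n, mean=m, low=m, high=m, level=level)
    low, high = stats.t.interval(level, df=n - 1, loc=m, scale=sem)
    return MeanCI(n=n, mean=m, low=float(low), high=float(high), level=level)


def assign_group(
    report_id: str,
    potentials: Mapping[str, Sequence[PotentialDdi]],
    occurred: Mapping[str, Sequence[OccurredDdi]],
) -> GroupLabel:
    """Group label for one analyzed report.

    The report must appear in the screening output (``potentials`` maps every
    analyzed report id, possibly to an empty list).
    """
    if report_id not in potentials:
        raise KeyError(f"report {report_id!r} absent from screening output")
    if occurred.get(report_id):
        return GroupLabel.A
    if potentials[report_id]:
        return GroupLabel.B
    return GroupLabel.C


def assign_groups(
    reports: Sequence[IcsrReport],
    potentials: Mapping[str, Sequence[PotentialDdi]],
    occurred: Mapping[str, Sequence[OccurredDdi]],
) -> dict[str, GroupLabel]:
    return {
        r.report_id: assign_group(r.report_id, potentials, occurred) for r in reports
    }


AGE_BANDS = (("18-44", 18.0, 44.0), ("45-64", 45.0, 64.0), (">64", 64.0, math.inf))


def _age_band(age: Optional[float]) -> Optional[str]:
    if age is None:
        return None
    for name, lo, hi in AGE_BANDS:
        if name == ">64":
            if age > lo:
                return name
        elif lo <= age <= hi:
            return name
    return None


@dataclass
class GroupSummary:
    """Descriptive cells for one group; ``None`` marks an undefined cell."""

    n: int
    age_mean: Optional[MeanCI]
    age_median: Optional[float]
    male: Optional[ProportionCI]
    reporter_source: dict[str, Optional[ProportionCI]]
    fatal: Optional[ProportionCI]
    drug_count_mean: Optional[MeanCI]
    contra_major_pct: Optional[ProportionCI]
    drug_count_by_sex_age: dict[tuple[str, str], Optional[float]]


@dataclass
class SummaryTable:
    """Per-group characterization of the analyzed set."""

    groups: dict[GroupLabel, GroupSummary]
    analyzed_n: int

    def __post_init__(self) -> None:
        if sum(g.n for g in self.groups.values()) != self.analyzed_n:
            raise ValueError("group sizes must sum to the analyzed set size")

    def to_frame(self) -> pd.DataFrame:
        """Flat presentation table, one column per group."""
        rows: dict[str, dict[str, str]] = {}

        def put(row: str, label: GroupLabel, cell: object) -> None:
            rows.setdefault(row, {})[f"Group {label.value}"] = (
                "undefined" if cell is None else str(cell)
            )

        for label, g in self.groups.items():
            put("n", label, g.n)
            put("age_mean_ci", label, g.age_mean)
            put(
                "age_median",
                label,
                None if g.age_median is None else f"{g.age_median:.1f}",
            )
            put("male_pct_ci", label, g.male)
            for src, ci in g.reporter_source.items():
                put(f"reporter_{src}_pct_ci", label, ci)
            put("fatal_pct_ci", label, g.fatal)
            put("drug_count_mean_ci", label, g.drug_count_mean)
            put("contra_major_pct_ci", label, g.contra_major_pct)
            for (sex, band), v in g.drug_count_by_sex_age.items():
                put(
                    f"mean_drugs_{sex}_{band}",
                    label,
                    None if v is None else f"{v:.1f}",
                )
        return pd.DataFrame(rows).T


_REPORTER_SOURCES = (
    Reporter.physician,
    Reporter.pharmacist,
    Reporter.other_hcp,
    Reporter.citizen,
)


def _summarize_group(
    members: list[IcsrReport],
    potentials: Mapping[str, Sequence[PotentialDdi]],
    label: GroupLabel,
    level: float,
) -> GroupSummary:
    n = len(members)
    if n == 0:
        return GroupSummary(
            n=0,
            age_mean=None,
            age_median=None,
            male=None,
            reporter_source={s.value: None for s in _REPORTER_SOURCES},
            fatal=None,
            drug_count_mean=None,
            contra_major_pct=None,
            drug_count_by_sex_age={},
        )
    ages = [r.age_years for r in members if r.age_years is not None]
    sexes = [r for r in members if r.sex is not Sex.unknown]
    n_male = sum(1 for r in sexes if r.sex is Sex.male)
    drug_counts = [len(r.distinct_drug_keys()) for r in members]

    # contraindicated+major share over the group's potential-DDI instances
    group_pots = [p for r in members for p in potentials.get(r.report_id, [])]
    contra_major: Optional[ProportionCI] = None
    if label in (GroupLabel.A, GroupLabel.B) and group_pots:
        k_cm = sum(
            1
            for p in group_pots
            if p.severity in (Severity.contraindicated, Severity.major)
        )
        contra_major = wilson_ci(k_cm, len(group_pots), level)

    by_sex_age: dict[tuple[str, str], Optional[float]] = {}
    for sex in (Sex.male, Sex.female):
        for band, _, _ in AGE_BANDS:
            vals = [
                len(r.distinct_drug_keys())
                for r in members
                if r.sex is sex and _age_band(r.age_years) == band
            ]
            by_sex_age[(sex.value, band)] = (
                float(np.mean(vals)) if vals else None
            )

    return GroupSummary(
        n=n,
        age_mean=mean_ci(ages, level) if len(ages) >= 2 else None,
        age_median=float(np.median(ages)) if ages else None,
        male=wilson_ci(n_male, len(sexes), level) if sexes else None,
        reporter_source={
            s.value: wilson_ci(
                sum(1 for r in members if r.reporter is s), n, level
            )
            for s in _REPORTER_SOURCES
        },
        fatal=wilson_ci(sum(1 for r in members if r.is_fatal), n, level),
        drug_count_mean=mean_ci(drug_counts, level) if n >= 2 else None,
        contra_major_pct=contra_major,
        drug_count_by_sex_age=by_sex_age,
    )


def group_summary(
    reports: Sequence[IcsrReport],
    labels: Mapping[str, GroupLabel],
    potentials: Mapping[str, Sequence[PotentialDdi]],
    level: float = 0.95,
) -> SummaryTable:
    """Per-group characterization table.

    Missing age/sex are excluded pairwise from the affected cells (their
    reports still count toward n). Empty groups get undefined cells.
    """
    groups: dict[GroupLabel, GroupSummary] = {}
    for label in GroupLabel:
        members = [r for r in reports if labels[r.report_id] is label]
        groups[label] = _summarize_group(members, potentials, label, level)
    return SummaryTable(groups=groups, analyzed_n=len(reports))


def pair_frequency(
    occurred: Mapping[str, Sequence[OccurredDdi]],
    min_reports: int = 1,
    top_terms: int = 6,
) -> pd.DataFrame:
    """Ranked table of drug pairs among occurred DDIs.

    One row per pair with >= ``min_reports`` reports: report count, the most
    frequently matched reaction terms (with per-report counts), and the
    reporter-recognition counts (both drugs suspect; flagged as interacting).
    Ranked by report count descending, ties broken lexicographically by pair.
    """
    per_pair: dict[str, dict] = {}
    for occs in occurred.values():
        for o in occs:
            key = str(o.pair)
            d = per_pair.setdefault(
                key,
                {
                    "pair": key,
                    "reports": set(),
                    "terms": Counter(),
                    "both_suspect": set(),
                    "flagged": set(),
                },
            )
            if o.report_id not in d["reports"]:
                for t in o.matched_terms:
                    d["terms"][t] += 1
            d["reports"].add(o.report_id)
            if o.both_drugs_suspect:
                d["both_suspect"].add(o.report_id)
            if o.flagged_interacting:
                d["flagged"].add(o.report_id)
    rows = []
    for d in per_pair.values():
        n = len(d["reports"])
        if n < min_reports:
            continue
        top = sorted(d["terms"].items(), key=lambda kv: (-kv[1], kv[0]))[:top_terms]
        rows.append(
            {
                "pair": d["pair"],
                "n_reports": n,
                "top_terms": "; ".join(f"{t} ({c})" for t, c in top),
                "n_both_suspect": len(d["both_suspect"]),
                "n_flagged": len(d["flagged"]),
            }
        )
    rows.sort(key=lambda r: (-r["n_reports"], r["pair"]))
    return pd.DataFrame(
        rows, columns=["pair", "n_reports", "top_terms", "n_both_suspect", "n_flagged"]
    )


def class_frequency(
    occurred: Mapping[str, Sequence[OccurredDdi]],
    class_map: Mapping[str, str],
    reports: Sequence[IcsrReport] = (),
    min_reports: int = 1,
) -> pd.DataFrame:
    """Occurred DDIs aggregated by pharmacological class pairs.

    ``class_map`` maps drug identity keys to class labels; unmapped drugs go
    to "UNMAPPED". Reports are counted once per class pair; fatality uses the
    report-level fatal predicate from ``reports``. Rows with >=
    ``min_reports`` reports, ranked by count descending then class pair.
    """
    fatal_ids = {r.report_id for r in reports if r.is_fatal}
    per_class: dict[tuple[str, str], set[str]] = {}
    for occs in occurred.values():
        for o in occs:
            ca = class_map.get(o.pair.first, "UNMAPPED")
            cb = class_map.get(o.pair.second, "UNMAPPED")
            key = tuple(sorted((ca, cb)))
            per_class.setdefault(key, set()).add(o.report_id)
    rows = []
    for (ca, cb), ids in per_class.items():
        n = len(ids)
        if n < min_reports:
            continue
        n_fatal = len(ids & fatal_ids)
        rows.append(
            {
                "class_a": ca,
                "class_b": cb,
                "n_reports": n,
                "n_fatal": n_fatal,
                "fatal_pct": round_pct(n_fatal / n),
            }
        )
    rows.sort(key=lambda r: (-r["n_reports"], r["class_a"], r["class_b"]))
    return pd.DataFrame(
        rows, columns=["class_a", "class_b", "n_reports", "n_fatal", "fatal_pct"]
    )


def recognition_rates(
    occurred: Mapping[str, Sequence[OccurredDdi]]
) -> tuple[Optional[float], Optional[float]]:
    """Reporter-recognition rates over Group A reports.

    Returns ``(pct_both_suspect, pct_flagged)``: the share of reports with at
    least one occurred DDI in which some occurred DDI has both drugs suspect,
    and in which some occurred DDI was flagged as interacting. ``(None, None)``
    when no report has an occurred DDI.
    """
    group_a = [occs for occs in occurred.values() if occs]
    n = len(group_a)
    if n == 0:
        return None, None
    k_suspect = sum(1 for occs in group_a if any(o.both_drugs_suspect for o in occs))
    k_flagged = sum(1 for occs in group_a if any(o.flagged_interacting for o in occs))
    return round_pct(k_suspect / n), round_pct(k_flagged / n)
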