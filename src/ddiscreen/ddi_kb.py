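"""Severity-graded drug-pair interaction knowledge base.

Mirrors the structure of compendium-style DDI references (DRUGDEX-like):
each entry is an unordered drug pair graded at one of four severity levels
(contraindicated > major > moderate > minor) with a free-text description of
the interaction effect and a set of reaction term codes that realise that
effect. Lookup is order-independent; duplicate rows for a pair are merged to
the highest severity with the union of effect terms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "Severity",
    "PairKey",
    "DdiRecord",
    "KnowledgeBase",
    "SelfPairError",
    "canonical_pair",
    "max_severity",
    "load_kb",
    "write_kb",
]

KB_COLUMNS = ["drug_a", "drug_b", "severity", "effect_text", "effect_terms", "mechanism_note"]


class Severity(enum.Enum):
    """Interaction severity, totally ordered: contraindicated > major >
    moderate > minor."""

    minor = 1
    moderate = 2
    major = 3
    contraindicated = 4

    def __lt__(self, other: "Severity") -> bool:
        if not isinstance(other, Severity):
            return NotImplemented
        return self.value < other.value

    def __le__(self, other: "Severity") -> bool:
        if not isinstance(other, Severity):
            return NotImplemented
        return self.value <= other.value

    def __gt__(self, other: "Severity") -> bool:
        return other < self

    def __ge__(self, other: "Severity") -> bool:
        return other <= self

    @classmethod
    def parse(cls, token: str) -> "Severity":
        try:
            return cls[token.strip().lower()]
        except KeyError:
            raise ValueError(
                f"unknown severity token {token!r}; expected one of "
                f"{[s.name for s in cls]}"
            ) from None


class SelfPairError(ValueError):
    """Raised when both members of a pair are the same drug."""


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical unordered drug pair: ``first < second`` lexicographically."""

    first: str
    second: str

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise SelfPairError(f"self-pair {self.first!r}")
        if self.first > self.second:
            raise ValueError("PairKey members out of order; use canonical_pair")

    def __str__(self) -> str:
        return f"{self.first}/{self.second}"


def canonical_pair(a: str, b: str) -> PairKey:
    """Order-independent pair key. ``canonical_pair(a, b) == canonical_pair(b, a)``."""
    a, b = a.strip().upper(), b.strip().upper()
    if not a or not b:
        raise ValueError("drug identity keys must be non-empty")
    if a == b:
        raise SelfPairError(f"self-pair {a!r}")
    return PairKey(*sorted((a, b)))


def max_severity(values: Iterable[Severity]) -> Severity:
    """Supremum of a non-empty collection under the fixed severity order."""
    values = list(values)
    if not values:
        raise ValueError("max_severity of empty collection")
    return max(values)


@dataclass(frozen=True)
class DdiRecord:
    """One merged knowledge-base entry for a drug pair.

    ``effect_terms`` may be empty only when the entry needs human review
    (no machine-matchable realisation of the effect is listed).
    """

    pair: PairKey
    severity: Severity
    effect_text: str = ""
    effect_terms: frozenset[str] = frozenset()
    mechanism_note: Optional[str] = None

    @property
    def needs_review(self) -> bool:
        return not self.effect_terms


@dataclass
class KnowledgeBase:
    """Pair-indexed DDI reference with order-independent lookup."""

    records: dict[PairKey, DdiRecord] = field(default_factory=dict)
    version_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pair: PairKey) -> bool:
        return pair in self.records

    def lookup(self, a: str, b: str) -> Optional[DdiRecord]:
        """The record for the unordered pair {a, b}, or ``None`` if absent."""
        return self.records.get(canonical_pair(a, b))

    def get(self, pair: PairKey) -> Optional[DdiRecord]:
        return self.records.get(pair)

    def add(self, record: DdiRecord) -> None:
        """Insert a record, merging with any existing entry for the pair:
        highest severity wins, effect terms are unioned."""
        old = self.records.get(record.pair)
        if old is None:
            self.records[record.pair] = record
        else:
            # free-text fields chosen independent of row order: the more
            # severe record's text wins, ties broken lexicographically
            ranked = sorted(
                (old, record),
                key=lambda r: (r.severity.value, r.effect_text, r.mechanism_note or ""),
                reverse=True,
            )
            self.records[record.pair] = replace(
                old,
                severity=max_severity([old.severity, record.severity]),
                effect_terms=old.effect_terms | record.effect_terms,
                effect_text=ranked[0].effect_text,
                mechanism_note=ranked[0].mechanism_note,
            )


def lookup(kb: KnowledgeBase, a: str, b: str) -> Optional[DdiRecord]:
    """Module-level alias for :meth:`KnowledgeBase.lookup`."""
    return kb.lookup(a, b)


def _parse_terms(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    return frozenset(t.strip().upper() for t in str(cell).split(";") if t.strip())


def load_kb(path: Union[str, Path], version_label: str = "") -> KnowledgeBase:
    """Load a KB from a tab-separated file.

    Columns: drug_a, drug_b, severity, effect_text, effect_terms
    (semicolon-separated term codes), mechanism_note. Header row required.
    Row errors (unknown severity token, empty drug field, self-pair) raise
    with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("drug_a", "drug_b", "severity") if c not in df.columns]
    if missing:
        raise ValueError(f"KB file {path} missing required columns {missing}")
    kb = KnowledgeBase(version_label=version_label or path.name)
    for idx, row in df.iterrows():
        row_no = idx + 2  # header is line 1
        a, b = row["drug_a"].strip(), row["drug_b"].strip()
        if not a or not b:
            raise ValueError(f"{path}:{row_no}: empty drug field")
        try:
            pair = canonical_pair(a, b)
            sev = Severity.parse(row["severity"])
        except ValueError as exc:
            raise ValueError(f"{path}:{row_no}: {exc}") from None
        kb.add(
            DdiRecord(
                pair=pair,
                severity=sev,
                effect_text=row.get("effect_text", ""),
                effect_terms=_parse_terms(row.get("effect_terms", "")),
                mechanism_note=row.get("mechanism_note") or None,
            )
        )
    return kb


def write_kb(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    """Write a KB as a tab-separated file (inverse of :func:`load_kb`)."""
    rows = []
    for pair in sorted(kb.records):
        rec = kb.records[pair]
        rows.append(
            {
                "drug_a": pair.first,
                "drug_b": pair.second,
                "severity": rec.severity.name,
                "effect_text": rec.effect_text,
                "effect_terms": ";".join(sorted(rec.effect_terms)),
                "mechanism_note": rec.mechanism_note or "",
            }
        )
    pd.DataFrame(rows, columns=KB_COLUMNS).to_csv(path, sep="\t", index=False)
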