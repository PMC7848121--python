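"""Data model and IO for individual case safety reports (ICSRs).

A spontaneous ADR report carries patient demographics, a seriousness
judgement with its criteria, a case-level causality assessment, the drugs
involved (suspect or concomitant, with ATC codes where available) and the
coded reactions (preferred-term-style identifiers). Two on-disk dialects are
supported: JSON lines (one report object per line) and a flat tab-separated
layout with one row per (report x drug x reaction) that is reassembled by
report id.
"""

from __future__ import annotations

import json
import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

__all__ = [
    "DrugRole",
    "Sex",
    "Reporter",
    "Causality",
    "SeriousnessCriterion",
    "DrugEntry",
    "ReactionEntry",
    "IcsrReport",
    "ReportSet",
    "RecordError",
    "validate_report",
    "read_reports",
    "write_reports",
]

ATC_PATTERN = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


class DrugRole(str, Enum):
    suspect = "suspect"
    concomitant = "concomitant"


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Reporter(str, Enum):
    physician = "physician"
    pharmacist = "pharmacist"
    other_hcp = "other_hcp"
    citizen = "citizen"
    unknown = "unknown"


class Causality(str, Enum):
    definite = "definite"
    probable = "probable"
    possible = "possible"
    unlikely = "unlikely"
    unassessable = "unassessable"
    unknown = "unknown"


class SeriousnessCriterion(str, Enum):
    death = "death"
    life_threatening = "life_threatening"
    hospitalization = "hospitalization"
    disability = "disability"
    congenital_anomaly = "congenital_anomaly"
    other_medically_important = "other_medically_important"


class DrugEntry(BaseModel):
    """One drug mentioned in a report.

    ``substance_id`` is a normalised active-substance key (uppercased,
    trimmed). ``atc_code`` is an ATC classification string; level 5 (7
    characters) identifies the substance, shorter prefixes are tolerated.
    ``flagged_interacting`` mirrors the Italian form's *Report's
    Characteristics* drug-interaction flag in this drug's report context.
    """

    model_config = ConfigDict(frozen=True)

    substance_id: str
    atc_code: Optional[str] = None
    role: DrugRole
    flagged_interacting: bool = False

    @field_validator("substance_id", mode="before")
    @classmethod
    def _normalize_substance(cls, v: object) -> str:
        s = str(v).strip().upper() if v is not None else ""
        if not s:
            raise ValueError("substance_id must be non-empty")
        return s

    @field_validator("atc_code", mode="before")
    @classmethod
    def _check_atc(cls, v: object) -> Optional[str]:
        if v is None or v == "":
            return None
        s = str(v).strip().upper()
        if not ATC_PATTERN.match(s):
            raise ValueError(f"atc_code {s!r} does not follow the ATC grammar")
        return s

    @property
    def identity_key(self) -> str:
        """Drug identity used for pairing: level-5 ATC code when present,
        otherwise the normalised substance name."""
        if self.atc_code is not None and len(self.atc_code) == 7:
            return self.atc_code
        return self.substance_id

    @property
    def is_vaccine_coded(self) -> bool:
        """ATC-based vaccine fallback: J07 is the vaccines group."""
        return self.atc_code is not None and self.atc_code.startswith("J07")


class ReactionEntry(BaseModel):
    """One coded reaction (preferred-term-style identifier)."""

    model_config = ConfigDict(frozen=True)

    term_code: str
    fatal_outcome: bool = False

    @field_validator("term_code", mode="before")
    @classmethod
    def _normalize_term(cls, v: object) -> str:
        s = str(v).strip().upper() if v is not None else ""
        if not s:
            raise ValueError("term_code must be non-empty")
        return s


class IcsrReport(BaseModel):
    """One individual case safety report."""

    model_config = ConfigDict(frozen=True)

    report_id: str
    age_years: Optional[float] = None
    sex: Sex = Sex.unknown
    reporter: Reporter = Reporter.unknown
    serious: bool = False
    seriousness_criteria: frozenset[SeriousnessCriterion] = frozenset()
    causality: Causality = Causality.unknown
    is_vaccine_report: bool = False
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[ReactionEntry, ...] = ()
    ddi_flagged: bool = False

    @field_validator("report_id", mode="before")
    @classmethod
    def _check_id(cls, v: object) -> str:
        s = str(v).strip() if v is not None else ""
        if not s:
            raise ValueError("report_id must be non-empty")
        return s

    @field_validator("age_years")
    @classmethod
    def _check_age(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError("age_years must be nonnegative")
        return v

    @model_validator(mode="after")
    def _check_serious_criteria(self) -> "IcsrReport":
        if self.serious and not self.seriousness_criteria:
            raise ValueError(
                "serious report must carry at least one seriousness criterion"
            )
        return self

    @property
    def is_fatal(self) -> bool:
        """Fatal iff death is among the seriousness criteria or any reaction
        has a fatal outcome."""
        return SeriousnessCriterion.death in self.seriousness_criteria or any(
            r.fatal_outcome for r in self.reactions
        )

    @property
    def is_vaccine(self) -> bool:
        """Explicit vaccine flag, with ATC group J07 as fallback."""
        return self.is_vaccine_report or any(d.is_vaccine_coded for d in self.drugs)

    def distinct_drug_keys(self) -> list[str]:
        """Distinct drug identity keys, first-seen order."""
        seen: dict[str, None] = {}
        for d in self.drugs:
            seen.setdefault(d.identity_key, None)
        return list(seen)


class ReportSet(BaseModel):
    """A collection of reports with unique ids."""

    reports: tuple[IcsrReport, ...] = ()
    provenance: str = ""

    @model_validator(mode="after")
    def _check_unique_ids(self) -> "ReportSet":
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate report_id values: {dupes}")
        return self

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


class RecordError(Exception):
    """A rejected input record, anchored to its source line."""

    def __init__(self, line_no: int, messages: list[str]):
        self.line_no = line_no
        self.messages = messages
        super().__init__(f"line {line_no}: " + "; ".join(messages))


def validate_report(raw: Mapping[str, object]) -> IcsrReport:
    """Build an :class:`IcsrReport` from a parsed field map.

    Raises ``ValueError`` whose message lists *every* violated invariant,
    not only the first.
    """
    try:
        return IcsrReport.model_validate(dict(raw))
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "report"
            msgs.append(f"{loc}: {err['msg']}")
        raise ValueError("; ".join(msgs)) from None


def report_errors(raw: Mapping[str, object]) -> list[str]:
    """All invariant violations for a parsed record; empty if valid."""
    try:
        validate_report(raw)
        return []
    except ValueError as exc:
        return str(exc).split("; ")


# ---------------------------------------------------------------------------
# IO

_REPORT_FIELDS = (
    "report_id",
    "age_years",
    "sex",
    "reporter",
    "serious",
    "seriousness_criteria",
    "causality",
    "is_vaccine_report",
    "ddi_flagged",
)

_DELIM_HEADER = list(_REPORT_FIELDS) + [
    "substance_id",
    "atc_code",
    "role",
    "flagged_interacting",
    "term_code",
    "fatal_outcome",
]


def _report_to_dict(r: IcsrReport) -> dict:
    return {
        "report_id": r.report_id,
        "age_years": r.age_years,
        "sex": r.sex.value,
        "reporter": r.reporter.value,
        "serious": r.serious,
        "seriousness_criteria": sorted(c.value for c in r.seriousness_criteria),
        "causality": r.causality.value,
        "is_vaccine_report": r.is_vaccine_report,
        "ddi_flagged": r.ddi_flagged,
        "drugs": [
            {
                "substance_id": d.substance_id,
                "atc_code": d.atc_code,
                "role": d.role.value,
                "flagged_interacting": d.flagged_interacting,
            }
            for d in r.drugs
        ],
        "reactions": [
            {"term_code": x.term_code, "fatal_outcome": x.fatal_outcome}
            for x in r.reactions
        ],
    }


def _bool(s: str) -> bool:
    return s.strip().lower() in {"1", "true", "t", "yes"}


def read_reports(
    path: Union[str, Path],
    dialect: str = "jsonl",
    *,
    collect_errors: Optional[list[RecordError]] = None,
) -> ReportSet:
    """Read a report file in either dialect.

    Malformed records are rejected individually: each produces a
    :class:`RecordError` appended to ``collect_errors`` (if given) while the
    run continues; with ``collect_errors=None`` the first bad record raises.
    An unreadable file always raises.
    """
    path = Path(path)
    if dialect == "jsonl":
        reports = _read_jsonl(path, collect_errors)
    elif dialect == "delimited":
        reports = _read_delimited(path, collect_errors)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ReportSet(reports=tuple(reports), provenance=str(path))


def _reject(
    line_no: int, messages: list[str], sink: Optional[list[RecordError]]
) -> None:
    err = RecordError(line_no, messages)
    if sink is None:
        raise err
    sink.append(err)


def _read_jsonl(path: Path, sink: Optional[list[RecordError]]) -> list[IcsrReport]:
    reports: list[IcsrReport] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                _reject(line_no, [f"invalid JSON: {exc.msg}"], sink)
                continue
            try:
                reports.append(validate_report(raw))
            except ValueError as exc:
                _reject(line_no, str(exc).split("; "), sink)
    return reports


def _read_delimited(path: Path, sink: Optional[list[RecordError]]) -> list[IcsrReport]:
    # One row per (report x drug x reaction); report-level fields repeated.
    # Rows are grouped by report_id; an invalid group rejects the whole report
    # anchored at its first row.
    groups: dict[str, dict] = {}
    first_line: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            return []
        header = header_line.rstrip("\n").split("\t")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                _reject(line_no, [f"expected {len(header)} columns, got {len(cells)}"], sink)
                continue
            row = dict(zip(header, cells))
            rid = row.get("report_id", "")
            g = groups.setdefault(
                rid,
                {
                    "report_id": rid,
                    "age_years": (
                        float(row["age_years"]) if row.get("age_years") else None
                    ),
                    "sex": row.get("sex", "unknown"),
                    "reporter": row.get("reporter", "unknown"),
                    "serious": _bool(row.get("serious", "")),
                    "seriousness_criteria": [
                        c for c in row.get("seriousness_criteria", "").split(";") if c
                    ],
                    "causality": row.get("causality", "unknown"),
                    "is_vaccine_report": _bool(row.get("is_vaccine_report", "")),
                    "ddi_flagged": _bool(row.get("ddi_flagged", "")),
                    "drugs": [],
                    "reactions": [],
                    "_drug_seen": set(),
                    "_rxn_seen": set(),
                },
            )
            first_line.setdefault(rid, line_no)
            if row.get("substance_id"):
                dkey = (
                    row["substance_id"].strip().upper(),
                    row.get("atc_code") or None,
                    row.get("role", ""),
                    _bool(row.get("flagged_interacting", "")),
                )
                if dkey not in g["_drug_seen"]:
                    g["_drug_seen"].add(dkey)
                    g["drugs"].append(
                        {
                            "substance_id": row["substance_id"],
                            "atc_code": row.get("atc_code") or None,
                            "role": row.get("role", ""),
                            "flagged_interacting": _bool(
                                row.get("flagged_interacting", "")
                            ),
                        }
                    )
            if row.get("term_code"):
                rkey = (
                    row["term_code"].strip().upper(),
                    _bool(row.get("fatal_outcome", "")),
                )
                if rkey not in g["_rxn_seen"]:
                    g["_rxn_seen"].add(rkey)
                    g["reactions"].append(
                        {
                            "term_code": row["term_code"],
                            "fatal_outcome": _bool(row.get("fatal_outcome", "")),
                        }
                    )
    reports: list[IcsrReport] = []
    for rid, g in groups.items():
        g.pop("_drug_seen")
        g.pop("_rxn_seen")
        try:
            reports.append(validate_report(g))
        except ValueError as exc:
            _reject(first_line[rid], str(exc).split("; "), sink)
    return reports


def write_reports(
    reports: Union[ReportSet, Iterable[IcsrReport]],
    path: Union[str, Path],
    dialect: str = "jsonl",
) -> None:
    """Write reports in the chosen dialect (inverse of :func:`read_reports`)."""
    items = list(reports.reports if isinstance(reports, ReportSet) else reports)
    path = Path(path)
    if dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in items:
                fh.write(json.dumps(_report_to_dict(r), sort_keys=True) + "\n")
    elif dialect == "delimited":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_DELIM_HEADER) + "\n")
            for r in items:
                base = [
                    r.report_id,
                    "" if r.age_years is None else repr(r.age_years),
                    r.sex.value,
                    r.reporter.value,
                    str(r.serious).lower(),
                    ";".join(sorted(c.value for c in r.seriousness_criteria)),
                    r.causality.value,
                    str(r.is_vaccine_report).lower(),
                    str(r.ddi_flagged).lower(),
                ]
                drugs = list(r.drugs) or [None]
                rxns = list(r.reactions) or [None]
                for d in drugs:
                    for x in rxns:
                        cells = base + [
                            d.substance_id if d else "",
                            (d.atc_code or "") if d else "",
                            d.role.value if d else "",
                            str(d.flagged_interacting).lower() if d else "",
                            x.term_code if x else "",
                            str(x.fatal_outcome).lower() if x else "",
                        ]
                        fh.write("\t".join(cells) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
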