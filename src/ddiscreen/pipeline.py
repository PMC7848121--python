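"""End-to-end orchestration: screen -> assess -> summarize, with a run
manifest accounting for every record."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .characterization import (
    GroupLabel,
    assign_groups,
    class_frequency,
    group_summary,
    pair_frequency,
    recognition_rates,
)
from .concordance import assess_reports
from .ddi_kb import KnowledgeBase, load_kb
from .icsr_model import RecordError, ReportSet, read_reports
from .screening import (
    CombinationCensus,
    EligibilityCriteria,
    FlowchartCounts,
    apply_eligibility_filters,
    combination_census,
    ddi_rate_by_polypharmacy,
    screen_reports,
)

__all__ = ["PipelineResult", "RunManifest", "run_pipeline", "run_analysis"]


@dataclass
class RunManifest:
    """Provenance record emitted with every run."""

    tool_version: str
    report_path: str
    kb_path: str
    kb_version: str
    criteria: dict
    seed: Optional[int]
    records_read: int
    records_rejected: int
    flowchart: dict
    n_potential_instances: int
    n_occurred_instances: int
    n_review_items: int
    group_sizes: dict

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory artifacts of a full analysis run."""

    analyzed: ReportSet
    flowchart: FlowchartCounts
    potentials: dict
    occurred: dict
    review: list
    labels: dict
    census: CombinationCensus
    summary: object
    pair_table: pd.DataFrame
    class_table: Optional[pd.DataFrame]
    strata: pd.DataFrame
    recognition: tuple
    manifest: RunManifest


def run_analysis(
    reports: ReportSet,
    kb: KnowledgeBase,
    criteria: EligibilityCriteria = EligibilityCriteria(),
    class_map: Optional[dict] = None,
    min_reports: int = 1,
    ci_level: float = 0.95,
    *,
    records_rejected: int = 0,
    report_path: str = "",
    kb_path: str = "",
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    analyzed, flow = apply_eligibility_filters(reports, criteria)
    potentials = screen_reports(analyzed, kb)
    occurred, review = assess_reports(analyzed, potentials)
    labels = assign_groups(list(analyzed), potentials, occurred)
    census = combination_census(list(analyzed), potentials)
    summary = group_summary(list(analyzed), labels, potentials, ci_level)
    pair_table = pair_frequency(occurred, min_reports=min_reports)
    class_table = (
        class_frequency(occurred, class_map, list(analyzed), min_reports=min_reports)
        if class_map
        else None
    )
    strata = ddi_rate_by_polypharmacy(list(analyzed), potentials)
    recog = recognition_rates(occurred)
    sizes = {g.value: sum(1 for v in labels.values() if v is g) for g in GroupLabel}
    manifest = RunManifest(
        tool_version=__version__,
        report_path=report_path,
        kb_path=kb_path,
        kb_version=kb.version_label,
        criteria={
            "require_serious": criteria.require_serious,
            "exclude_vaccines": criteria.exclude_vaccines,
            "allowed_causality": sorted(c.value for c in criteria.allowed_causality),
            "min_drugs": criteria.min_drugs,
        },
        seed=seed,
        records_read=len(reports),
        records_rejected=records_rejected,
        flowchart=flow.to_dict(),
        n_potential_instances=census.potential_instances,
        n_occurred_instances=sum(len(v) for v in occurred.values()),
        n_review_items=len(review),
        group_sizes=sizes,
    )
    return PipelineResult(
        analyzed=analyzed,
        flowchart=flow,
        potentials=potentials,
        occurred=occurred,
        review=review,
        labels=labels,
        census=census,
        summary=summary,
        pair_table=pair_table,
        class_table=class_table,
        strata=strata,
        recognition=recog,
        manifest=manifest,
    )


def _potentials_frame(potentials: dict) -> pd.DataFrame:
    rows = [
        {
            "report_id": p.report_id,
            "drug_a": p.pair.first,
            "drug_b": p.pair.second,
            "severity": p.severity.name,
        }
        for plist in potentials.values()
        for p in plist
    ]
    rows.sort(key=lambda r: (r["report_id"], r["drug_a"], r["drug_b"]))
    return pd.DataFrame(rows, columns=["report_id", "drug_a", "drug_b", "severity"])


def _occurred_frame(occurred: dict) -> pd.DataFrame:
    rows = [
        {
            "report_id": o.report_id,
            "drug_a": o.pair.first,
            "drug_b": o.pair.second,
            "severity": o.severity.name,
            "matched_terms": ";".join(sorted(o.matched_terms)),
            "both_drugs_suspect": o.both_drugs_suspect,
            "flagged_interacting": o.flagged_interacting,
        }
        for olist in occurred.values()
        for o in olist
    ]
    rows.sort(key=lambda r: (r["report_id"], r["drug_a"], r["drug_b"]))
    return pd.DataFrame(
        rows,
        columns=[
            "report_id", "drug_a", "drug_b", "severity",
            "matched_terms", "both_drugs_suspect", "flagged_interacting",
        ],
    )


def _review_frame(review: list) -> pd.DataFrame:
    rows = [
        {
            "report_id": item.report_id,
            "drug_a": item.pair.first,
            "drug_b": item.pair.second,
            "severity": item.severity.name,
            "effect_text": item.effect_text,
            "reaction_terms": ";".join(sorted(item.reaction_terms)),
        }
        for item in review
    ]
    rows.sort(key=lambda r: (r["report_id"], r["drug_a"], r["drug_b"]))
    return pd.DataFrame(
        rows,
        columns=["report_id", "drug_a", "drug_b", "severity", "effect_text",
                 "reaction_terms"],
    )


def run_pipeline(
    report_path: Union[str, Path],
    kb_path: Union[str, Path],
    out_dir: Union[str, Path],
    dialect: str = "jsonl",
    criteria: EligibilityCriteria = EligibilityCriteria(),
    class_map_path: Optional[Union[str, Path]] = None,
    min_reports: int = 1,
    ci_level: float = 0.95,
    max_reject_fraction: float = 0.10,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the pipeline from files and write all artifacts under ``out_dir``.

    Raises ``FileNotFoundError`` for missing inputs and ``ValueError`` when
    more than ``max_reject_fraction`` of the input records are rejected.
    """
    report_path, kb_path = Path(report_path), Path(kb_path)
    for p in (report_path, kb_path):
        if not p.exists():
            raise FileNotFoundError(p)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    errors: list[RecordError] = []
    reports = read_reports(report_path, dialect, collect_errors=errors)
    total_records = len(reports) + len(errors)
    if total_records and len(errors) / total_records > max_reject_fraction:
        raise ValueError(
            f"{len(errors)} of {total_records} records rejected "
            f"(> {max_reject_fraction:.0%} threshold)"
        )
    kb = load_kb(kb_path)
    class_map = None
    if class_map_path is not None:
        cm = pd.read_csv(class_map_path, sep="\t", dtype=str)
        class_map = dict(zip(cm.iloc[:, 0].str.upper(), cm.iloc[:, 1]))

    result = run_analysis(
        reports,
        kb,
        criteria,
        class_map=class_map,
        min_reports=min_reports,
        ci_level=ci_level,
        records_rejected=len(errors),
        report_path=str(report_path),
        kb_path=str(kb_path),
        seed=seed,
    )

    _potentials_frame(result.potentials).to_csv(
        out / "potential_ddis.tsv", sep="\t", index=False
    )
    _occurred_frame(result.occurred).to_csv(
        out / "occurred_ddis.tsv", sep="\t", index=False
    )
    _review_frame(result.review).to_csv(
        out / "review_queue.tsv", sep="\t", index=False
    )
    (out / "flowchart.json").write_text(
        json.dumps(result.flowchart.to_dict(), indent=2) + "\n"
    )
    result.summary.to_frame().to_csv(out / "group_summary.tsv", sep="\t")
    result.pair_table.to_csv(out / "pair_frequency.tsv", sep="\t", index=False)
    if result.class_table is not None:
        result.class_table.to_csv(out / "class_frequency.tsv", sep="\t", index=False)
    result.strata.to_csv(out / "polypharmacy_strata.tsv", sep="\t", index=False)
    if errors:
        with open(out / "rejected_records.txt", "w", encoding="utf-8") as fh:
            for e in errors:
                fh.write(str(e) + "\n")
    (out / "manifest.json").write_text(result.manifest.to_json() + "\n")
    return result
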