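"""Eligibility funnel, pair enumeration, screening and the census."""

import math
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddiscreen import (
    EligibilityCriteria,
    ReportSet,
    SimConfig,
    apply_eligibility_filters,
    combination_census,
    ddi_rate_by_polypharmacy,
    enumerate_pairs,
    generate_kb,
    generate_reports,
    screen_report,
    screen_reports,
)
from ddiscreen.ddi_kb import Severity, canonical_pair
from ddiscreen.screening import FlowchartCounts

from conftest import make_kb, make_report


class TestFlowchart:
    def test_hand_enumerated_fixture(self, funnel_reports):
        analyzed, counts = apply_eligibility_filters(funnel_reports)
        assert counts.total == 12
        assert counts.excluded_vaccine == 2
        assert counts.excluded_nonserious == 3
        assert counts.excluded_causality == 1
        assert counts.eligible_serious == 6
        assert counts.excluded_single_drug == 2
        assert counts.analyzed_multidrug == 4
        assert {r.report_id for r in analyzed} == {"r01", "r02", "r11", "r12"}

    def test_all_vaccine_fixture_empty(self):
        rs = ReportSet(
            reports=tuple(
                make_report(f"v{i}", [("a", "suspect"), ("b", "suspect")],
                            ["T"], vaccine=True)
                for i in range(4)
            )
        )
        _, counts = apply_eligibility_filters(rs)
        assert counts.analyzed_multidrug == 0

    def test_counts_invariant_enforced(self):
        with pytest.raises(ValueError):
            FlowchartCounts(
                total=10, excluded_vaccine=0, excluded_nonserious=0,
                excluded_causality=0, eligible_serious=10,
                excluded_single_drug=3, analyzed_multidrug=8,
            )

    def test_final_set_invariant_to_filter_order(self, funnel_reports):
        """Intermediate exclusion counts depend on filter order; the
        analyzed set does not."""
        analyzed, _ = apply_eligibility_filters(funnel_reports)
        ref_ids = {r.report_id for r in analyzed}

        preds = [
            lambda r: not r.is_vaccine,
            lambda r: r.serious,
            lambda r: r.causality.value in {"definite", "probable", "possible"},
            lambda r: len(r.distinct_drug_keys()) >= 2,
        ]
        import itertools

        for order in itertools.permutations(preds):
            kept = list(funnel_reports)
            for pred in order:
                kept = [r for r in kept if pred(r)]
            assert {r.report_id for r in kept} == ref_ids


class TestEnumeratePairs:
    def test_three_distinct_drugs_three_pairs(self):
        r = make_report("p1", [("a", "suspect"), ("b", "concomitant"),
                               ("c", "concomitant")])
        assert len(enumerate_pairs(r)) == 3

    def test_duplicate_substance_collapses(self):
        r = make_report("p2", [("w", "suspect"), ("w", "concomitant"),
                               ("x", "concomitant")])
        assert enumerate_pairs(r) == [canonical_pair("W", "X")]

    def test_eight_distinct_drugs_28_pairs(self):
        r = make_report("p3", [(f"d{i}", "suspect") for i in range(8)])
        assert len(enumerate_pairs(r)) == 28

    def test_single_drug_empty(self):
        r = make_report("p4", [("only", "suspect")])
        assert enumerate_pairs(r) == []

    @given(
        names=st.lists(
            st.text(alphabet="abcdefgh", min_size=1, max_size=3),
            min_size=0, max_size=12,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_pair_count_law(self, names):
        """|pairs| = C(d, 2) over distinct identity keys, roles pooled."""
        r = make_report(
            "prop", [(n, "suspect" if i % 2 else "concomitant")
                     for i, n in enumerate(names)] or [("z", "suspect")]
        )
        d = len(r.distinct_drug_keys())
        assert len(enumerate_pairs(r)) == math.comb(d, 2)


class TestScreenReport:
    def test_single_hit_with_copied_severity(self, small_kb):
        r = make_report("s1", [("warfarin", "suspect"), ("aspirin", "concomitant"),
                               ("metformin", "concomitant")])
        hits = screen_report(r, small_kb)
        assert len(hits) == 1
        assert hits[0].severity is Severity.major
        assert hits[0].pair == canonical_pair("WARFARIN", "ASPIRIN")

    def test_no_kb_pairs_empty(self, small_kb):
        r = make_report("s2", [("metformin", "suspect"), ("amlodipine", "suspect")])
        assert screen_report(r, small_kb) == []

    def test_two_hits_with_planted_severities(self):
        kb = make_kb(
            [
                ("A", "B", Severity.contraindicated, {"T1"}),
                ("C", "D", Severity.minor, {"T2"}),
            ]
        )
        r = make_report("s3", [("a", "suspect"), ("b", "suspect"),
                               ("c", "concomitant"), ("d", "concomitant")])
        sevs = sorted(h.severity.name for h in screen_report(r, kb))
        assert sevs == ["contraindicated", "minor"]


def _brute_force_census(reports, kb):
    """Independent recount: raw loops over the drug lists, no package
    screening helpers."""
    instances = 0
    distinct = set()
    potential = 0
    distinct_hits = set()
    breakdown = {}
    for r in reports:
        keys = sorted({d.identity_key for d in r.drugs})
        for a, b in combinations(keys, 2):
            instances += 1
            distinct.add((a, b))
            rec = kb.lookup(a, b)
            if rec is not None:
                potential += 1
                distinct_hits.add((a, b))
                breakdown[rec.severity] = breakdown.get(rec.severity, 0) + 1
    return instances, len(distinct), potential, len(distinct_hits), breakdown


class TestCensus:
    def test_empty_input_all_zero(self):
        census = combination_census([], {})
        assert census.pair_instances == census.potential_instances == 0
        assert census.severity_breakdown == {}

    def test_breakdown_partitions_potential_instances(self, small_kb):
        reports = [
            make_report("c1", [("warfarin", "suspect"), ("aspirin", "suspect"),
                               ("omeprazole", "concomitant")]),
            make_report("c2", [("digoxin", "suspect"), ("furosemide", "suspect")]),
        ]
        pots = screen_reports(reports, small_kb)
        census = combination_census(reports, pots)
        assert census.potential_instances == 3
        assert sum(census.severity_breakdown.values()) == 3

    def test_census_matches_brute_force_on_synthetic_fixture(self):
        cfg = SimConfig(n_reports=80)
        kb = generate_kb(cfg, seed=11)
        reports, _ = generate_reports(cfg, kb, seed=11)
        analyzed, _ = apply_eligibility_filters(reports)
        pots = screen_reports(analyzed, kb)
        census = combination_census(list(analyzed), pots)
        inst, dist, pot, dist_hits, brk = _brute_force_census(list(analyzed), kb)
        assert census.pair_instances == inst
        assert census.distinct_pairs == dist
        assert census.potential_instances == pot
        assert census.distinct_potential_pairs == dist_hits
        assert census.severity_breakdown == brk


class TestPolypharmacyStrata:
    def test_saturated_two_drug_stratum(self, small_kb):
        reports = [
            make_report(f"t{i}", [("warfarin", "suspect"), ("aspirin", "suspect")])
            for i in range(5)
        ]
        pots = screen_reports(reports, small_kb)
        tab = ddi_rate_by_polypharmacy(reports, pots)
        row = tab[tab.stratum == "2"].iloc[0]
        assert row.n_reports == 5 and row.pct_with_ddi == 100.0

    def test_empty_kb_all_rates_zero(self):
        kb = make_kb([])
        reports = [
            make_report(f"z{i}", [(f"d{j}", "suspect") for j in range(i + 2)])
            for i in range(6)
        ]
        pots = screen_reports(reports, kb)
        tab = ddi_rate_by_polypharmacy(reports, pots)
        filled = tab[tab.n_reports > 0]
        assert (filled.pct_with_ddi == 0.0).all()

    def test_empty_stratum_marked_undefined(self):
        reports = [make_report("u1", [("a", "suspect"), ("b", "suspect")])]
        tab = ddi_rate_by_polypharmacy(reports, {"u1": []})
        row = tab[tab.stratum == "8+"].iloc[0]
        assert row.n_reports == 0 and math.isnan(row.pct_with_ddi)


def test_min_drugs_below_two_rejected():
    with pytest.raises(ValueError):
        EligibilityCriteria(min_drugs=1)
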