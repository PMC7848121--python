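"""Group partition, Wilson/t intervals, rounding, and the summary tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from ddiscreen import (
    GroupLabel,
    SimConfig,
    apply_eligibility_filters,
    assess_reports,
    assign_group,
    assign_groups,
    class_frequency,
    generate_kb,
    generate_reports,
    group_summary,
    mean_ci,
    pair_frequency,
    recognition_rates,
    round_pct,
    screen_reports,
    wilson_ci,
)
from ddiscreen.ddi_kb import Severity

from conftest import make_kb, make_report


class TestRoundPct:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (381, 2195, 17.4),
            (1369, 14473, 9.5),
            (0, 1, 0.0),
            (1, 8, 12.5),
        ],
    )
    def test_printed_precision(self, num, den, expected):
        assert round_pct(num / den) == expected

    def test_half_away_from_zero(self):
        assert round_pct(0.12345) == 12.3
        assert round_pct(0.1235) == 12.4
        assert round_pct(-0.1235) == -12.4


class TestWilsonCI:
    @pytest.mark.parametrize(
        "k, n, point, low, high",
        [
            (17, 381, 4.5, 2.8, 7.0),
            (179, 381, 47.0, 42.0, 52.0),
            (345, 381, 90.6, 87.2, 93.1),
        ],
    )
    def test_reported_group_a_cells(self, k, n, point, low, high):
        """The score interval reproduces the published group-A summary
        bounds to one decimal."""
        ci = wilson_ci(k, n, 0.95)
        assert (ci.point_pct, ci.low_pct, ci.high_pct) == (point, low, high)

    def test_zero_successes_lower_bound_zero(self):
        assert wilson_ci(0, 50, 0.95).low_pct == 0.0

    def test_all_successes_upper_bound_hundred(self):
        assert wilson_ci(50, 50, 0.95).high_pct == 100.0

    def test_n_zero_errors(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)

    @given(
        n=st.integers(min_value=1, max_value=2000),
        frac=st.floats(min_value=0, max_value=1),
        level=st.sampled_from([0.90, 0.95, 0.99]),
    )
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_independent_implementation(self, n, frac, level):
        """Closed-form score interval matches statsmodels' Wilson interval."""
        k = round(frac * n)
        ci = wilson_ci(k, n, level)
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
        assert ci.low_pct == round_pct(lo)
        assert ci.high_pct == round_pct(hi)
        assert ci.low_pct <= ci.point_pct <= ci.high_pct

    def test_interval_narrows_with_n_at_fixed_rate(self):
        widths = []
        for n in (50, 200, 800, 3200):
            ci = wilson_ci(n // 5, n, 0.95)
            widths.append(ci.high_pct - ci.low_pct)
        assert widths == sorted(widths, reverse=True)


class TestMeanCI:
    def test_constant_vector_zero_width(self):
        ci = mean_ci([4.0, 4.0, 4.0], 0.95)
        assert ci.low == ci.mean == ci.high == 4.0

    def test_textbook_t_interval(self):
        # x = 1..5: mean 3, s = sqrt(2.5), t_{.975,4} = 2.7764
        ci = mean_ci([1, 2, 3, 4, 5], 0.95)
        assert ci.mean == pytest.approx(3.0)
        assert ci.low == pytest.approx(1.036757, abs=1e-5)
        assert ci.high == pytest.approx(4.963243, abs=1e-5)

    def test_narrower_with_larger_n_same_variance(self):
        small = mean_ci([1, 2, 3, 4, 5], 0.95)
        large = mean_ci([1, 2, 3, 4, 5] * 8, 0.95)
        assert (large.high - large.low) < (small.high - small.low)

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            mean_ci([3.0])


class TestAssignGroup:
    def test_definitions(self):
        pots = {"a": [object(), object()], "b": [object()], "c": []}
        occ = {"a": [object()], "b": [], "c": []}
        assert assign_group("a", pots, occ) is GroupLabel.A
        assert assign_group("b", pots, occ) is GroupLabel.B
        assert assign_group("c", pots, occ) is GroupLabel.C

    def test_unscreened_report_errors(self):
        with pytest.raises(KeyError):
            assign_group("ghost", {}, {})

    def test_partition_exhaustive_and_exclusive_on_synthetic_set(self):
        cfg = SimConfig(n_reports=400)
        kb = generate_kb(cfg, seed=5)
        reports, _ = generate_reports(cfg, kb, seed=5)
        analyzed, _ = apply_eligibility_filters(reports)
        pots = screen_reports(analyzed, kb)
        occ, _ = assess_reports(analyzed, pots)
        labels = assign_groups(list(analyzed), pots, occ)
        assert set(labels) == {r.report_id for r in analyzed}
        sizes = {g: sum(1 for v in labels.values() if v is g) for g in GroupLabel}
        assert sum(sizes.values()) == len(analyzed)


def _fixture_30():
    """30 analyzed reports with known groups: 8 A, 10 B, 12 C."""
    kb = make_kb(
        [
            ("W", "A", Severity.major, {"BLEED"}),
            ("D", "F", Severity.moderate, {"BRADY"}),
        ]
    )
    reports = []
    for i in range(8):  # occurred
        reports.append(
            make_report(
                f"a{i}", [("w", "suspect"), ("a", "suspect" if i < 5 else "concomitant")],
                ["BLEED"], age=70 + i, sex="male" if i % 2 else "female",
                fatal_reaction=(i == 0),
            )
        )
    for i in range(10):  # potential only
        reports.append(
            make_report(
                f"b{i}", [("d", "suspect"), ("f", "concomitant"), ("x", "concomitant")],
                ["RASH"], age=60 + i, sex="male" if i % 3 == 0 else "female",
            )
        )
    for i in range(12):  # no listed interaction
        reports.append(
            make_report(
                f"c{i}", [("p", "suspect"), ("q", "concomitant")], ["NAUSEA"],
                age=None if i == 0 else 40 + i, sex="unknown" if i == 1 else "female",
            )
        )
    return reports, kb


class TestGroupSummary:
    def test_hand_fixture_cells(self):
        reports, kb = _fixture_30()
        pots = screen_reports(reports, kb)
        occ, _ = assess_reports(reports, pots)
        labels = assign_groups(reports, pots, occ)
        table = group_summary(reports, labels, pots)
        ga, gb, gc = (table.groups[g] for g in GroupLabel)
        assert (ga.n, gb.n, gc.n) == (8, 10, 12)
        # brute-force recompute of selected cells via the independent oracle
        assert ga.fatal.k == 1 and ga.fatal.n == 8
        lo, hi = proportion_confint(1, 8, 0.05, method="wilson")
        assert (ga.fatal.low_pct, ga.fatal.high_pct) == (round_pct(lo), round_pct(hi))
        assert ga.male.k == 4 and ga.male.n == 8
        # contraindicated+major over group potential instances: A all major
        assert ga.contra_major_pct.k == 8 and ga.contra_major_pct.n == 8
        assert gb.contra_major_pct.k == 0 and gb.contra_major_pct.n == 10
        assert gc.contra_major_pct is None
        # pairwise-deleted age: group C has one missing age
        assert gc.age_mean.n == 11
        assert np.isclose(
            gc.age_mean.mean, np.mean([40 + i for i in range(1, 12)])
        )

    def test_single_group_input_no_crash(self):
        reports = [
            make_report(f"c{i}", [("p", "suspect"), ("q", "suspect")], ["T"])
            for i in range(4)
        ]
        pots = {r.report_id: [] for r in reports}
        labels = {r.report_id: GroupLabel.C for r in reports}
        table = group_summary(reports, labels, pots)
        assert table.groups[GroupLabel.A].n == 0
        assert table.groups[GroupLabel.A].fatal is None
        frame = table.to_frame()
        assert (frame["Group A"] == "undefined").sum() > 0

    def test_group_sizes_must_sum(self):
        reports, kb = _fixture_30()
        pots = screen_reports(reports, kb)
        occ, _ = assess_reports(reports, pots)
        labels = assign_groups(reports, pots, occ)
        table = group_summary(reports, labels, pots)
        assert table.analyzed_n == 30


class TestFrequencyTables:
    def test_pair_ranking_and_tie_break(self, small_kb):
        reports = (
            [make_report(f"p{i}", [("warfarin", "suspect"), ("aspirin", "suspect")],
                         ["GI_BLEED"]) for i in range(3)]
            + [make_report("q0", [("digoxin", "suspect"), ("furosemide", "suspect")],
                           ["BRADYCARDIA"])]
        )
        pots = screen_reports(reports, small_kb)
        occ, _ = assess_reports(reports, pots)
        tab = pair_frequency(occ)
        assert list(tab.n_reports) == [3, 1]
        assert tab.iloc[0].pair == "ASPIRIN/WARFARIN"
        assert "GI_BLEED (3)" in tab.iloc[0].top_terms

    def test_recognition_columns(self, small_kb):
        reports = []
        for i in range(5):
            both = i < 3
            reports.append(
                make_report(
                    f"r{i}",
                    [("warfarin", "suspect"),
                     ("aspirin", "suspect" if both else "concomitant")],
                    ["GI_BLEED"],
                    flags={"WARFARIN": i == 0, "ASPIRIN": i == 0},
                )
            )
        pots = screen_reports(reports, small_kb)
        occ, _ = assess_reports(reports, pots)
        tab = pair_frequency(occ)
        assert tab.iloc[0].n_both_suspect == 3
        assert tab.iloc[0].n_flagged == 1

    def test_min_reports_threshold(self, small_kb):
        reports = [
            make_report(f"p{i}", [("warfarin", "suspect"), ("aspirin", "suspect")],
                        ["GI_BLEED"]) for i in range(3)
        ] + [make_report("q0", [("digoxin", "suspect"), ("furosemide", "suspect")],
                         ["BRADYCARDIA"])]
        pots = screen_reports(reports, small_kb)
        occ, _ = assess_reports(reports, pots)
        tab = pair_frequency(occ, min_reports=2)
        assert list(tab.pair) == ["ASPIRIN/WARFARIN"]

    def test_empty_occurred_empty_table(self):
        assert pair_frequency({}).empty

    def test_class_frequency_fatal_share(self, small_kb):
        reports = []
        for i in range(26):
            reports.append(
                make_report(
                    f"k{i}", [("warfarin", "suspect"), ("aspirin", "suspect")],
                    ["GI_BLEED"], fatal_reaction=(i < 3),
                )
            )
        pots = screen_reports(reports, small_kb)
        occ, _ = assess_reports(reports, pots)
        cmap = {"WARFARIN": "Vitamin K antagonists",
                "ASPIRIN": "Antiplatelet drugs"}
        tab = class_frequency(occ, cmap, reports)
        row = tab.iloc[0]
        assert row.n_reports == 26 and row.n_fatal == 3
        assert row.fatal_pct == 11.5

    def test_unmapped_drug_bucketed(self, small_kb):
        reports = [make_report("u0", [("warfarin", "suspect"),
                                      ("aspirin", "suspect")], ["GI_BLEED"])]
        pots = screen_reports(reports, small_kb)
        occ, _ = assess_reports(reports, pots)
        tab = class_frequency(occ, {"WARFARIN": "VKA"}, reports)
        assert set(tab.iloc[0][["class_a", "class_b"]]) == {"VKA", "UNMAPPED"}


class TestRecognitionRates:
    def test_rates_over_group_a_reports(self, small_kb):
        reports = []
        for i in range(10):
            reports.append(
                make_report(
                    f"r{i}",
                    [("warfarin", "suspect"),
                     ("aspirin", "suspect" if i < 4 else "concomitant")],
                    ["GI_BLEED"] if i < 8 else ["RASH"],
                    flags={"WARFARIN": i < 2, "ASPIRIN": i < 2},
                )
            )
        pots = screen_reports(reports, small_kb)
        occ, _ = assess_reports(reports, pots)
        pct_suspect, pct_flagged = recognition_rates(occ)
        # 8 occurred reports; 4 both-suspect, 2 flagged
        assert pct_suspect == 50.0
        assert pct_flagged == 25.0

    def test_no_occurred_reports_undefined(self):
        assert recognition_rates({"a": [], "b": []}) == (None, None)
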