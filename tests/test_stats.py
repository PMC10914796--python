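"""Odds ratios, Wald intervals, rate ratios and panel construction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcma_faers import (ConfigurationError, MortalityCounts, TwoByTwo,
                        build_event_table, build_fatality_table, dispro_panel,
                        mortality_panel, odds_ratio, rate_ratio)
from bcma_faers.stats import percentage, round_half_away
from bcma_faers.taxonomy import CategoryCounts


def make_counts(events, totals):
    """CategoryCounts from {drug: {cat: n}} and {drug: total_events}."""
    return CategoryCounts(
        events=events,
        cases={d: {c: 0 for c in cats} for d, cats in events.items()},
        total_events=totals,
        total_cases={d: 0 for d in events},
    )


class TestOddsRatio:
    @pytest.mark.parametrize(
        ("table", "point", "ci"),
        [
            # ide-cel CRS against the other two drugs, event-level counts
            (TwoByTwo(344, 1788, 220, 2017), 1.76, (1.47, 2.11)),
            # teclistamab non-ICANS neurotoxicity
            (TwoByTwo(52, 1311, 271, 2735), 0.40, (0.30, 0.54)),
            # cilta-cel all-cause fatal reports, case-level counts
            (TwoByTwo(82, 395, 227, 1080), 0.99, None),
        ],
    )
    def test_published_style_tables(self, table, point, ci):
        est = odds_ratio(table)
        assert round_half_away(est.point, 2) == pytest.approx(point)
        if ci:
            assert round_half_away(est.ci_low, 2) == pytest.approx(ci[0])
            assert round_half_away(est.ci_high, 2) == pytest.approx(ci[1])
        assert not est.corrected

    def test_identity_table_symmetric_on_log_scale(self):
        est = odds_ratio(TwoByTwo(1, 1, 1, 1))
        assert est.point == pytest.approx(1.0)
        assert est.ci_low * est.ci_high == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        est = odds_ratio(TwoByTwo(0, 10, 5, 5))
        assert est.corrected
        assert est.point == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_event_unseen_anywhere_has_no_estimate(self):
        assert odds_ratio(TwoByTwo(0, 10, 0, 10)) is None

    def test_alpha_shrinking_widens_interval(self):
        table = TwoByTwo(30, 70, 20, 80)
        narrow = odds_ratio(table, alpha=0.10)
        wide = odds_ratio(table, alpha=0.01)
        assert wide.ci_low < narrow.ci_low < narrow.ci_high < wide.ci_high

    def test_negative_or_empty_margins_invalid(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            TwoByTwo(0, 0, 3, 4)

    def test_matches_statsmodels_oracle(self):
        """Independent route: statsmodels Table2x2 point estimate and Wald CI."""
        from statsmodels.stats.contingency_tables import Table2x2

        rng = np.random.default_rng(12345)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 400, size=4)
            est = odds_ratio(TwoByTwo(int(a), int(b), int(c), int(d)))
            ref = Table2x2(np.array([[a, b], [c, d]]))
            lo, hi = ref.oddsratio_confint(0.05)
            assert est.point == pytest.approx(ref.oddsratio, rel=1e-12)
            assert est.ci_low == pytest.approx(lo, rel=1e-9)
            assert est.ci_high == pytest.approx(hi, rel=1e-9)


cells = st.integers(1, 10_000)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_transposition_law(a, b, c, d):
    """Swapping index and comparator arms inverts the estimate and mirrors
    the interval."""
    fwd = odds_ratio(TwoByTwo(a, b, c, d))
    rev = odds_ratio(TwoByTwo(c, d, a, b))
    assert fwd.point * rev.point == pytest.approx(1.0)
    assert fwd.ci_low * rev.ci_high == pytest.approx(1.0)
    assert fwd.ci_high * rev.ci_low == pytest.approx(1.0)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(a=st.integers(1, 500), b=st.integers(1, 500), c=st.integers(1, 500),
       d=st.integers(1, 500), k=st.integers(2, 20))
def test_scaling_preserves_point_and_narrows_ci(a, b, c, d, k):
    base = odds_ratio(TwoByTwo(a, b, c, d))
    scaled = odds_ratio(TwoByTwo(a * k, b * k, c * k, d * k))
    assert scaled.point == pytest.approx(base.point)
    assert scaled.ci_low >= base.ci_low and scaled.ci_high <= base.ci_high


class TestRateRatio:
    @pytest.mark.parametrize(
        ("args", "expected"),
        [
            ((7, 874, 4, 2132), 4.2689),   # parkinsonism-style contrast
            ((5, 100, 5, 100), 1.0),
            ((0, 10, 5, 10), 0.0),
        ],
    )
    def test_values(self, args, expected):
        assert rate_ratio(*args) == pytest.approx(expected, abs=1e-4)

    def test_zero_reference_is_undefined(self):
        assert rate_ratio(3, 10, 0, 10) is None

    def test_zero_denominator_invalid(self):
        with pytest.raises(ValueError):
            rate_ratio(1, 0, 1, 10)


class TestTables:
    # per-drug event-level category counts in the style of a published
    # three-drug summary table
    EVENTS = {"ide-cel": {"CRS": 344, "non-ICANS neurotoxicity": 215},
              "cilta-cel": {"CRS": 90, "non-ICANS neurotoxicity": 56},
              "teclistamab": {"CRS": 130, "non-ICANS neurotoxicity": 52}}
    TOTALS = {"ide-cel": 2132, "cilta-cel": 874, "teclistamab": 1363}

    def test_event_table_pools_comparators(self):
        counts = make_counts(self.EVENTS, self.TOTALS)
        t = build_event_table(counts, "ide-cel", "CRS")
        assert (t.a, t.b, t.c, t.d) == (344, 1788, 220, 2017)
        t = build_event_table(counts, "teclistamab", "non-ICANS neurotoxicity")
        assert (t.a, t.b, t.c, t.d) == (52, 1311, 271, 2735)

    def test_equal_frequencies_give_unit_odds(self):
        counts = make_counts({"x": {"CRS": 10}, "y": {"CRS": 20}},
                             {"x": 100, "y": 200})
        t = build_event_table(counts, "x", "CRS")
        assert t.a * t.d == t.b * t.c

    def test_fatality_table_case_level(self):
        counts = MortalityCounts(
            n_cases={"ide-cel": 584, "cilta-cel": 477, "teclistamab": 723},
            n_death={"ide-cel": 68, "cilta-cel": 82, "teclistamab": 159},
            n_nrm={"ide-cel": 60, "cilta-cel": 70, "teclistamab": 140})
        t = build_fatality_table(counts, "cilta-cel", "death")
        assert (t.a, t.b, t.c, t.d) == (82, 395, 227, 1080)
        t = build_fatality_table(counts, "cilta-cel", "nrm")
        assert (t.a, t.b) == (70, 407)

    def test_single_drug_cohort_has_no_comparator(self):
        counts = make_counts({"x": {"CRS": 10}}, {"x": 100})
        with pytest.raises(ConfigurationError, match="comparator"):
            build_event_table(counts, "x", "CRS")

    def test_all_fatal_cohort_flagged_for_correction(self):
        counts = MortalityCounts(n_cases={"x": 5, "y": 8},
                                 n_death={"x": 5, "y": 8},
                                 n_nrm={"x": 5, "y": 8})
        t = build_fatality_table(counts, "x", "death")
        assert t.b == t.d == 0
        assert odds_ratio(t).corrected


class TestPanel:
    def test_cardinality_three_drugs_two_categories(self):
        counts = make_counts(TestTables.EVENTS, TestTables.TOTALS)
        panel = dispro_panel(counts)
        assert len(panel) == 6
        mort = mortality_panel(MortalityCounts(
            n_cases={"a": 10, "b": 10, "c": 10},
            n_death={"a": 2, "b": 3, "c": 4},
            n_nrm={"a": 1, "b": 2, "c": 3}))
        assert len(mort) == 3

    def test_drug_order_permutation_gives_same_estimates(self):
        counts = make_counts(TestTables.EVENTS, TestTables.TOTALS)
        permuted = make_counts(
            {d: TestTables.EVENTS[d] for d in
             ["teclistamab", "ide-cel", "cilta-cel"]},
            {d: TestTables.TOTALS[d] for d in
             ["teclistamab", "ide-cel", "cilta-cel"]})
        base = {(r.drug, r.category): r.estimate.point
                for r in dispro_panel(counts)}
        perm = {(r.drug, r.category): r.estimate.point
                for r in dispro_panel(permuted)}
        assert base == perm


@pytest.mark.parametrize(
    ("value", "decimals", "expected"),
    [(1.765, 1, 1.8), (0.125, 2, 0.13), (-0.125, 2, -0.13), (4.2689, 1, 4.3),
     (2.5, 0, 3.0)],
)
def test_round_half_away_from_zero(value, decimals, expected):
    assert round_half_away(value, decimals) == pytest.approx(expected)


def test_percentage_recomputes_from_count_and_denominator():
    assert percentage(82, 477) == 17.2
    assert percentage(208, 584) == 35.6
    assert percentage(344, 2132) == 16.1
    assert percentage(130, 1363) == 9.5
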