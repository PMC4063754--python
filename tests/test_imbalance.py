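"""Allele-imbalance statistics: c_v, equality test, categories, quadrants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polyase.imbalance import (
    CV_ONE_SILENCED,
    SQRT3,
    chromosome_rank_table,
    classify_category,
    coefficient_of_variation,
    concordance,
    equal_expression_test,
    quadrant,
)


class TestCoefficientOfVariation:
    def test_equal_expression_has_zero_dispersion(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_one_silenced_allele_landmark(self):
        # (x, x, 0): the c_v is sqrt(3)/2 regardless of x.
        for x in (1.0, 7.0, 250.0):
            assert coefficient_of_variation([x, x, 0.0]) == pytest.approx(SQRT3 / 2)

    def test_two_silenced_alleles_landmark(self):
        for x in (1.0, 9.0, 4000.0):
            assert coefficient_of_variation([x, 0.0, 0.0]) == pytest.approx(SQRT3)

    def test_all_zero_is_undefined(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([0.0, 0.0, 0.0])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.floats(0, 1e6, allow_nan=False),
            st.floats(0, 1e6, allow_nan=False),
            st.floats(0, 1e6, allow_nan=False),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_bounded_by_sqrt3_for_triples(self, values):
        cv = coefficient_of_variation(values)
        assert 0.0 <= cv <= SQRT3 + 1e-9
        if cv > SQRT3 - 1e-9:  # the bound is approached only when one value dominates
            assert sorted(values)[1] <= 1e-6 * max(values)


class TestEqualExpressionTest:
    def test_perfectly_even_expression(self):
        assert equal_expression_test([10.0, 10.0, 10.0]) == pytest.approx(1.0)

    def test_fully_skewed_statistic_and_tail(self):
        # (30,0,0): expected 10 each, statistic 400/10 + 100/10 + 100/10 = 60.
        p = equal_expression_test([30.0, 0.0, 0.0])
        assert p == pytest.approx(float(stats.chi2.sf(60.0, df=2)), rel=1e-12)
        assert p == pytest.approx(math.exp(-30.0), rel=1e-9)

    def test_mild_deviation(self):
        # (12,9,9): expected 10, statistic 0.6, df 2 tail exp(-0.3).
        assert equal_expression_test([12.0, 9.0, 9.0]) == pytest.approx(
            math.exp(-0.3), rel=1e-9
        )

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            equal_expression_test([0.0, 0.0])


class TestClassifyCategory:
    def test_not_rejected_is_even(self):
        assert classify_category({"a": 10, "b": 10, "c": 10}, p_value=1.0) == "even"

    def test_single_silenced_allele_is_down(self):
        # median 20; 0 < 20/2.
        assert classify_category({"a": 0, "b": 20, "c": 22}, p_value=1e-4) == "a_down"

    def test_single_dominant_allele_is_up(self):
        # median 12; 50 > 24; no down since 10 > 6.
        assert classify_category({"a": 50, "b": 10, "c": 12}, p_value=1e-4) == "a_up"

    def test_rejected_but_within_fold_is_spread(self):
        assert classify_category({"a": 18, "b": 10, "c": 12}, p_value=1e-4) == "spread"

    def test_two_crossings_same_direction_are_spread(self):
        # At higher ploidy two alleles can exceed 2x the median; neither is
        # then singled out and the transcript falls through to spread.
        values = {"a": 100.0, "b": 90.0, "c": 10.0, "d": 9.0, "e": 8.0}
        assert classify_category(values, p_value=1e-4) == "spread"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(st.floats(0.01, 1e4), st.floats(0.01, 1e4), st.floats(0.01, 1e4)),
        st.floats(1e-6, 1.0),
        st.floats(1.5, 10),
    )
    def test_scale_invariant(self, values, p, k):
        base = {"a": values[0], "b": values[1], "c": values[2]}
        scaled = {s: k * v for s, v in base.items()}
        assert classify_category(base, p) == classify_category(scaled, p)


class TestQuadrant:
    @pytest.mark.parametrize(
        "ratio, cv, expected",
        [(1.0, 0.2, "0"), (3.0, 0.2, "II"), (1.0, 1.0, "I"), (4.0, 1.0, "III"),
         (0.2, 0.2, "II"), (2.0, CV_ONE_SILENCED, "0")],
    )
    def test_grid(self, ratio, cv, expected):
        assert quadrant(ratio * 8.0, 8.0, cv) == expected

    def test_positive_expression_required(self):
        with pytest.raises(ValueError):
            quadrant(0.0, 5.0, 0.2)


class TestConcordance:
    def test_identical_maps(self):
        a = {"t1": "even", "t2": "a_up"}
        total, per_cat = concordance(a, dict(a))
        assert total == 2 and per_cat == {"even": 1, "a_up": 1}

    def test_fully_discordant(self):
        total, per_cat = concordance({"t1": "even"}, {"t1": "a_up"})
        assert total == 0 and per_cat == {}

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance({"t1": "even"}, {"t2": "even"})

    def test_fuzzed_matches_per_transcript_comparison(self):
        rng = np.random.default_rng(9)
        cats = ["even", "spread", "a_up", "a_down", "b_up"]
        universe = [f"t{i}" for i in range(200)]
        a = {t: cats[rng.integers(len(cats))] for t in universe}
        b = {t: cats[rng.integers(len(cats))] for t in universe}
        total, per_cat = concordance(a, b)
        expected = [t for t in universe if a[t] == b[t]]
        assert total == len(expected)
        assert sum(per_cat.values()) == total
        for cat in per_cat:
            assert per_cat[cat] == sum(1 for t in expected if a[t] == cat)


class TestChromosomeRankTable:
    def annotation(self, rows):
        return pd.DataFrame(rows, columns=["transcript_id", "chromosome", "order"])

    def test_sequential_ranks_within_chromosome(self):
        ann = self.annotation([("t2", "chr1", 500), ("t1", "chr1", 100), ("t3", "chr1", 900)])
        table = chromosome_rank_table({"t1": "even", "t2": "a_up", "t3": "even"}, ann)
        assert list(table["transcript_id"]) == ["t1", "t2", "t3"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_coordinate_ties_get_sequential_ranks_input_order(self):
        ann = self.annotation([("tA", "chr2", 50), ("tB", "chr2", 50)])
        table = chromosome_rank_table({"tA": "even", "tB": "spread"}, ann)
        assert list(table["transcript_id"]) == ["tA", "tB"]
        assert list(table["rank"]) == [1, 2]

    def test_empty_annotation(self):
        table = chromosome_rank_table({"t1": "even"}, self.annotation([]))
        assert table.empty

    def test_unannotated_transcripts_omitted(self):
        ann = self.annotation([("t1", "chr1", 1)])
        table = chromosome_rank_table({"t1": "even", "t9": "spread"}, ann)
        assert list(table["transcript_id"]) == ["t1"]

    def test_duplicate_placement_rejected(self):
        ann = self.annotation([("t1", "chr1", 1), ("t1", "chr1", 1)])
        with pytest.raises(ValueError):
            chromosome_rank_table({"t1": "even"}, ann)
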