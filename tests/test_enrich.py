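"""Exact test, Storey q-values, and the enrichment report assembly."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from enrichkit import (
    DegenerateTableError,
    GeneSet,
    GeneSetCollection,
    InputError,
    QvalueParams,
    enrich,
    fisher_exact_two_sided,
    query_set_vs_collection,
    storey_qvalues,
)


def fisher_oracle(a, b, c, d):
    """Exact two-sided p by integer enumeration of the hypergeometric
    support with a common denominator (no floating point until the end)."""
    n_total, row1, col1 = a + b + c + d, a + b, a + c
    k_min, k_max = max(0, row1 + col1 - n_total), min(row1, col1)
    nums = [comb(col1, k) * comb(n_total - col1, row1 - k) for k in range(k_min, k_max + 1)]
    obs = nums[a - k_min]
    return float(Fraction(sum(x for x in nums if x <= obs), comb(n_total, row1)))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((3, 1, 1, 3), 34 / 70),   # enumeration over margins (4,4|4,4)
            ((1, 1, 1, 1), 1.0),       # symmetric table, every outcome qualifies
            ((5, 0, 0, 5), 2 / 252),   # only the two extreme tables qualify
        ],
    )
    def test_frozen_enumeration_values(self, table, expected):
        assert fisher_exact_two_sided(table) == pytest.approx(expected, abs=1e-12)
        assert fisher_oracle(*table) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("table", [(0, 0, 1, 1), (1, 1, 0, 0), (1, 0, 1, 0), (0, 1, 0, 1)])
    def test_zero_margin_is_degenerate(self, table):
        with pytest.raises(DegenerateTableError):
            fisher_exact_two_sided(table)

    def test_negative_cell_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_two_sided((-1, 2, 3, 4))

    def test_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            cells = rng.integers(0, 30, size=4)
            a, b, c, d = (int(x) for x in cells)
            if (a + b) in (0, a + b + c + d) or (a + c) in (0, a + b + c + d):
                continue
            assert fisher_exact_two_sided((a, b, c, d)) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-11
            )

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 40, size=4))
            ours = fisher_exact_two_sided((a, b, c, d))
            theirs = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)


class TestStoreyQvalues:
    def test_fixed_pi0_one_reduces_to_benjamini_hochberg(self):
        p = [0.01, 0.02, 0.03, 0.04]
        q, pi0 = storey_qvalues(p, QvalueParams(pi0_method="fixed", fixed_pi0=1.0))
        assert pi0 == 1.0
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_equality_on_random_vectors(self):
        params = QvalueParams(pi0_method="fixed", fixed_pi0=1.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            q, _ = storey_qvalues(p, params)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh, atol=1e-12)

    def test_single_pvalue_of_one(self):
        q, pi0 = storey_qvalues([1.0], QvalueParams(pi0_method="fixed", fixed_pi0=1.0))
        assert q.tolist() == [1.0] and pi0 == 1.0

    def test_out_of_range_pvalue_rejected(self):
        with pytest.raises(InputError):
            storey_qvalues([0.5, 1.5])

    def test_smoother_pi0_near_one_under_global_null(self):
        vals = []
        for seed in range(10):
            p = np.random.default_rng(seed).uniform(size=2000)
            _, pi0 = storey_qvalues(p)
            vals.append(pi0)
        assert 0.9 <= float(np.mean(vals)) <= 1.0

    def test_smoother_matches_r_smooth_spline_df3(self):
        """Frozen cross-check: pi0 for the seed-5 null draw computed with R's
        smooth.spline(df=3) on the identical grid estimates is 0.9620016."""
        p = np.random.default_rng(5).uniform(size=2000)
        _, pi0 = storey_qvalues(p)
        assert pi0 == pytest.approx(0.9620016, abs=5e-5)

    def test_pi0_scales_q_linearly(self):
        p = np.random.default_rng(5).uniform(size=100)
        q_half, _ = storey_qvalues(p, QvalueParams(pi0_method="fixed", fixed_pi0=0.5))
        q_full, _ = storey_qvalues(p, QvalueParams(pi0_method="fixed", fixed_pi0=1.0))
        unclamped = q_full < 1.0
        assert np.allclose(q_half[unclamped], 0.5 * q_full[unclamped])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_qvalues_monotone_in_sorted_p_and_bounded(self, pvals):
        q, pi0 = storey_qvalues(pvals, QvalueParams(pi0_method="fixed", fixed_pi0=1.0))
        assert 0 < pi0 <= 1
        assert np.all(q >= 0) and np.all(q <= 1)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_bad_params_rejected(self):
        with pytest.raises(InputError):
            QvalueParams(lambda_grid=(0.5, 0.2))
        with pytest.raises(InputError):
            QvalueParams(lambda_grid=(0.0, 0.95))
        with pytest.raises(InputError):
            QvalueParams(pi0_method="fixed", fixed_pi0=0.0)


@pytest.fixture
def background20():
    return list(range(1, 21))


class TestEnrich:
    def test_counts_and_p_against_enumeration_oracle(self, toy_collection, background20):
        report = enrich([1, 2, 3, 4, 5, 16], background20, toy_collection,
                        p_threshold=1.0)
        row = next(r for r in report.rows if r.set_id == "pathA")
        assert (row.count, row.set_size, row.test_size, row.background_size) == (5, 10, 6, 20)
        assert row.direction == "over"
        assert row.p_value == pytest.approx(fisher_oracle(5, 1, 5, 9), abs=1e-11)

    def test_test_equal_to_background_is_degenerate_tie(self, toy_collection, background20):
        report = enrich(background20, background20, toy_collection, p_threshold=1.0)
        for row in report.rows:
            assert row.count == row.set_size
            assert row.direction == "under"  # exact tie resolves to under
            assert row.p_value == 1.0

    def test_percent_cover_mode_ranks_descending_without_filter(self, background20):
        coll = GeneSetCollection("t", 9606, [
            GeneSet("half", "x", frozenset({1, 2, 3, 4})),
            GeneSet("all", "x", frozenset({1, 2})),
            GeneSet("none", "x", frozenset({19, 20})),
        ])
        report = enrich([1, 2], background20, coll, method="percent_cover")
        assert [r.set_id for r in report.rows] == ["all", "half", "none"]
        assert [r.percent_cover for r in report.rows] == [100.0, 50.0, 0.0]

    def test_genes_outside_background_dropped_and_reported(self, toy_collection, background20):
        report = enrich([1, 2, 99], background20, toy_collection, p_threshold=1.0)
        assert report.dropped_genes == [99]
        assert report.test_size == 2

    def test_all_genes_outside_background_is_an_error(self, toy_collection, background20):
        with pytest.raises(InputError, match="99"):
            enrich([99], background20, toy_collection)

    def test_empty_collection_is_an_error(self, background20):
        with pytest.raises(InputError):
            enrich([1], background20, GeneSetCollection("e", 9606, []))

    def test_q_computed_over_all_sets_before_p_filter(self, background20):
        """The q-value of a retained row reflects the full collection size,
        not just the displayed rows."""
        coll = GeneSetCollection("t", 9606, [
            GeneSet("sig", "x", frozenset(range(1, 11))),
            GeneSet("null1", "x", frozenset({11, 15})),
            GeneSet("null2", "x", frozenset({12, 16})),
            GeneSet("null3", "x", frozenset({13, 17})),
        ])
        params = QvalueParams(pi0_method="fixed", fixed_pi0=1.0)
        full = enrich(list(range(1, 11)), background20, coll, params=params,
                      p_threshold=1.0)
        filtered = enrich(list(range(1, 11)), background20, coll, params=params,
                          p_threshold=0.05)
        q_full = {r.set_id: r.q_value for r in full.rows}
        assert len(filtered.rows) < len(full.rows)
        for r in filtered.rows:
            assert r.q_value == q_full[r.set_id]

    def test_rows_never_filtered_on_q(self, background20):
        """A row with p below threshold stays even when its q-value exceeds it."""
        coll = GeneSetCollection("t", 9606, [
            GeneSet(f"s{i}", "x", frozenset({i, i + 1})) for i in range(1, 15)
        ])
        report = enrich([1, 2], background20, coll, p_threshold=0.05,
                        params=QvalueParams(pi0_method="fixed", fixed_pi0=1.0))
        assert any(r.q_value > 0.05 for r in report.rows) or all(
            r.p_value <= 0.05 for r in report.rows
        )

    def test_invariant_to_input_order(self, toy_collection, background20):
        a = enrich([1, 2, 3, 16], background20, toy_collection, p_threshold=1.0)
        b = enrich([16, 3, 2, 1], list(reversed(background20)), toy_collection,
                   p_threshold=1.0)
        assert [(r.set_id, r.p_value, r.q_value) for r in a.rows] == [
            (r.set_id, r.p_value, r.q_value) for r in b.rows
        ]

    def test_ties_in_p_break_by_set_id(self, background20):
        coll = GeneSetCollection("t", 9606, [
            GeneSet("zz", "x", frozenset({1, 2})),
            GeneSet("aa", "x", frozenset({1, 2})),
        ])
        report = enrich([1, 2], background20, coll, p_threshold=1.0)
        assert [r.set_id for r in report.rows] == ["aa", "zz"]

    def test_over_direction_implies_upper_tail_below_half(self, background20):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(21)
        coll = GeneSetCollection("t", 9606, [
            GeneSet(f"s{i}", "x",
                    frozenset(int(g) for g in rng.choice(20, size=6, replace=False) + 1))
            for i in range(10)
        ])
        test = [int(g) for g in rng.choice(20, size=8, replace=False) + 1]
        report = enrich(test, background20, coll, p_threshold=1.0)
        for r in report.rows:
            if r.direction == "over" and r.count * 20 != r.set_size * r.test_size:
                upper = hypergeom.sf(r.count - 1, 20, r.set_size, r.test_size)
                assert upper <= 0.5

    def test_membership_lists_intersections(self, toy_collection, background20):
        report = enrich([1, 2, 16], background20, toy_collection, p_threshold=1.0)
        assert report.members["pathA"] == [1, 2]


class TestQuerySetVsCollection:
    def test_source_must_be_in_source_collection(self, toy_collection):
        with pytest.raises(InputError):
            query_set_vs_collection("missing", toy_collection, toy_collection)

    def test_disjoint_source_is_empty_test_error(self, toy_collection):
        src = GeneSetCollection("src", 9606, [GeneSet("far", "x", frozenset({99}))])
        with pytest.raises(InputError):
            query_set_vs_collection("far", src, toy_collection)

    def test_identical_set_and_universe_gives_p_one(self):
        target = GeneSetCollection("t", 9606, [GeneSet("T", "x", frozenset({1, 2, 3}))])
        src = GeneSetCollection("s", 9606, [GeneSet("S", "x", frozenset({1, 2, 3}))])
        report = query_set_vs_collection("S", src, target, p_threshold=1.0)
        assert len(report.rows) == 1 and report.rows[0].p_value == 1.0

    def test_planted_overlap_ranks_first(self):
        rng = np.random.default_rng(13)
        universe = np.arange(1, 501)
        overlap = frozenset(range(1, 41))
        target_sets = [GeneSet("hit", "planted overlap", overlap | frozenset({100, 101}))]
        for i in range(9):
            members = frozenset(int(g) for g in rng.choice(universe[60:], 40, replace=False))
            target_sets.append(GeneSet(f"bg{i}", "x", members))
        target = GeneSetCollection("t", 9606, target_sets)
        src = GeneSetCollection("s", 9606, [GeneSet("S", "x", overlap)])
        report = query_set_vs_collection("S", src, target)
        assert report.rows[0].set_id == "hit" and report.rows[0].direction == "over"

    def test_explicit_background_override(self, toy_collection):
        src = GeneSetCollection("s", 9606, [GeneSet("S", "x", frozenset({1, 2}))])
        report = query_set_vs_collection("S", src, toy_collection,
                                         background=range(1, 21), p_threshold=1.0)
        assert report.rows[0].background_size == 20
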