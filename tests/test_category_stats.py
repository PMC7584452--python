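"""Rank tests, FDR correction, and hypergeometric overlap enrichment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from topsignal.category_stats import (
    CategoryMap,
    benjamini_yekutieli,
    category_topscore_analysis,
    hypergeometric_upper_tail,
    mann_whitney_u,
    overlap_enrichment,
)
from topsignal.topscore import TopScoreRecord


def exact_u_distribution(nx: int, ny: int) -> dict[int, float]:
    """Null distribution of U_x by enumerating all C(nx+ny, nx) labelings."""
    n = nx + ny
    dist: dict[int, int] = {}
    for x_pos in itertools.combinations(range(n), nx):
        # ranks are 0..n-1; U = rank sum of x minus its minimum
        u = sum(x_pos) - nx * (nx - 1) // 2
        dist[u] = dist.get(u, 0) + 1
    total = math.comb(n, nx)
    return {u: c / total for u, c in dist.items()}


def exact_two_sided_p(nx: int, ny: int, u: float) -> float:
    dist = exact_u_distribution(nx, ny)
    lower = sum(p for v, p in dist.items() if v <= u)
    upper = sum(p for v, p in dist.items() if v >= u)
    return min(1.0, 2 * min(lower, upper))


class TestMannWhitney:
    def test_complete_separation_gives_u_zero(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.direction == "lower"

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_interleaved_pair_against_enumeration(self):
        res = mann_whitney_u([1, 3], [2, 4])
        assert res.u_statistic == 1
        assert res.p == pytest.approx(exact_two_sided_p(2, 2, 1))  # = 2/3

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=60, deadline=None)
    @given(
        x=st.lists(st.integers(0, 20), min_size=1, max_size=12),
        y=st.lists(st.integers(0, 20), min_size=1, max_size=12),
    )
    def test_u_statistics_sum_to_pair_count(self, x, y):
        ux = mann_whitney_u(x, y).u_statistic
        uy = mann_whitney_u(y, x).u_statistic
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_and_normal_p_agree_for_balanced_eights(self):
        from scipy.stats import norm

        rng = np.random.default_rng(5)
        for _ in range(25):
            pooled = rng.permutation(np.arange(16, dtype=float))
            x, y = pooled[:8], pooled[8:]
            res = mann_whitney_u(x, y)  # n = 16, tieless -> exact path
            approx_p = min(1.0, 2 * norm.sf(abs(res.z)))
            assert abs(res.p - approx_p) < 0.02


class TestBenjaminiYekutieli:
    def test_single_p_is_unchanged(self):
        assert benjamini_yekutieli([0.03]) == pytest.approx([0.03])

    def test_two_p_closed_form(self):
        # c(2) = 1.5: (0.01*2*1.5/1, 0.04*2*1.5/2) = (0.03, 0.06)
        adjusted = benjamini_yekutieli([0.01, 0.04])
        assert adjusted == pytest.approx([0.03, 0.06])

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError):
            benjamini_yekutieli([0.0, 0.5])
        with pytest.raises(ValueError):
            benjamini_yekutieli([1.5])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_by_dominates_bh_dominates_raw(self, p_values):
        p = np.asarray(p_values)
        by = benjamini_yekutieli(p)
        # independent BH step-up oracle
        order = np.argsort(p)
        m = len(p)
        bh_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        bh = np.minimum(1.0, bh_sorted)[np.argsort(order)]
        assert np.all(by >= bh - 1e-12)
        assert np.all(bh >= p - 1e-12)

    def test_monotone_along_sorted_order(self, rng):
        p = rng.uniform(1e-4, 1, 40)
        adjusted = benjamini_yekutieli(p)
        assert np.all(np.diff(adjusted[np.argsort(p)]) >= -1e-12)


def enumeration_upper_tail(N, K, n, k):
    """P(|A ∩ draw| >= k) by exact counting over all C(N, n) draws."""
    total = math.comb(N, n)
    favourable = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return favourable / total


class TestHypergeometric:
    def test_zero_overlap_tail_is_one(self):
        assert hypergeometric_upper_tail(10, 4, 5, 0) == 1.0

    def test_above_max_overlap_tail_is_zero(self):
        assert hypergeometric_upper_tail(10, 4, 5, 5) == 0.0

    def test_small_case_against_enumeration(self):
        assert hypergeometric_upper_tail(10, 4, 5, 3) == pytest.approx(66 / 252)

    def test_bounds_violations(self):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(10, 11, 5, 0)
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(10, 4, 5, 6)

    @settings(max_examples=80, deadline=None)
    @given(
        N=st.integers(1, 20),
        data=st.data(),
    )
    def test_matches_enumeration_oracle(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeometric_upper_tail(N, K, n, k) == pytest.approx(
            enumeration_upper_tail(N, K, n, k), abs=1e-12
        )


class TestOverlapEnrichment:
    def test_identical_sets_degenerate(self):
        universe = {f"p{i}" for i in range(8)}
        res = overlap_enrichment(universe, universe, universe)
        assert res.overlap == 8
        assert res.expected == pytest.approx(8.0)
        assert res.p_upper == pytest.approx(1.0)
        assert not res.exceeds_twice_expected

    def test_disjoint_sets(self):
        universe = {f"p{i}" for i in range(100)}
        a = {f"p{i}" for i in range(10)}
        b = {f"p{i}" for i in range(50, 60)}
        res = overlap_enrichment(a, b, universe)
        assert res.overlap == 0
        assert res.p_upper == pytest.approx(1.0)

    def test_constructed_overlap_against_enumeration(self):
        universe = {f"p{i}" for i in range(12)}
        a = {f"p{i}" for i in range(5)}
        b = {f"p{i}" for i in range(3, 9)}
        res = overlap_enrichment(a, b, universe)
        assert res.overlap == 2
        assert res.expected == pytest.approx(6 * 5 / 12)
        assert res.p_upper == pytest.approx(enumeration_upper_tail(12, 5, 6, 2))

    def test_membership_violation(self):
        with pytest.raises(ValueError, match="outside the universe"):
            overlap_enrichment({"x"}, {"a"}, {"a", "b"})


def scored(scores):
    return [
        TopScoreRecord(f"g{i}", float(s), 100, 1) for i, s in enumerate(scores)
    ]


class TestCategoryAnalysis:
    def test_top_half_category_is_significantly_higher(self, rng):
        scores = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(5, 6, 30)])
        records = scored(scores)
        top_half = frozenset(r.gene_id for r in records[30:])
        categories = CategoryMap(members={"top": top_half}, names={"top": "Top"})
        (res,) = category_topscore_analysis(categories, records)
        assert res.direction == "higher"
        assert res.p_adj < 1e-6

    def test_small_category_skipped(self, rng):
        records = scored(rng.uniform(0, 5, 40))
        categories = CategoryMap(
            members={"tiny": frozenset({"g0", "g1"})}, names={"tiny": "Tiny"}
        )
        assert category_topscore_analysis(categories, records, min_size=5) == []

    def test_adjustment_family_is_all_tested_categories(self, rng):
        records = scored(rng.uniform(0, 5, 60))
        members = {
            f"c{j}": frozenset(rng.choice([r.gene_id for r in records], 10,
                                          replace=False))
            for j in range(6)
        }
        results = category_topscore_analysis(
            CategoryMap(members=members, names={}), records
        )
        assert len(results) == 6
        assert all(r.m_tests == 6 for r in results)
        assert all(r.p_adj >= r.p - 1e-12 for r in results)
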