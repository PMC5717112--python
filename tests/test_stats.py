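"""Mann-Whitney machinery, p-value maps and group tables."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flow4d.atlas import CohortMap
from flow4d.core import ParameterError, StatsError, HemodynamicSummary
from flow4d.stats import (
    _u_pmf,
    compare_group_summaries,
    mann_whitney_u,
    pvalue_map,
    significance_fractions,
)


def enumeration_u_counts(n1: int, n2: int) -> np.ndarray:
    """Independent oracle: count arrangements per U value by brute-force
    enumeration of all rank subsets."""
    N = n1 + n2
    counts = np.zeros(n1 * n2 + 1)
    for ranks in itertools.combinations(range(1, N + 1), n1):
        u = sum(ranks) - n1 * (n1 + 1) // 2
        counts[u] += 1
    return counts


class TestExactDistribution:
    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 2), (5, 5), (6, 4)])
    def test_pmf_matches_enumeration(self, n1, n2):
        oracle = enumeration_u_counts(n1, n2)
        np.testing.assert_allclose(_u_pmf(n1, n2), oracle / oracle.sum(), atol=1e-12)

    def test_three_vs_three_extreme(self):
        # x fully below y: U = 0, two-sided p = 2 / C(6,3) = 0.10
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(2 / comb(6, 3))

    def test_fourteen_vs_fourteen_extreme(self):
        u, p = mann_whitney_u(np.arange(1, 15), np.arange(15, 29), method="exact")
        assert u == 0
        assert p == pytest.approx(2 / comb(28, 14), rel=1e-9)

    def test_identical_samples_p_one(self):
        x = [2.0, 2.0, 2.0]
        u, p = mann_whitney_u(x, x)
        assert p == 1.0

    def test_exact_requires_no_ties(self):
        with pytest.raises(ParameterError):
            mann_whitney_u([1, 1, 2], [3, 4, 5], method="exact")


class TestProperties:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_u_sum(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, 2)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        ux, px = mann_whitney_u(x, y)
        uy, py = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(n1 * n2)
        assert px == pytest.approx(py, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6), rng.normal(size=7)
        _, p0 = mann_whitney_u(x, y)
        f = lambda v: np.exp(3 * v) - 5  # strictly increasing
        _, p1 = mann_whitney_u(f(x), f(y))
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_exact_close_to_asymptotic_8v8(self):
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(50):
            x, y = rng.normal(size=8), rng.normal(size=8)
            _, pe = mann_whitney_u(x, y, method="exact")
            _, pa = mann_whitney_u(x, y, method="asymptotic")
            worst = max(worst, abs(pe - pa))
        assert worst < 0.02

    def test_matches_scipy_exact(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        for _ in range(50):
            n1, n2 = rng.integers(2, 8, 2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            u, p = mann_whitney_u(x, y, method="exact")
            ref = mannwhitneyu(x, y, method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


def make_cohort(shared, values):
    return CohortMap(values, shared, "voxel")


class TestPValueMap:
    def test_min_n_rule(self, cube_shared):
        n = cube_shared.n_voxel_locations
        rng = np.random.default_rng(0)
        a = rng.normal(size=(14, n))
        b = rng.normal(size=(14, n))
        a[6:, 0] = np.nan  # only 6 subjects at location 0
        pm = pvalue_map(make_cohort(cube_shared, a), make_cohort(cube_shared, b), min_n=7)
        assert not pm.testable[0]
        assert np.isnan(pm.p[0])
        assert pm.testable[1:].all()

    def test_planted_effect_detected_with_direction(self, cube_shared):
        n = cube_shared.n_voxel_locations
        rng = np.random.default_rng(1)
        a = rng.normal(size=(14, n))
        b = rng.normal(size=(14, n))
        planted = np.zeros(n, bool)
        planted[:50] = True
        b[:, planted] += 10.0
        pm = pvalue_map(make_cohort(cube_shared, a), make_cohort(cube_shared, b))
        assert pm.significant[planted].all()
        assert np.all(pm.direction[planted] == 1)

    def test_no_testable_locations_raises(self, cube_shared):
        n = cube_shared.n_voxel_locations
        a = np.full((3, n), 1.0)
        b = np.full((3, n), 2.0)
        with pytest.raises(StatsError):
            pvalue_map(make_cohort(cube_shared, a), make_cohort(cube_shared, b), min_n=7)

    def test_fdr_is_more_conservative(self, cube_shared):
        n = cube_shared.n_voxel_locations
        rng = np.random.default_rng(3)
        a = rng.normal(size=(14, n))
        b = rng.normal(size=(14, n))
        pm = pvalue_map(make_cohort(cube_shared, a), make_cohort(cube_shared, b))
        pm_fdr = pvalue_map(make_cohort(cube_shared, a), make_cohort(cube_shared, b), fdr=True)
        assert pm_fdr.significant.sum() <= pm.significant.sum()
        assert np.all(pm_fdr.p[pm.testable] >= pm.p[pm.testable] - 1e-12)


class TestSignificanceFractions:
    def _pmap(self, cube_shared, p, direction):
        from flow4d.stats import PValueMap

        return PValueMap(
            p=p, direction=direction, testable=~np.isnan(p), alpha=0.05,
            domain="voxel", shared=cube_shared,
        )

    def test_two_of_ten(self, cube_shared):
        n = cube_shared.n_voxel_locations
        p = np.full(n, np.nan)
        d = np.zeros(n, int)
        p[:10] = 0.5
        p[:2] = 0.01
        d[:2] = 1
        fr = significance_fractions(self._pmap(cube_shared, p, d))
        assert fr["positive_pct"] == pytest.approx(20.0)
        assert fr["negative_pct"] == 0.0

    def test_none_significant(self, cube_shared):
        n = cube_shared.n_voxel_locations
        p = np.full(n, 0.5)
        fr = significance_fractions(self._pmap(cube_shared, p, np.zeros(n, int)))
        assert fr["positive_pct"] == 0.0 and fr["negative_pct"] == 0.0

    def test_all_one_direction(self, cube_shared):
        n = cube_shared.n_voxel_locations
        p = np.full(n, 0.001)
        fr = significance_fractions(self._pmap(cube_shared, p, -np.ones(n, int)))
        assert fr["negative_pct"] == pytest.approx(100.0)
        assert fr["positive_pct"] == 0.0


def summaries(values):
    return [
        HemodynamicSummary(
            peak_velocity=v, mean_velocity=v / 2, mean_wss=0.6, energy_loss=e, peak_frame=4
        )
        for v, e in values
    ]


class TestGroupTable:
    def test_identical_groups_p_one(self):
        g = summaries([(2.0, 8.0), (2.1, 9.0), (2.2, 10.0)])
        table = compare_group_summaries(g, g)
        assert np.allclose(table["p"], 1.0)

    def test_planted_el_shift(self):
        rng = np.random.default_rng(4)
        base = [(2.0 + 0.1 * rng.normal(), 8.0 + rng.normal()) for _ in range(14)]
        ga = summaries(base)
        gb = summaries([(v, e + 10.0) for v, e in base])
        table = compare_group_summaries(ga, gb)
        assert table.loc["energy_loss", "p"] < 0.05
        assert table.loc["energy_loss", "median_B"] - table.loc["energy_loss", "median_A"] == pytest.approx(10.0)

    def test_consistent_with_mann_whitney(self):
        ga = summaries([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        gb = summaries([(4.0, 4.0), (5.0, 5.0), (6.0, 6.0)])
        table = compare_group_summaries(ga, gb)
        assert table.loc["peak_velocity", "p"] == pytest.approx(0.10)
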