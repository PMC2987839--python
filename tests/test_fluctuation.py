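"""Fluctuation-analysis estimators against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutlab import (
    CultureSet,
    RateEstimate,
    ci_overlap,
    estimate_rate,
    ld_pmf,
    lea_coulson_m,
    mle_m,
    relative_rate,
)
from mutlab.simulate import SimulationConfig, simulate_cultures

from conftest import ld_sample


def bisect_lea_coulson(r: float) -> float:
    """Independent bisection oracle for r/m - ln m = 1.24."""
    lo, hi = 1e-6, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if r / mid - math.log(mid) - 1.24 > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestLeaCoulson:
    def test_unit_root(self):
        # at m = 1 the equation reads r = 1.24
        assert lea_coulson_m(1.24) == pytest.approx(1.0, rel=1e-9)

    def test_zero_median_maps_to_zero(self):
        assert lea_coulson_m(0) == 0.0

    @pytest.mark.parametrize("r", [1.0, 2.5, 5.0, 12.0, 35.0, 200.0])
    def test_matches_bisection_oracle(self, r):
        assert lea_coulson_m(r) == pytest.approx(bisect_lea_coulson(r), rel=1e-6)

    def test_median_five(self):
        assert lea_coulson_m(5) == pytest.approx(2.375, abs=5e-3)

    def test_negative_median_rejected(self):
        with pytest.raises(ValueError):
            lea_coulson_m(-1)

    @given(
        st.tuples(
            st.floats(min_value=1.0, max_value=500.0),
            st.floats(min_value=1.0, max_value=500.0),
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_median(self, pair):
        r1, r2 = sorted(pair)
        if r2 - r1 > 1e-6:
            assert lea_coulson_m(r1) < lea_coulson_m(r2)


class TestLdPmf:
    def test_zero_class_is_poisson(self):
        assert ld_pmf(1.0, 0)[0] == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_first_recursion_step_by_hand(self):
        # p1 = (m/1) * p0 / 2
        p = ld_pmf(1.0, 1)
        assert p[1] == pytest.approx(p[0] / 2.0, rel=1e-12)

    @pytest.mark.parametrize("m", [0.5, 1.0, 2.0, 5.0])
    def test_normalization_head_mass(self, m):
        p = ld_pmf(m, 10_000)
        csum = np.cumsum(p)
        assert np.all(np.diff(csum) >= 0)
        assert csum[-1] <= 1.0 + 1e-12
        assert csum[-1] > 0.99

    def test_rejects_nonpositive_m(self):
        with pytest.raises(ValueError):
            ld_pmf(0.0, 10)


class TestMle:
    def test_all_zero_counts(self):
        with pytest.warns(UserWarning):
            assert mle_m([0] * 20) == 0.0

    def test_recovers_m_from_large_sample(self):
        rng = np.random.default_rng(42)
        counts = ld_sample(2.0, 1000, rng)
        assert 1.8 <= mle_m(counts) <= 2.2

    def test_single_count_matches_grid_search(self):
        grid = np.linspace(0.01, 20, 4000)
        ll = [math.log(ld_pmf(m, 3)[3]) for m in grid]
        best = grid[int(np.argmax(ll))]
        assert mle_m([3]) == pytest.approx(best, abs=0.02)


class TestEstimateRate:
    def test_all_zero_counts_fall_back_to_p0(self):
        cs = CultureSet("s", "l", (0,) * 9, 1e8)
        est = estimate_rate(cs, "median")
        assert est.method == "p0"
        assert est.rate == 0.0
        assert est.ci_low == 0.0

    def test_rate_recovery_from_simulation(self):
        cfg = SimulationConfig(seed=5, mu=1e-7, n0=1e3, nt=1e8, n_cultures=45)
        est = estimate_rate(simulate_cultures(cfg), "median")
        assert 0.5e-7 <= est.rate <= 2e-7

    def test_rate_scales_inversely_with_nt(self):
        counts = (0, 1, 3, 5, 2, 8, 4, 1, 2)
        a = estimate_rate(CultureSet("s", "l", counts, 1e8))
        b = estimate_rate(CultureSet("s", "l", counts, 2e8))
        assert b.rate == pytest.approx(a.rate / 2.0, rel=1e-12)
        assert b.ci_high == pytest.approx(a.ci_high / 2.0, rel=1e-12)

    def test_all_jackpot_rejected(self):
        with pytest.raises(ValueError, match="jackpot"):
            estimate_rate(CultureSet("s", "l", (100, 100), 100))

    def test_mle_method_consistent_with_median(self):
        rng = np.random.default_rng(0)
        counts = tuple(int(c) for c in ld_sample(3.0, 45, rng))
        med = estimate_rate(CultureSet("s", "l", counts, 1e8), "median")
        ml = estimate_rate(CultureSet("s", "l", counts, 1e8), "mle")
        assert ml.method == "mle"
        assert ml.ci_low <= ml.rate <= ml.ci_high
        assert abs(med.m - ml.m) / ml.m < 0.5

    def test_p0_needs_a_zero_culture(self):
        with pytest.raises(ValueError, match="p0"):
            estimate_rate(CultureSet("s", "l", (1, 2, 3), 1e8), "p0")


class TestRelativeRateRounding:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (74.3, 10.1, 7.4),
            (2720, 12.9, 211),
            (10.0, 10.0, 1.0),
        ],
    )
    def test_published_convention(self, num, den, expected):
        assert relative_rate(num, den) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_rate(1.0, 0.0)


def _est(lo, hi):
    rate = 0.5 * (lo + hi)
    return RateEstimate(0.0, rate, lo, hi, 9, "median")


class TestCiOverlap:
    def test_disjoint_published_intervals(self):
        # wt Canr vs dpb3-null Canr
        assert ci_overlap(_est(3.9, 14.6), _est(72.2, 95.2)) is False

    def test_identical_intervals(self):
        assert ci_overlap(_est(1, 2), _est(1, 2)) is True

    def test_shared_endpoint_counts_as_overlap(self):
        assert ci_overlap(_est(0.5, 1.0), _est(1.0, 2.0)) is True


class TestInvariantsAtScale:
    """Slower statistical properties of the estimators."""

    def test_median_and_mle_agree_on_simulated_sets(self):
        # 200 culture sets across a realistic range of m; the two
        # estimators should agree within 30% for at least 95% of sets.
        rng = np.random.default_rng(42)
        ok = tot = 0
        for m_true in (0.5, 1.0, 2.0, 5.0):
            for _ in range(50):
                counts = ld_sample(m_true, 45, rng)
                med = estimate_rate(
                    CultureSet("s", "l", tuple(int(c) for c in counts), 1e8), "median"
                ).m
                ml = mle_m(counts)
                tot += 1
                if ml == 0 or med == 0:
                    ok += med == ml
                else:
                    ok += abs(med - ml) / ml <= 0.30
        assert ok / tot >= 0.95

    def test_ci_coverage_of_true_rate(self):
        # rank-based CI on the median is approximate; demand >= 85%
        mu = 1e-7
        cover = 0
        n_rep = 500
        for rep in range(n_rep):
            cfg = SimulationConfig(
                seed=20_000 + rep, mu=mu, n0=1e3, nt=1e8, n_cultures=27
            )
            est = estimate_rate(simulate_cultures(cfg), "median")
            cover += est.ci_low <= mu <= est.ci_high
        assert cover / n_rep >= 0.85
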