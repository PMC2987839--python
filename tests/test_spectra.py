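"""Mutation-spectrum representation and homogeneity testing."""

import numpy as np
import pytest
from scipy import stats

from mutlab import (
    MutationSpectrum,
    collapse,
    mc_homogeneity,
    pearson_chi2,
    percentages,
    spectrum_correlation,
)


def exact_2x2_p(table) -> float:
    """Exact conditional p by hypergeometric enumeration (2x2 oracle)."""
    (a, b), (c, d) = table
    n1, col1, total = a + b, a + c, a + b + c + d
    pooled = np.array([col1, total - col1], dtype=float)

    def chi2(x1: int) -> float:
        row1 = np.array([x1, n1 - x1], dtype=float)
        e1 = pooled * n1 / total
        e2 = pooled * (total - n1) / total
        return float(((row1 - e1) ** 2 / e1 + (pooled - row1 - e2) ** 2 / e2).sum())

    obs = chi2(a)
    kmin, kmax = max(0, n1 - (total - col1)), min(n1, col1)
    return float(
        sum(
            stats.hypergeom.pmf(k, total, col1, n1)
            for k in range(kmin, kmax + 1)
            if chi2(k) >= obs - 1e-9
        )
    )


class TestPearsonChi2:
    def test_invitro_2x4_statistic(self, invitro):
        a, b = invitro
        # hand-checkable 2x4 Pearson statistic of the published counts
        assert pearson_chi2(a, b) == pytest.approx(12.258, abs=1e-3)

    def test_matches_scipy_contingency(self, invitro):
        a, b = invitro
        expected = stats.chi2_contingency(
            np.array([a.counts, b.counts]), correction=False
        ).statistic
        assert pearson_chi2(a, b) == pytest.approx(expected, rel=1e-12)

    def test_identical_spectra_are_zero(self):
        s = MutationSpectrum("x", ("a", "b"), (10, 10))
        assert pearson_chi2(s, s) == 0.0

    def test_mismatched_categories_rejected(self):
        s1 = MutationSpectrum("x", ("a", "b"), (1, 2))
        s2 = MutationSpectrum("y", ("a", "c"), (1, 2))
        with pytest.raises(ValueError):
            pearson_chi2(s1, s2)

    def test_zero_pooled_category_dropped(self):
        s1 = MutationSpectrum("x", ("a", "b", "c"), (5, 0, 5))
        s2 = MutationSpectrum("y", ("a", "b", "c"), (5, 0, 5))
        assert pearson_chi2(s1, s2) == 0.0
        with pytest.raises(ValueError):
            pearson_chi2(
                MutationSpectrum("x", ("a", "b"), (5, 0)),
                MutationSpectrum("y", ("a", "b"), (5, 0)),
            )


class TestMcHomogeneity:
    def test_identical_spectra_give_p_one(self):
        s = MutationSpectrum("x", ("a", "b"), (10, 10))
        assert mc_homogeneity(s, s, B=500, seed=0).p_value == 1.0

    def test_seed_reproducibility(self, invitro):
        a, b = invitro
        r1 = mc_homogeneity(a, b, B=5000, seed=17)
        r2 = mc_homogeneity(a, b, B=5000, seed=17)
        assert r1.p_value == r2.p_value
        assert r1.chi2_observed == r2.chi2_observed

    def test_addone_pvalue_form(self, invitro):
        a, b = invitro
        res = mc_homogeneity(a, b, B=999, seed=3)
        k = round(res.p_value * (1 + res.n_resamples)) - 1
        assert 0 <= k <= res.n_resamples
        assert res.p_value == pytest.approx((1 + k) / (1 + res.n_resamples))

    def test_seed_required_and_b_validated(self, invitro):
        a, b = invitro
        with pytest.raises(ValueError):
            mc_homogeneity(a, b, B=100)
        with pytest.raises(ValueError):
            mc_homogeneity(a, b, B=0, seed=1)

    def test_swap_and_order_invariance_in_distribution(self, invitro):
        a, b = invitro
        perm = (2, 0, 3, 1)
        ap = MutationSpectrum(
            "a", tuple(a.categories[i] for i in perm), tuple(a.counts[i] for i in perm)
        )
        bp = MutationSpectrum(
            "b", tuple(b.categories[i] for i in perm), tuple(b.counts[i] for i in perm)
        )
        p_ref = mc_homogeneity(a, b, B=40_000, seed=5).p_value
        p_swap = mc_homogeneity(b, a, B=40_000, seed=6).p_value
        p_perm = mc_homogeneity(ap, bp, B=40_000, seed=7).p_value
        assert p_swap == pytest.approx(p_ref, abs=0.004)
        assert p_perm == pytest.approx(p_ref, abs=0.004)

    def test_matches_exact_enumeration_on_2x2(self):
        rng = np.random.default_rng(3)
        for trial in range(4):
            tab = rng.integers(1, 6, size=(2, 2))
            s1 = MutationSpectrum("1", ("x", "y"), tuple(int(v) for v in tab[0]))
            s2 = MutationSpectrum("2", ("x", "y"), tuple(int(v) for v in tab[1]))
            p_mc = mc_homogeneity(s1, s2, B=200_000, seed=trial).p_value
            assert p_mc == pytest.approx(exact_2x2_p(tab.tolist()), abs=0.005)


class TestCollapseAndPercentages:
    def test_drop_other_from_invitro(self, invitro):
        _, b = invitro
        assert collapse(b, ["other"]).counts == (229, 35, 7)

    def test_drop_nothing_is_identity(self, invitro):
        a, _ = invitro
        assert collapse(a, []) == a

    def test_unknown_category_rejected(self, invitro):
        a, _ = invitro
        with pytest.raises(ValueError):
            collapse(a, ["nonexistent"])

    def test_collapse_to_one_category_fails_on_test_use(self, invitro):
        a, b = invitro
        a1 = collapse(a, ["-1 frameshifts", "+1 frameshifts", "other"])
        b1 = collapse(b, ["-1 frameshifts", "+1 frameshifts", "other"])
        with pytest.raises(ValueError):
            pearson_chi2(a1, b1)

    def test_published_percentages(self, can1):
        wt = can1["wt"]
        pct = dict(zip(wt.categories, percentages(wt)))
        assert pct["GC->CG"] == pytest.approx(25.0)
        dd = can1["dpb3d dpb4d"]
        pct_dd = dict(zip(dd.categories, percentages(dd)))
        assert pct_dd["-1 frameshifts"] == pytest.approx(18.4)

    def test_unrounded_percentages_sum_to_100(self, can1):
        for s in can1.values():
            assert (100.0 * s.proportions()).sum() == pytest.approx(100.0)


class TestSpectrumCorrelation:
    def test_identical_spectra(self, can1):
        wt = can1["wt"]
        assert spectrum_correlation(wt, wt) == pytest.approx(1.0)

    def test_reversed_proportions(self):
        s1 = MutationSpectrum("x", ("a", "b", "c"), (5, 3, 2))
        s2 = MutationSpectrum("y", ("a", "b", "c"), (2, 3, 5))
        # direct formula on proportions (.5,.3,.2) vs (.2,.3,.5)
        assert spectrum_correlation(s1, s2) == pytest.approx(-0.9286, abs=1e-3)

    def test_zero_variance_rejected(self):
        s1 = MutationSpectrum("x", ("a", "b", "c"), (5, 5, 5))
        s2 = MutationSpectrum("y", ("a", "b", "c"), (1, 2, 3))
        with pytest.raises(ValueError):
            spectrum_correlation(s1, s2)

    def test_two_categories_excluded(self):
        s1 = MutationSpectrum("x", ("a", "b"), (5, 3))
        with pytest.raises(ValueError):
            spectrum_correlation(s1, s1)
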