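"""Mutation spectra and Monte Carlo homogeneity testing.

A mutation spectrum is a vector of counts of independent mutants by class
(base-substitution types, +/-1 frameshifts, complex, other).  Two spectra
are compared as a 2xN contingency table with the Pearson chi-square
statistic; because class counts are small, the null distribution is
obtained by Monte Carlo rather than the chi-square approximation.

The resampling scheme conditions on both margins: the pooled mutants are
randomly partitioned into two groups of the observed sizes, i.e. each
null table row is a multivariate hypergeometric draw.  The p-value uses
the add-one estimator ``p = (1 + #{chi2* >= chi2_obs}) / (1 + B)``, so it
is never exactly zero.  A small p (<= 0.05) indicates the two spectra
differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MutationSpectrum",
    "HomogeneityResult",
    "pearson_chi2",
    "mc_homogeneity",
    "collapse",
    "percentages",
    "spectrum_correlation",
]


@dataclass(frozen=True)
class MutationSpectrum:
    """Labelled per-class mutant counts for one strain or enzyme."""

    label: str
    categories: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        cats = tuple(str(c) for c in self.categories)
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "counts", counts)
        if len(cats) < 1:
            raise ValueError("spectrum needs at least one category")
        if len(cats) != len(counts):
            raise ValueError("categories and counts differ in length")
        if len(set(cats)) != len(cats):
            raise ValueError("duplicate category names")
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts)

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("spectrum total is zero")
        return np.asarray(self.counts, dtype=float) / self.total


@dataclass(frozen=True)
class HomogeneityResult:
    """Outcome of the Monte Carlo Pearson chi-square homogeneity test."""

    chi2_observed: float
    p_value: float
    n_resamples: int
    seed: int
    categories_used: tuple[str, ...]

    @property
    def significant(self) -> bool:
        """Spectra called different at the conventional 0.05 level."""
        return self.p_value <= 0.05


def _aligned_table(
    s1: MutationSpectrum, s2: MutationSpectrum
) -> tuple[np.ndarray, tuple[str, ...]]:
    """2xN count table over the shared categories, dropping categories
    whose pooled count is zero (the chi-square is undefined there)."""
    if s1.categories != s2.categories:
        raise ValueError(
            f"category lists differ: {s1.categories} vs {s2.categories}"
        )
    table = np.array([s1.counts, s2.counts], dtype=np.int64)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    cats = tuple(c for c, k in zip(s1.categories, keep) if k)
    if table.shape[1] < 2:
        raise ValueError("need at least 2 categories with non-zero pooled count")
    if table.sum(axis=1).min() <= 0:
        raise ValueError("each spectrum must have a positive total")
    return table, cats


def _chi2_rows(row1: np.ndarray, pooled: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Pearson chi-square for 2xN tables given the first row(s).

    ``row1`` has shape (..., N); expected counts come from the fixed
    margins, so the statistic is computed identically for the observed
    table and for every resampled table (exact tie handling)."""
    total = n1 + n2
    e1 = pooled * (n1 / total)
    e2 = pooled * (n2 / total)
    row2 = pooled - row1
    return ((row1 - e1) ** 2 / e1 + (row2 - e2) ** 2 / e2).sum(axis=-1)


def pearson_chi2(s1: MutationSpectrum, s2: MutationSpectrum) -> float:
    """Pearson chi-square statistic of the 2xN table of two spectra."""
    table, _ = _aligned_table(s1, s2)
    pooled = table.sum(axis=0)
    n1, n2 = int(table[0].sum()), int(table[1].sum())
    return float(_chi2_rows(table[0].astype(float), pooled.astype(float), n1, n2))


def mc_homogeneity(
    s1: MutationSpectrum,
    s2: MutationSpectrum,
    B: int = 100_000,
    seed: "int | None" = None,
    batch_size: int = 200_000,
) -> HomogeneityResult:
    """Monte Carlo Pearson chi-square test of spectrum homogeneity.

    Under the null hypothesis that both spectra are draws from one
    multinomial, the pooled mutants are partitioned uniformly at random
    into groups of sizes ``n1`` and ``n2`` (both margins fixed); the
    statistic of each of ``B`` such tables is compared to the observed
    one.  Reproducible given ``seed`` (required).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    table, cats = _aligned_table(s1, s2)
    pooled = table.sum(axis=0)
    n1, n2 = int(table[0].sum()), int(table[1].sum())
    obs = float(_chi2_rows(table[0].astype(float), pooled.astype(float), n1, n2))

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    thresh = obs - 1e-9  # guard float jitter on exact ties
    while done < B:
        nb = min(batch_size, B - done)
        draws = rng.multivariate_hypergeometric(pooled, n1, size=nb).astype(float)
        sim = _chi2_rows(draws, pooled.astype(float), n1, n2)
        exceed += int(np.count_nonzero(sim >= thresh))
        done += nb
    p = (1 + exceed) / (1 + B)
    return HomogeneityResult(
        chi2_observed=obs,
        p_value=p,
        n_resamples=B,
        seed=seed,
        categories_used=cats,
    )


def collapse(s: MutationSpectrum, drop: Sequence[str]) -> MutationSpectrum:
    """Remove the given categories (e.g. ``["Other"]``) from a spectrum."""
    drop_set = set(drop)
    unknown = drop_set - set(s.categories)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    keep = [(c, n) for c, n in zip(s.categories, s.counts) if c not in drop_set]
    return MutationSpectrum(
        label=s.label,
        categories=tuple(c for c, _ in keep),
        counts=tuple(n for _, n in keep),
    )


def percentages(s: MutationSpectrum, decimals: int = 1) -> np.ndarray:
    """Per-category percentages of the spectrum total, rounded."""
    return np.round(100.0 * s.proportions(), decimals)


def spectrum_correlation(s1: MutationSpectrum, s2: MutationSpectrum) -> float:
    """Pearson linear correlation of the two proportion vectors."""
    if s1.categories != s2.categories:
        raise ValueError("category lists differ")
    if len(s1.categories) < 3:
        raise ValueError("need at least 3 categories for a meaningful correlation")
    p1, p2 = s1.proportions(), s2.proportions()
    if np.ptp(p1) == 0 or np.ptp(p2) == 0:
        raise ValueError("correlation undefined for a zero-variance spectrum")
    return float(stats.pearsonr(p1, p2).statistic)
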