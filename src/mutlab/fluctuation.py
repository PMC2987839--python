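"""Luria-Delbruck fluctuation analysis.

Spontaneous mutation rates are measured by growing many parallel cultures
from small inocula and plating on selective medium.  Mutations arise at
random during growth; a mutation early in the expansion founds a large
mutant clone ("jackpot"), so the distribution of mutant counts across
cultures is the heavy-tailed Luria-Delbruck distribution, parameterised by
``m``, the expected number of mutation events per culture.  The per-cell
per-generation rate is ``m / Nt`` where ``Nt`` is the number of cells per
culture at plating.

Estimators provided:

``median``
    Lea-Coulson method of the median: the sample median mutant count
    ``r`` satisfies ``r/m - ln(m) = 1.24``; invert numerically.  This is
    the workhorse estimator for 9-45 culture assays.
``mle``
    Ma-Sandri-Sarkar maximum likelihood, using the exact recursion for
    the Luria-Delbruck probability mass function (:func:`ld_pmf`).
``p0``
    Zero-class method, ``m = -ln(P0)`` with ``P0`` the fraction of
    cultures with no mutants; the automatic fallback when the median is 0.

Confidence limits for the median method are distribution-free binomial
order-statistic bounds on the median count, mapped through the estimator.
Two rates are called significantly different when their 95% confidence
intervals do not overlap.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CultureSet",
    "RateEstimate",
    "lea_coulson_m",
    "ld_pmf",
    "mle_m",
    "estimate_rate",
    "relative_rate",
    "ci_overlap",
]

logger = logging.getLogger(__name__)

#: Constant of the Lea-Coulson median equation r/m - ln(m) = 1.24.
LEA_COULSON_CONSTANT = 1.24

Method = Literal["median", "mle", "p0"]


@dataclass(frozen=True)
class CultureSet:
    """Mutant counts from parallel cultures of one strain at one locus.

    Parameters
    ----------
    strain_label, locus_label
        Free-text identifiers (e.g. ``"wt"``, ``"CAN1"``).
    mutant_counts
        One non-negative mutant count per culture.
    n_final_cells
        Cells per culture at plating (``Nt``); every count must be <= Nt.
    plating_fraction
        Fraction of each culture plated, in (0, 1].  Default 1 (no
        dilution correction).
    """

    strain_label: str
    locus_label: str
    mutant_counts: tuple[int, ...]
    n_final_cells: float
    plating_fraction: float = 1.0

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.mutant_counts)
        object.__setattr__(self, "mutant_counts", counts)
        if len(counts) < 1:
            raise ValueError("CultureSet needs at least one culture")
        if self.n_final_cells <= 0:
            raise ValueError("n_final_cells must be positive")
        if not (0.0 < self.plating_fraction <= 1.0):
            raise ValueError("plating_fraction must be in (0, 1]")
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if any(c > self.n_final_cells for c in counts):
            raise ValueError("a mutant count exceeds n_final_cells")

    @property
    def n_cultures(self) -> int:
        return len(self.mutant_counts)

    @property
    def median_count(self) -> float:
        return float(np.median(self.mutant_counts))


@dataclass(frozen=True)
class RateEstimate:
    """A mutation-rate estimate with 95% confidence limits.

    ``rate = m / (Nt * plating_fraction)`` and
    ``ci_low <= rate <= ci_high`` always hold.
    """

    m: float
    rate: float
    ci_low: float
    ci_high: float
    n_cultures: int
    method: Method
    strain_label: str = ""
    locus_label: str = ""

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be non-negative")
        if not (0.0 <= self.ci_low <= self.rate <= self.ci_high):
            raise ValueError(
                "confidence limits must bracket the rate: "
                f"{self.ci_low} <= {self.rate} <= {self.ci_high} violated"
            )


def lea_coulson_m(median_count: float) -> float:
    """Invert the Lea-Coulson median equation ``r/m - ln(m) = 1.24``.

    For ``median_count >= 1`` the left-hand side is strictly decreasing
    in ``m``, so the root is unique; it is found to a relative tolerance
    of 1e-12.  A median of 0 returns 0: the zero-class (p0) method must
    be used instead, which :func:`estimate_rate` does automatically.
    """
    r = float(median_count)
    if r < 0:
        raise ValueError("median_count must be non-negative")
    if r == 0.0:
        return 0.0

    def f(m: float) -> float:
        return r / m - math.log(m) - LEA_COULSON_CONSTANT

    lo = 1e-12
    hi = max(4.0, r)
    while f(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(f, lo, hi, rtol=1e-12, maxiter=200))


def ld_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria-Delbruck probability mass function by the exact recursion.

    ``p[0] = exp(-m)`` and ``p[r] = (m/r) * sum_{i<r} p[i] / (r - i + 1)``.
    Returns ``p[0..r_max]``.  The full distribution sums to 1; the
    returned head sums to <= 1 and approaches 1 as ``r_max`` grows.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    r_max = int(r_max)
    if r_max < 0:
        raise ValueError("r_max must be non-negative")
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    if r_max == 0:
        return p
    # inv[k] = 1/(k+1); the weight on p[i] in the p[r] update is
    # 1/(r-i+1) = inv[r-i], i.e. inv[1:r+1] reversed against p[:r].
    inv = 1.0 / np.arange(1.0, r_max + 2.0)
    for r in range(1, r_max + 1):
        p[r] = (m / r) * float(np.dot(p[:r], inv[1 : r + 1][::-1]))
    return p


def _neg_loglik(m: float, counts: np.ndarray, max_count: int) -> float:
    """Negative log-likelihood with counts above ``max_count`` censored."""
    r_cap = int(min(counts.max(initial=0), max_count))
    p = ld_pmf(m, r_cap)
    ll = 0.0
    censored = 0
    for c in counts:
        if c > max_count:
            censored += 1
        else:
            ll += math.log(max(p[int(c)], 1e-300))
    if censored:
        tail = max(1.0 - p.sum(), 1e-300)
        ll += censored * math.log(tail)
    return -ll


def mle_m(counts: Sequence[int], max_count: int = 1000) -> float:
    """Ma-Sandri-Sarkar maximum-likelihood estimate of ``m``.

    Maximises the Luria-Delbruck likelihood over ``m`` by bounded 1-D
    search.  Jackpot counts above ``max_count`` are treated as censored
    (likelihood contribution = the tail mass beyond ``max_count``), which
    keeps the recursion affordable without discarding data.

    All-zero counts return 0 with a warning (the likelihood is maximised
    at the boundary).
    """
    arr = np.asarray(counts, dtype=np.int64)
    if arr.size < 1:
        raise ValueError("need at least one count")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr == 0).all():
        warnings.warn("all counts are zero; MLE of m is 0", stacklevel=2)
        return 0.0
    guess = lea_coulson_m(max(float(np.median(arr)), 1.0))
    hi = max(30.0, 5.0 * guess + 10.0)
    res = optimize.minimize_scalar(
        _neg_loglik,
        bounds=(1e-6, hi),
        args=(arr, max_count),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _median_rank_bounds(n: int, conf: float = 0.95) -> tuple[int, int]:
    """1-based order-statistic ranks (l, u) with
    ``P(x_(l) <= median <= x_(u)) >= conf`` under Binomial(n, 1/2)."""
    if n < 3:
        return 1, n
    alpha = (1.0 - conf) / 2.0
    # largest l with P(X <= l-1) <= alpha, X ~ Binomial(n, 1/2)
    l = int(stats.binom.ppf(alpha, n, 0.5))
    while l >= 1 and stats.binom.cdf(l - 1, n, 0.5) > alpha:
        l -= 1
    l = max(l, 1)
    u = n + 1 - l
    return l, u


def _p0_estimate(cultures: CultureSet, conf: float = 0.95) -> RateEstimate:
    counts = np.asarray(cultures.mutant_counts)
    n = counts.size
    n_zero = int((counts == 0).sum())
    if n_zero == 0:
        raise ValueError(
            "p0 method needs at least one zero-mutant culture; use median or mle"
        )
    denom = cultures.n_final_cells * cultures.plating_fraction
    m = -math.log(n_zero / n)
    # Clopper-Pearson interval on the zero-class fraction, mapped through -ln.
    alpha = 1.0 - conf
    p_lo = stats.beta.ppf(alpha / 2.0, n_zero, n - n_zero + 1) if n_zero > 0 else 0.0
    p_hi = (
        stats.beta.ppf(1.0 - alpha / 2.0, n_zero + 1, n - n_zero)
        if n_zero < n
        else 1.0
    )
    m_hi = -math.log(p_lo) if p_lo > 0 else math.inf
    m_lo = -math.log(p_hi) if p_hi < 1 else 0.0
    return RateEstimate(
        m=m,
        rate=m / denom,
        ci_low=m_lo / denom,
        ci_high=m_hi / denom,
        n_cultures=n,
        method="p0",
        strain_label=cultures.strain_label,
        locus_label=cultures.locus_label,
    )


def estimate_rate(cultures: CultureSet, method: Method = "median") -> RateEstimate:
    """Estimate the per-cell mutation rate from one fluctuation assay.

    ``median`` uses the Lea-Coulson median equation with a rank-based 95%
    confidence interval on the median count transformed through the
    estimator; when the median count is 0 it falls back to the p0 method
    (logged).  ``mle`` uses :func:`mle_m` with a profile-likelihood
    interval.  ``p0`` uses the zero-class fraction with Clopper-Pearson
    limits.
    """
    counts = np.asarray(cultures.mutant_counts)
    n = counts.size
    if (counts == cultures.n_final_cells).all():
        raise ValueError("every culture is a jackpot (count == Nt); rate not estimable")
    denom = cultures.n_final_cells * cultures.plating_fraction

    if method == "p0":
        return _p0_estimate(cultures)

    if method == "median":
        r_med = float(np.median(counts))
        if r_med == 0.0:
            logger.info(
                "median mutant count is 0 for %s/%s; falling back to p0 method",
                cultures.strain_label,
                cultures.locus_label,
            )
            return _p0_estimate(cultures)
        m = lea_coulson_m(r_med)
        srt = np.sort(counts)
        l, u = _median_rank_bounds(n)
        m_lo = lea_coulson_m(float(srt[l - 1]))
        m_hi = lea_coulson_m(float(srt[u - 1]))
        return RateEstimate(
            m=m,
            rate=m / denom,
            ci_low=min(m_lo, m) / denom,
            ci_high=max(m_hi, m) / denom,
            n_cultures=n,
            method="median",
            strain_label=cultures.strain_label,
            locus_label=cultures.locus_label,
        )

    if method == "mle":
        m_hat = mle_m(counts)
        if m_hat == 0.0:
            return replace(_p0_estimate(cultures), method="mle")
        # profile-likelihood 95% CI: loglik drop of chi2_{1,0.95}/2
        drop = stats.chi2.ppf(0.95, df=1) / 2.0
        nll_hat = _neg_loglik(m_hat, counts, 1000)

        def g(m: float) -> float:
            return (_neg_loglik(m, counts, 1000) - nll_hat) - drop

        lo_bracket = 1e-8
        m_lo = (
            optimize.brentq(g, lo_bracket, m_hat, xtol=1e-10)
            if g(lo_bracket) > 0
            else 0.0
        )
        hi_bracket = max(4.0 * m_hat, m_hat + 5.0)
        while g(hi_bracket) < 0:
            hi_bracket *= 2.0
        m_hi = optimize.brentq(g, m_hat, hi_bracket, xtol=1e-10)
        return RateEstimate(
            m=m_hat,
            rate=m_hat / denom,
            ci_low=m_lo / denom,
            ci_high=m_hi / denom,
            n_cultures=n,
            method="mle",
            strain_label=cultures.strain_label,
            locus_label=cultures.locus_label,
        )

    raise ValueError(f"unknown method {method!r}")


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def _rate_of(x: "RateEstimate | float") -> float:
    return float(x.rate) if isinstance(x, RateEstimate) else float(x)


def relative_rate(
    est: "RateEstimate | float",
    reference: "RateEstimate | float",
    sig_figs: int = 2,
) -> float:
    """Rate ratio vs a reference strain, rounded as in published tables.

    Ratios >= 100 are rounded to 3 significant figures (e.g. 211),
    ratios in [1, 100) to ``sig_figs`` (default 2) significant figures,
    and ratios below 1 to one decimal place (e.g. 0.3, 0.9) — the
    convention recovered from the printed rate tables.
    """
    ref = _rate_of(reference)
    if ref <= 0:
        raise ValueError("reference rate must be positive")
    ratio = _rate_of(est) / ref
    if ratio >= 100:
        return _round_sig(ratio, 3)
    if ratio >= 1:
        return _round_sig(ratio, sig_figs)
    return round(ratio, 1)


def ci_overlap(a: RateEstimate, b: RateEstimate) -> bool:
    """True iff the closed 95% CIs intersect (shared endpoint counts).

    Two rates are called significantly different when this is False.
    """
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
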