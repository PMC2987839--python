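# Methods

`mutlab` implements the four quantitative stages of a yeast
spontaneous-mutagenesis study — fluctuation-assay mutation rates,
mutation-spectrum homogeneity testing, lacZ fidelity error rates, and
polymerase/exonuclease processivity profiles — together with generators that
produce synthetic inputs with exactly the statistical structure each stage
assumes.

## Fluctuation analysis (`mutlab.fluctuation`)

**Model.** Parallel cultures grow from a small inoculum (`n0`) to `Nt` cells
and are plated on selective medium. Mutations arise during growth at rate `mu`
per cell per generation; because the number of generations is ≈ `Nt` for
exponential growth from a small inoculum, the expected number of mutation
*events* per culture is `m = mu · (Nt − n0) ≈ mu · Nt`. A mutation at a random
time founds a clone whose final size follows the classic heavy-tailed law, so
per-culture mutant counts follow the Luria–Delbrück distribution with
parameter `m`, and `rate = m / (Nt · plating_fraction)`.

**Estimators.**

- *Method of the median* (default): the sample median count `r` (mean of the
  two central order statistics for even n) satisfies `r/m − ln m = 1.24`. The
  left side is strictly decreasing in `m`, so the root is unique; we solve it
  by Brent's method to 1e-12 relative tolerance. When the median is 0 the
  equation has no positive solution and the code logs a notice and falls back
  to the zero-class method.
- *Zero-class (p0)*: `m = −ln(fraction of cultures with 0 mutants)`, with
  Clopper–Pearson limits on the zero fraction mapped through `−ln`.
- *MSS maximum likelihood*: the exact Luria–Delbrück pmf recursion
  (`p0 = e^−m`, `p_r = (m/r) Σ_{i<r} p_i/(r−i+1)`) feeds a bounded 1-D
  likelihood search. Counts above a cap (default 1000) are treated as
  censored at the cap using the tail mass: jackpot counts can reach `Nt`
  itself and the recursion is quadratic in the largest count, while the
  likelihood beyond the cap is essentially flat in `m`. The profile
  likelihood (χ²₁ drop of 1.92) gives the CI.

**Confidence limits for the median method.** The assay protocol this package
mirrors does not specify its interval procedure, so we use distribution-free
binomial order-statistic bounds: ranks `(l, n+1−l)` chosen from
Binomial(n, 1/2) so the pair of order statistics covers the population median
with ≥ 95% probability, each bound then mapped through the (monotone) median
equation and divided by `Nt`. This is approximate — simulated coverage at
n = 27 cultures is ≈ 97%, and the test suite asserts only ≥ 85% — but needs
no distributional assumptions beyond exchangeability.

**Significance calls and relative rates.** Two rates are called different
when their closed 95% intervals are disjoint; a shared endpoint counts as
overlap (conservative). Rate ratios vs a reference strain are rounded the
way the published rate tables round them: 3 significant figures at ≥ 100,
2 in [1, 100), one decimal place below 1. One caveat worth recording: the
bundled rate table's own footnote claims every mutant's CI is disjoint from
wild type, yet the printed wild-type Lys+ interval (9.5–26.2) overlaps two
mutant intervals; the corresponding acceptance tests assert the footnote
claim and therefore fail for exactly those two pairs rather than paper over
the discrepancy.

## Spectrum homogeneity (`mutlab.spectra`)

Two spectra over the same mutation classes form a 2×N contingency table.
The statistic is the Pearson χ² with expected counts from the table margins;
classes with zero pooled count are dropped first (χ² is undefined there), and
at least two usable classes are required. Because per-class counts are small
(a few to a few dozen), the χ² reference distribution is unreliable; instead
the null distribution is simulated by randomly partitioning the pooled
mutants into two groups of the observed sizes — a multivariate hypergeometric
draw per table, i.e. the permutation null conditional on both margins (the
construction behind the classical spectra-comparison programs). The p-value
is the add-one estimator `(1 + #{χ²* ≥ χ²obs})/(1 + B)`, never exactly zero;
B defaults to 100 000 and a seed is mandatory. Observed and resampled
statistics are computed by the same code path so exact ties are handled
exactly (a 1e-9 guard absorbs float jitter). Column totals may differ (one
strain yielded 49 mutations from 48 mutants); no normalisation is applied.

Calibration checked by the suite: type-I error at 0.05 within [0.03, 0.07]
over 1000 null pairs; agreement with exact conditional enumeration on 2×2
tables to < 0.005 at B = 10⁶; invariance (in distribution) to category order
and argument swap.

`spectrum_correlation` is the Pearson correlation of the two proportion
vectors (≥ 3 categories; zero-variance input is an error).

## lacZ fidelity (`mutlab.fidelity`)

The M13mp2 forward-mutation assay yields a mutant frequency MF, N sequenced
mutants, per-class mutation counts Ni, and per-class detectable-site counts
D. The per-site error rate is `ER = [(Ni/N)·MF]/(D·p_expr)` with
`p_expr = 0.6`, the probability that a mutant lacZ allele is phenotypically
expressed (configurable). Ni counts mutations while N counts mutants, so
ΣNi need not equal N and no reconciliation is attempted. D values are assay
constants from the wider fidelity literature and are always user inputs,
never hard-coded. `background_adjusted_frequency` subtracts the uncopied-DNA
background and flags frequencies at or below it.

## Processivity (`mutlab.processivity`)

Under single-hit conditions each primer meets at most one enzyme, so band
intensity at product length N is proportional to the number of molecules
that dissociated there, and the termination probability is the discrete
hazard: `T(N) = I_N / Σ_{n≥N} I_n` for synthesis, `Σ_{n≤N}` for excision.
The runoff band (full-length product or fully degraded primer) is completion
rather than termination: it stays in denominators but is excluded from the
reported profile (configurable by simply not marking a runoff band).
Unquantified gel positions are absent, not zero; a position with zero
denominator is omitted with a logged notice. Whether published profiles
included their runoff bands in denominators is not documented; this choice
is therefore explicit and recorded here.

Enzyme comparisons divide profiles position-by-position; the summary is the
geometric mean of the per-position ratios (fold changes are multiplicative),
with the arithmetic mean also written to CLI output for transparency.

## Synthetic data (`mutlab.simulate`)

- **Cultures**: events per culture ~ Poisson(`mu·(nt−n0)`); each event's
  clone size is `floor(1/u)`, `u ~ U(0,1)` — the deterministic-growth
  approximation of the Luria–Delbrück clone-size law — capped at `nt`
  to prevent super-population jackpots. Defaults mirror the emulated assay
  design: nine 5-ml cultures grown to saturation (`nt = 1e8`, `n0 = 1e3`)
  at `mu = 1e-7`, the order of magnitude of a forward-mutation reporter.
  Rates above 0.1 per cell per generation are rejected as unphysical.
- **Spectra**: one multinomial draw.
- **Lanes**: molecules traverse positions in walk order and the *expected*
  fraction T(N) of those remaining stops at each band
  (`band = remaining · T`); survivors accumulate at runoff. The walk is
  deterministic so that with `noise_cv = 0` the termination profile
  round-trips exactly — this is a design choice: per-molecule Bernoulli
  sampling would add binomial noise indistinguishable in practice from
  densitometry error, which is instead modelled explicitly as multiplicative
  Gaussian noise `1 + N(0, noise_cv)` floored at 0 (phosphoimager intensities
  are positive with roughly proportional error).
- **lacZ assays**: class counts are multinomial with weights
  `ER_i·D_i·p_expr/MF` (which must sum to ≤ 1; the remainder are mutants
  outside the listed classes), so `error_rate` on the output recovers the
  input rates within sampling error.

All generators are bit-reproducible given (seed, parameters).

**What the generators do not emulate** — and hence what green tests do not
show about real data: phenotypic lag, plating efficiency < 1 and differential
mutant fitness in cultures (the clone-size law is the ideal
Luria–Delbrück one); per-molecule shot noise and gel-background subtraction
artifacts in lanes; sequencing-selection bias among mutant plaques;
experiment-to-experiment variance when cultures are pooled across days.

## Problem sizes and numerics

Monte Carlo homogeneity tests use B = 100 000 resamples (results
reproducible to ~±0.002 in p across seeds at the published table sizes).
Statistical property checks in the suite use 100–1000 replicates of 27–45
culture sets and B = 999 per null pair — sizes chosen to keep each property's
sampling error well inside its asserted band. Root finding uses Brent's
method with 1e-12 relative tolerance; the pmf recursion is evaluated with a
vectorised dot product per term; all randomness flows through
`numpy.random.default_rng` seeds.

## Known limitations

- The median-method CI is approximate (rank CI transformed through a
  nonlinear estimator); it is validated by simulated coverage, not theory.
- The MC test's tie-handling and B may differ from the historical COLLAPSE
  program's internals, which are not documented; published p-values are
  reproduced within Monte Carlo error regardless.
- No corrections for phenotypic lag, plating efficiency or mutant fitness
  are offered, and multi-spectrum (> 2 groups) simultaneous testing is out
  of scope.
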