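"""Synthetic-data generators for every analysis stage.

Each generator produces data with exactly the statistical structure the
corresponding analysis assumes, so the whole pipeline is testable
without any experimental input:

* :func:`simulate_cultures` — Luria-Delbruck mutant counts for a
  fluctuation assay.  Mutation events per culture are Poisson with mean
  ``m = mu * (nt - n0)``; each event founds a clone whose size follows
  the classic ``floor(1/u)`` law (deterministic exponential growth from
  a uniformly-random event time), capped at ``nt``.
* :func:`simulate_spectrum` — multinomial mutant-class counts.
* :func:`simulate_lane` — gel-lane band intensities from a true
  termination-probability profile.  The molecule walk is deterministic
  in expectation (band = remaining * T), so at ``noise_cv = 0`` the
  profile round-trips exactly; multiplicative Gaussian noise emulates
  densitometry error.
* :func:`simulate_lacz` — lacZ assay class counts from true per-class
  error rates.

All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fidelity import LacZAssay, MutationClass
from .fluctuation import CultureSet
from .processivity import LaneProfile
from .spectra import MutationSpectrum

__all__ = [
    "SimulationConfig",
    "simulate_cultures",
    "simulate_spectrum",
    "simulate_lane",
    "simulate_lacz",
]


@dataclass
class SimulationConfig:
    """Bundle of generator settings mirroring a typical assay.

    Defaults emulate the yeast fluctuation-assay design: 5-ml cultures
    grown to saturation (~1e8 cells) from a small inoculum, nine
    parallel cultures, and a per-cell per-generation rate of 1e-7 (the
    order of magnitude of a forward-mutation reporter).
    """

    seed: int = 0
    mu: float = 1e-7
    n0: float = 1e3
    nt: float = 1e8
    n_cultures: int = 9
    spectrum_probs: "Sequence[float] | None" = None
    termination_truth: "Mapping[int, float] | None" = None
    n_molecules: int = 10_000
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.nt <= self.n0 or self.n0 < 1:
            raise ValueError("need nt > n0 >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.spectrum_probs is not None:
            p = np.asarray(self.spectrum_probs, dtype=float)
            if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("spectrum_probs must be non-negative and sum to 1")


def simulate_cultures(
    cfg: SimulationConfig,
    strain_label: str = "sim",
    locus_label: str = "sim",
) -> CultureSet:
    """Draw one fluctuation-assay culture set.

    Per culture the number of mutation events is Poisson with mean
    ``m = mu * (nt - n0)``; each event's clone size is ``floor(1/u)``
    with ``u ~ Uniform(0, 1)``, and the per-culture mutant count is the
    clone-size sum capped at ``nt``.
    """
    if cfg.mu > 0.1:
        raise ValueError("mu > 0.1 per cell per generation is not a credible rate")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.mu * (cfg.nt - cfg.n0)
    nt_int = int(cfg.nt)
    counts = []
    for _ in range(cfg.n_cultures):
        k = int(rng.poisson(m))
        if k == 0:
            counts.append(0)
            continue
        u = rng.random(k)
        clones = np.minimum(np.floor(1.0 / u), nt_int)
        counts.append(int(min(clones.sum(), nt_int)))
    return CultureSet(
        strain_label=strain_label,
        locus_label=locus_label,
        mutant_counts=tuple(counts),
        n_final_cells=cfg.nt,
    )


def simulate_spectrum(
    probs: Sequence[float],
    n: int,
    seed: int,
    categories: "Sequence[str] | None" = None,
    label: str = "sim",
) -> MutationSpectrum:
    """Multinomial draw of ``n`` mutants over the given class probabilities."""
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("probs must be non-negative and sum to 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p)
    if categories is None:
        categories = tuple(f"class_{i}" for i in range(len(p)))
    return MutationSpectrum(
        label=label, categories=tuple(categories), counts=tuple(int(c) for c in counts)
    )


def simulate_lane(
    termination_truth: Mapping[int, float],
    n_molecules: int,
    noise_cv: float,
    direction: str,
    seed: int,
    runoff_position: "int | None" = None,
) -> LaneProfile:
    """Band intensities implied by a true termination profile.

    Molecules traverse the positions in walk order (ascending product
    length for synthesis, descending for excision); at each position the
    expected fraction ``T(N)`` of those still bound terminates there.
    Survivors accumulate in the runoff band (one step past the last
    position unless ``runoff_position`` is given).  Intensities are the
    expected molecule counts times multiplicative Gaussian noise
    ``1 + N(0, noise_cv)``, floored at 0.
    """
    truth = {int(k): float(v) for k, v in dict(termination_truth).items()}
    if not truth:
        raise ValueError("termination_truth is empty")
    if any(not (0.0 <= t <= 1.0) for t in truth.values()):
        raise ValueError("termination probabilities must be in [0, 1]")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")

    order = sorted(truth, reverse=(direction == "excision"))
    if runoff_position is None:
        runoff_position = order[-1] + 1 if direction == "synthesis" else order[-1] - 1
    if runoff_position <= 0:
        raise ValueError(
            "runoff position would be non-positive; provide runoff_position"
        )
    if runoff_position in truth:
        raise ValueError("runoff_position collides with a profiled position")

    rng = np.random.default_rng(seed)
    remaining = float(n_molecules)
    counts: dict[int, float] = {}
    for pos in order:
        band = remaining * truth[pos]
        remaining -= band
        counts[pos] = band
    counts[runoff_position] = remaining

    noisy: dict[int, float] = {}
    for pos in sorted(counts):
        c = counts[pos]
        if noise_cv > 0:
            c *= 1.0 + rng.normal(0.0, noise_cv)
        noisy[pos] = max(c, 0.0)
    return LaneProfile(
        direction=direction, intensities=noisy, runoff_position=runoff_position
    )


def simulate_lacz(
    class_er_and_d: Mapping[str, tuple[float, int]],
    n: int,
    mf: float,
    seed: int,
    expression_prob: float = 0.6,
    enzyme_label: str = "sim",
) -> LacZAssay:
    """Draw per-class mutation counts from true per-class error rates.

    Each class receives weight ``ER_i * D_i * expression_prob / MF``
    (the expected fraction of sequenced mutants in that class); the
    weights must sum to <= 1, any remainder being mutants whose change
    falls outside the listed classes.  ``error_rate`` applied to the
    output recovers the input ER values within multinomial error.
    """
    names = list(class_er_and_d)
    ers = np.array([class_er_and_d[k][0] for k in names], dtype=float)
    ds = np.array([class_er_and_d[k][1] for k in names], dtype=float)
    if (ers < 0).any() or (ds < 1).any():
        raise ValueError("need ER >= 0 and D >= 1 for every class")
    if not (0 < mf <= 1):
        raise ValueError("MF must be in (0, 1]")
    weights = ers * ds * expression_prob / mf
    w_sum = weights.sum()
    if w_sum > 1.0 + 1e-9:
        raise ValueError(
            f"class weights sum to {w_sum:.4f} > 1; inconsistent ER/D/MF inputs"
        )
    rng = np.random.default_rng(seed)
    probs = np.append(weights, max(1.0 - w_sum, 0.0))
    draw = rng.multinomial(n, probs / probs.sum())
    classes = {
        name: MutationClass(int(ni), int(d))
        for name, ni, d in zip(names, draw[:-1], ds)
    }
    return LacZAssay(
        enzyme_label=enzyme_label,
        n_mutants_sequenced=n,
        mutant_frequency=mf,
        classes=classes,
        expression_prob=expression_prob,
    )
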