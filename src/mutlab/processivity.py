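"""Termination-probability (processivity) profiles from gel lanes.

Under single-hit conditions each primer is extended (or degraded) by at
most one enzyme encounter, so the band intensity at product length N is
proportional to the number of enzyme molecules that dissociated exactly
there.  The termination probability is the discrete hazard of
dissociation:

* synthesis:  T(N) = I_N / sum of I_n over n >= N
  (of all molecules that reached position N, the fraction stopping there)
* excision:   T(N) = I_N / sum of I_n over n <= N
  (degradation proceeds toward shorter products)

A runoff band (full-length product, or fully degraded primer) represents
completion rather than termination: it is kept in denominators but
excluded from the reported profile.

A less processive enzyme has uniformly higher T(N); per-position fold
changes and their geometric mean summarise the difference between two
enzymes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "LaneProfile",
    "TerminationProfile",
    "termination_profile",
    "fold_change",
    "mean_fold_change",
]

logger = logging.getLogger(__name__)

Direction = Literal["synthesis", "excision"]


def _validate_direction(direction: str) -> None:
    if direction not in ("synthesis", "excision"):
        raise ValueError("direction must be 'synthesis' or 'excision'")


@dataclass(frozen=True)
class LaneProfile:
    """Band intensities of one gel lane, keyed by product length (nt).

    Positions are 1-based product lengths; unquantified positions are
    simply absent.  ``runoff_position`` marks the full-length (synthesis)
    or fully-degraded (excision) band, if present.
    """

    direction: Direction
    intensities: Mapping[int, float]
    runoff_position: "int | None" = None

    def __post_init__(self) -> None:
        _validate_direction(self.direction)
        ints = {int(k): float(v) for k, v in dict(self.intensities).items()}
        object.__setattr__(self, "intensities", ints)
        if len(ints) < 2:
            raise ValueError("lane needs at least 2 distinct positions")
        if any(k <= 0 for k in ints):
            raise ValueError("positions must be strictly positive")
        if any(v < 0 for v in ints.values()):
            raise ValueError("intensities must be non-negative")
        if sum(ints.values()) <= 0:
            raise ValueError("total lane intensity must be positive")
        if self.runoff_position is not None and self.runoff_position not in ints:
            raise ValueError("runoff_position must be one of the band positions")


@dataclass(frozen=True)
class TerminationProfile:
    """Per-position termination probabilities, keyed by product length."""

    direction: Direction
    probabilities: Mapping[int, float]

    def __post_init__(self) -> None:
        _validate_direction(self.direction)
        probs = {int(k): float(v) for k, v in dict(self.probabilities).items()}
        object.__setattr__(self, "probabilities", probs)
        if any(not (0.0 <= p <= 1.0) for p in probs.values()):
            raise ValueError("probabilities must be in [0, 1]")

    def positions(self) -> list[int]:
        return sorted(self.probabilities)


def termination_profile(lane: LaneProfile) -> TerminationProfile:
    """Per-position termination probabilities of one lane.

    Synthesis: divide band N by the summed intensity of all bands >= N;
    excision: by all bands <= N.  The runoff band contributes to
    denominators but is not reported.  Positions with a zero denominator
    are omitted with a logged notice.
    """
    positions = sorted(lane.intensities)
    intens = np.array([lane.intensities[p] for p in positions])
    if lane.direction == "synthesis":
        # cumulative from the top: sum over n >= N
        denom = np.cumsum(intens[::-1])[::-1]
    else:
        denom = np.cumsum(intens)
    probs: dict[int, float] = {}
    for pos, i_n, d in zip(positions, intens, denom):
        if pos == lane.runoff_position:
            continue
        if d <= 0:
            logger.info("position %d omitted: zero denominator", pos)
            continue
        probs[pos] = float(i_n / d)
    return TerminationProfile(direction=lane.direction, probabilities=probs)


def fold_change(
    a: TerminationProfile, b: TerminationProfile
) -> dict[int, float]:
    """Per-position ratio T_a(N) / T_b(N) over shared positions with
    T_b(N) > 0."""
    if a.direction != b.direction:
        raise ValueError("profiles must share a direction")
    shared = [
        p
        for p in sorted(set(a.probabilities) & set(b.probabilities))
        if b.probabilities[p] > 0
    ]
    if not shared:
        raise ValueError("no shared positions with non-zero reference probability")
    return {p: a.probabilities[p] / b.probabilities[p] for p in shared}


def mean_fold_change(
    ratios: "Mapping[int, float] | list[float]",
    kind: Literal["geometric", "arithmetic"] = "geometric",
) -> float:
    """Average per-position fold change.

    The geometric mean (default) is the natural summary of multiplicative
    per-position ratios; the arithmetic mean is available for comparison.
    """
    values = np.asarray(
        list(ratios.values()) if isinstance(ratios, Mapping) else ratios, dtype=float
    )
    if values.size == 0:
        raise ValueError("need at least one ratio")
    if kind == "geometric":
        return float(stats.gmean(values))
    if kind == "arithmetic":
        return float(values.mean())
    raise ValueError(f"unknown kind {kind!r}")
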