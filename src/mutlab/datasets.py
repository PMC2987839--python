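"""Published summary tables bundled as ready-made inputs.

These are the printed results of a S. cerevisiae spontaneous-mutagenesis
study of the Pol epsilon accessory subunits Dpb3/Dpb4: fluctuation-assay
mutation rates with 95% confidence limits for mutants of the replication
and mismatch-repair machinery (His+/Lys+ reversion and canavanine
resistance reporters), lacZ forward-mutation spectra of exonuclease-
deficient Pol epsilon forms measured in vitro, and CAN1 forward-mutation
spectra of four isogenic strains.  Only table-level summaries were
published; per-culture and per-plaque raw data are not available.
"""

from __future__ import annotations

import pandas as pd

from .fluctuation import RateEstimate
from .spectra import MutationSpectrum

__all__ = [
    "mutation_rate_table",
    "rate_estimates",
    "invitro_spectra",
    "invitro_mutant_frequencies",
    "can1_spectra",
]

# (strain, locus) -> (rate x1e-8, ci_low, ci_high, printed relative rate)
# "wt" is the reference for table "main"; "dpb3d dpb4d" for table "rev3".
_RATE_ROWS: list[tuple[str, str, str, float, float, float, float]] = [
    # table, strain, locus, rate, ci_low, ci_high, printed relative
    ("main", "wt", "His+", 1.5, 0.6, 2.4, 1),
    ("main", "wt", "Lys+", 12.9, 9.5, 26.2, 1),
    ("main", "wt", "Canr", 10.1, 3.9, 14.6, 1),
    ("main", "dpb3d", "His+", 4.4, 3.6, 5.7, 3.9),
    ("main", "dpb3d", "Lys+", 35.7, 31.9, 56.7, 2.8),
    ("main", "dpb3d", "Canr", 81.8, 72.2, 95.2, 8.1),
    ("main", "dpb4d", "His+", 3.7, 3.0, 5.0, 2.5),
    ("main", "dpb4d", "Lys+", 22.3, 19.9, 28.6, 1.7),
    ("main", "dpb4d", "Canr", 63.4, 57.3, 71.4, 6.3),
    ("main", "dpb3d dpb4d", "His+", 4.1, 2.5, 5.1, 2.7),
    ("main", "dpb3d dpb4d", "Lys+", 33.4, 25.9, 46.4, 2.6),
    ("main", "dpb3d dpb4d", "Canr", 74.3, 66.4, 89.5, 7.4),
    ("main", "pol2-4", "His+", 6.9, 4.2, 8.6, 4.6),
    ("main", "pol2-4", "Lys+", 35.7, 32.9, 48.3, 2.7),
    ("main", "pol2-4", "Canr", 77.9, 69.4, 90.5, 7.7),
    ("main", "pol2-4 dpb3d", "His+", 13.4, 10.9, 18.8, 8.9),
    ("main", "pol2-4 dpb3d", "Lys+", 44.5, 37.8, 52.5, 3.4),
    ("main", "pol2-4 dpb3d", "Canr", 153, 128, 210, 15.1),
    ("main", "pol2-4 dpb4d", "His+", 28.1, 23.0, 30.4, 18.7),
    ("main", "pol2-4 dpb4d", "Lys+", 44.5, 39.1, 59.9, 3.4),
    ("main", "pol2-4 dpb4d", "Canr", 224, 200, 268, 22.2),
    ("main", "pol2-4 dpb3d dpb4d", "His+", 22.1, 18.5, 26.8, 14.8),
    ("main", "pol2-4 dpb3d dpb4d", "Lys+", 41.0, 35.6, 49.3, 3.2),
    ("main", "pol2-4 dpb3d dpb4d", "Canr", 132, 123, 170, 13),
    ("main", "msh6d", "His+", 5.3, 3.5, 6.7, 3.5),
    ("main", "msh6d", "Lys+", 2720, 2390, 3690, 211),
    ("main", "msh6d", "Canr", 165, 119, 226, 16.3),
    ("main", "msh6d dpb3d", "His+", 7.0, 5.5, 9.4, 4.6),
    ("main", "msh6d dpb3d", "Lys+", 1360, 1100, 1550, 105),
    ("main", "msh6d dpb3d", "Canr", 299, 216, 399, 29.6),
    ("main", "msh6d dpb4d", "His+", 7.6, 6.3, 9.3, 5.1),
    ("main", "msh6d dpb4d", "Lys+", 1430, 1180, 1590, 111),
    ("main", "msh6d dpb4d", "Canr", 278, 217, 344, 27.5),
    ("main", "msh6d dpb3d dpb4d", "His+", 9.0, 8.1, 12.4, 6.0),
    ("main", "msh6d dpb3d dpb4d", "Lys+", 2200, 2060, 2830, 171),
    ("main", "msh6d dpb3d dpb4d", "Canr", 261, 217, 346, 25.8),
    ("main", "msh6d pol2-4", "His+", 71.1, 55.7, 82.7, 47.4),
    ("main", "msh6d pol2-4", "Lys+", 7180, 6190, 8870, 557),
    ("main", "msh6d pol2-4", "Canr", 7150, 6410, 9810, 708),
    ("main", "msh6d pol2-4 dpb3d", "His+", 72.6, 45.9, 119, 48.4),
    ("main", "msh6d pol2-4 dpb3d", "Lys+", 2460, 1800, 4670, 190),
    ("main", "msh6d pol2-4 dpb3d", "Canr", 13400, 11200, 17000, 1320),
    ("main", "msh6d pol2-4 dpb4d", "His+", 76.6, 32.6, 121, 51.1),
    ("main", "msh6d pol2-4 dpb4d", "Lys+", 2590, 1870, 5510, 201),
    ("main", "msh6d pol2-4 dpb4d", "Canr", 17800, 10500, 21100, 1760),
    ("main", "msh6d pol2-4 dpb3d dpb4d", "His+", 68.6, 54.9, 100, 45.7),
    ("main", "msh6d pol2-4 dpb3d dpb4d", "Lys+", 2600, 594, 4010, 201),
    ("main", "msh6d pol2-4 dpb3d dpb4d", "Canr", 8450, 6670, 13800, 837),
    ("main", "pol3-5DV", "His+", 7.3, 6.2, 8.8, 4.9),
    ("main", "pol3-5DV", "Lys+", 71, 57, 77, 5.5),
    ("main", "pol3-5DV", "Canr", 350, 304, 419, 35),
    ("main", "pol3-5DV dpb3d dpb4d", "His+", 17.8, 15, 21, 11.9),
    ("main", "pol3-5DV dpb3d dpb4d", "Lys+", 67, 54, 85, 5.2),
    ("main", "pol3-5DV dpb3d dpb4d", "Canr", 363, 288, 547, 36),
    # rev3 suppression experiment (reference strain: dpb3d dpb4d)
    ("rev3", "dpb3d dpb4d", "His+", 4.1, 2.5, 5.1, 1),
    ("rev3", "dpb3d dpb4d", "Lys+", 33.4, 25.9, 46.4, 1),
    ("rev3", "dpb3d dpb4d", "Canr", 74.3, 66.4, 89.5, 1),
    ("rev3", "dpb3d dpb4d rev3d", "His+", 3.6, 2.7, 4.2, 0.9),
    ("rev3", "dpb3d dpb4d rev3d", "Lys+", 33.2, 30.1, 39.1, 1),
    ("rev3", "dpb3d dpb4d rev3d", "Canr", 26, 20.7, 29.1, 0.3),
]

#: Mutation classes of the in vitro lacZ assay (2x4 comparison).
INVITRO_CATEGORIES = (
    "substitutions",
    "-1 frameshifts",
    "+1 frameshifts",
    "other",
)

_INVITRO = {
    # label -> (counts, mutant frequency, mutants sequenced)
    "holoenzyme pol2-4": ((214, 53, 9, 11), 0.026, 285),
    "pol2-4/Dpb2": ((229, 35, 7, 29), 0.029, 277),
}

#: CAN1 forward-mutation classes (10-category spectra).
CAN1_CATEGORIES = (
    "AT->TA",
    "AT->CG",
    "AT->GC",
    "GC->CG",
    "GC->AT",
    "GC->TA",
    "-1 frameshifts",
    "+1 frameshifts",
    "Complex",
    "Other",
)

_CAN1 = {
    "wt": (1, 2, 3, 12, 7, 10, 5, 2, 1, 5),
    "dpb3d dpb4d": (1, 1, 3, 9, 9, 8, 9, 1, 5, 3),
    "pol2-4": (6, 5, 5, 4, 3, 6, 5, 11, 2, 1),
    "pol2-4 dpb3d dpb4d": (6, 4, 0, 8, 2, 7, 9, 6, 3, 3),
}


def mutation_rate_table(which: str = "main") -> pd.DataFrame:
    """Published mutation rates (x1e-8) with 95% confidence limits.

    ``which="main"`` returns the replication/MMR mutant panel (reference
    strain ``wt``); ``which="rev3"`` the Pol zeta suppression experiment
    (reference strain ``dpb3d dpb4d``).  ``relative_printed`` is the
    rate ratio vs the reference as printed in the source table.
    """
    rows = [r[1:] for r in _RATE_ROWS if r[0] == which]
    if not rows:
        raise ValueError(f"unknown table {which!r}; use 'main' or 'rev3'")
    return pd.DataFrame(
        rows,
        columns=["strain", "locus", "rate", "ci_low", "ci_high", "relative_printed"],
    )


def rate_estimates(which: str = "main") -> dict[tuple[str, str], RateEstimate]:
    """The same rates as :func:`mutation_rate_table`, as
    :class:`~mutlab.fluctuation.RateEstimate` objects keyed by
    (strain, locus).

    Only the printed summaries are available, so ``m`` and
    ``n_cultures`` are unknown (set to 0) and the method is recorded as
    ``median`` per the source's footnotes.
    """
    out: dict[tuple[str, str], RateEstimate] = {}
    for _, strain, locus, rate, lo, hi, _rel in (
        r for r in _RATE_ROWS if r[0] == which
    ):
        out[(strain, locus)] = RateEstimate(
            m=0.0,
            rate=rate,
            ci_low=lo,
            ci_high=hi,
            n_cultures=0,
            method="median",
            strain_label=strain,
            locus_label=locus,
        )
    if not out:
        raise ValueError(f"unknown table {which!r}; use 'main' or 'rev3'")
    return out


def invitro_spectra() -> dict[str, MutationSpectrum]:
    """lacZ mutation-class counts of the two exonuclease-deficient Pol
    epsilon forms (4-subunit holoenzyme vs 2-subunit Pol2/Dpb2)."""
    return {
        label: MutationSpectrum(
            label=label, categories=INVITRO_CATEGORIES, counts=counts
        )
        for label, (counts, _mf, _n) in _INVITRO.items()
    }


def invitro_mutant_frequencies() -> dict[str, tuple[float, int]]:
    """lacZ mutant frequency and number of mutants sequenced per enzyme."""
    return {label: (mf, n) for label, (_c, mf, n) in _INVITRO.items()}


def can1_spectra() -> dict[str, MutationSpectrum]:
    """CAN1 forward-mutation spectra of the four isogenic strains
    (48-49 sequenced Can-resistant mutants each, 10 mutation classes)."""
    return {
        label: MutationSpectrum(
            label=label, categories=CAN1_CATEGORIES, counts=counts
        )
        for label, counts in _CAN1.items()
    }
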