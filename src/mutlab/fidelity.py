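"""lacZ forward-mutation assay error rates.

In the M13mp2 gap-filling fidelity assay a polymerase copies a
single-stranded lacZ region in vitro; the products are introduced into
E. coli and mutant (light blue / colorless) plaques are scored.  The
mutant frequency MF, the number of sequenced mutants N, the per-class
mutation counts Ni, and the number of detectable sites D for each class
give the per-site error rate

    ER = [(Ni / N) * MF] / (D * 0.6)

where 0.6 is the probability that a mutant lacZ allele is expressed in
E. coli.  Ni are mutation counts and N is a mutant count, so the class
counts may legitimately sum to more or less than N (multi-mutation
mutants; undetectable changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

__all__ = [
    "MutationClass",
    "LacZAssay",
    "AdjustedFrequency",
    "mutant_frequency",
    "error_rate",
    "background_adjusted_frequency",
]


class MutationClass(NamedTuple):
    """Per-class summary: mutation count Ni and detectable sites D."""

    ni: int
    detectable_sites: int


class AdjustedFrequency(NamedTuple):
    value: float
    near_background: bool


@dataclass(frozen=True)
class LacZAssay:
    """Summary of one lacZ forward-mutation fidelity assay."""

    enzyme_label: str
    n_mutants_sequenced: int
    mutant_frequency: float
    classes: Mapping[str, MutationClass] = field(default_factory=dict)
    background_frequency: "float | None" = None
    expression_prob: float = 0.6

    def __post_init__(self) -> None:
        cls = {k: MutationClass(*v) for k, v in dict(self.classes).items()}
        object.__setattr__(self, "classes", cls)
        if self.n_mutants_sequenced < 0:
            raise ValueError("n_mutants_sequenced must be non-negative")
        if not (0.0 <= self.mutant_frequency <= 1.0):
            raise ValueError("mutant_frequency must be in [0, 1]")
        if not (0.0 < self.expression_prob <= 1.0):
            raise ValueError("expression_prob must be in (0, 1]")
        for name, mc in cls.items():
            if mc.ni < 0:
                raise ValueError(f"class {name!r}: Ni must be non-negative")
            if mc.detectable_sites < 1:
                raise ValueError(f"class {name!r}: D must be >= 1")


def mutant_frequency(n_mutant_plaques: int, n_total_plaques: int) -> float:
    """Fraction of mutant plaques among all plaques scored."""
    if n_total_plaques <= 0:
        raise ValueError("total plaque count must be positive")
    if not (0 <= n_mutant_plaques <= n_total_plaques):
        raise ValueError("mutant plaques must be between 0 and the total")
    return n_mutant_plaques / n_total_plaques


def error_rate(assay: LacZAssay, class_name: str) -> float:
    """Per-detectable-site error rate ``[(Ni/N) * MF] / (D * 0.6)``."""
    if class_name not in assay.classes:
        raise KeyError(f"unknown mutation class {class_name!r}")
    if assay.n_mutants_sequenced == 0:
        raise ValueError("N (mutants sequenced) must be positive")
    ni, d = assay.classes[class_name]
    return (ni / assay.n_mutants_sequenced * assay.mutant_frequency) / (
        d * assay.expression_prob
    )


def background_adjusted_frequency(
    mf: float, mf_background: float
) -> AdjustedFrequency:
    """MF minus the background of uncopied DNA, floored at 0.

    The ``near_background`` flag is set when MF <= background, i.e. the
    polymerase is so accurate that its products are indistinguishable
    from unreacted template.
    """
    if mf < 0 or mf_background < 0:
        raise ValueError("frequencies must be non-negative")
    return AdjustedFrequency(max(mf - mf_background, 0.0), mf <= mf_background)
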