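import numpy as np
import pytest

from mutlab import datasets, ld_pmf


@pytest.fixture(scope="session")
def invitro():
    """The two lacZ in vitro spectra (4-subunit vs 2-subunit enzyme)."""
    sp = datasets.invitro_spectra()
    return sp["holoenzyme pol2-4"], sp["pol2-4/Dpb2"]


@pytest.fixture(scope="session")
def can1():
    """CAN1 forward-mutation spectra of the four strains."""
    return datasets.can1_spectra()


def ld_sample(m: float, n: int, rng: np.random.Generator, cap: int = 3000):
    """Draw Luria-Delbruck counts by inverting the exact pmf (truncated
    at ``cap`` and renormalised) — independent of the clone-size
    generator in mutlab.simulate."""
    p = ld_pmf(m, cap)
    return rng.choice(cap + 1, size=n, p=p / p.sum())
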