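import numpy as np
import pytest

from loyscan import SimulationConfig, make_default_layout
from loyscan.genome import Chromosome, GenomeLayout


@pytest.fixture(scope="session")
def layout():
    return make_default_layout()


@pytest.fixture(scope="session")
def small_layout():
    """Tiny layout (2 autosomes + X + Y) for fast unit cases.

    Y is 50 kb with a 30 kb MSY, so MSY restriction and ragged windows
    are both exercised at 10 kb resolution.
    """
    return GenomeLayout(
        (
            Chromosome("chr1", 100_000, "autosome"),
            Chromosome("chr2", 100_000, "autosome"),
            Chromosome("chrX", 100_000, "X"),
            Chromosome("chrY", 50_000, "Y"),
        ),
        msy_length=30_000,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture()
def noiseless_config():
    """Poisson-free, jitter-free configuration for analytic cases."""
    return SimulationConfig(nb_dispersion=0.0, efficiency_sd=0.0, seed=7)
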