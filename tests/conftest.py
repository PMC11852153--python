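import numpy as np
import pytest

from spongeworks.synthdata import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (4v4, planted DE + sponge triplets)."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def deterministic_study():
    """Noise-free, dispersion-free limit: planted structure is exact."""
    return simulate_study(SimConfig(seed=5, noise_sd=0.0, nb_dispersion=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
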