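import numpy as np
import pytest

from inkfidelity import beam


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    """A mid-range filament: 0.4 mm radius over a 4 mm gap, k*L ~ 0.6."""
    return beam.BeamParameters(E=10e3, P=5e-6, r=0.4e-3, rho=1026.0, L=4e-3)


def random_beam_params(rng, kl_range=(0.05, 5.0)):
    """Random physical parameters with k*L controlled via P."""
    E = 10.0 ** rng.uniform(2.5, 5.0)
    r = rng.uniform(0.1e-3, 0.5e-3)
    L = rng.uniform(2e-3, 16e-3)
    kl = rng.uniform(*kl_range)
    I = np.pi * r**4 / 4.0
    P = (kl / L) ** 2 * E * I
    return beam.BeamParameters(E=E, P=P, r=r, rho=1026.0, L=L)
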