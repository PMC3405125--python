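import numpy as np
import pytest

from critwave import LatticeSpec, NoiseSpec
from critwave.lattice import build_coupling, distance_shells


@pytest.fixture(scope="session")
def small_spec():
    return LatticeSpec(n=8, g=1.0, bc="periodic")


@pytest.fixture(scope="session")
def small_coupling(small_spec):
    return build_coupling(small_spec)


@pytest.fixture(scope="session")
def small_shells(small_spec):
    return distance_shells(small_spec)


@pytest.fixture()
def impulse_state(small_spec):
    x0 = np.zeros(small_spec.n_sites)
    x0[small_spec.site_index(*small_spec.center)] = 1.0
    return x0


@pytest.fixture()
def quiet_noise():
    return NoiseSpec(eta=0.0, seed=0, dt=0.01)
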