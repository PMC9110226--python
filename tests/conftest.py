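import numpy as np
import pytest

from ctprestore.phantom import build_phantom, default_kinetics, default_spec
from ctprestore.pipeline import RunConfig, seed_sweep


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 48^2 phantom with the default 20-frame sampling."""
    return build_phantom(default_spec(grid_size=48))


@pytest.fixture(scope="session")
def kinetics():
    return default_kinetics()


@pytest.fixture(scope="session")
def default_sweep():
    """The headline experiment: default low-dose pipeline over 10 seeds,
    restored and unrestored arms sharing each seed's noisy data."""
    return seed_sweep(RunConfig(), seeds=list(range(10)))
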