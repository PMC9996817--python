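import numpy as np
import pytest

from deltarisk import dispersal, pas


@pytest.fixture
def sampler():
    """Default AlteSil sheet with the laboratory log Kpw table."""
    return pas.PolymerSampler()


@pytest.fixture
def field_kin(sampler):
    """Deployment kinetics implied by the default field sampling rate."""
    return pas.field_kinetics(sampler)


@pytest.fixture
def small_grid():
    return dispersal.Grid(nx=40, ny=40, dx=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
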