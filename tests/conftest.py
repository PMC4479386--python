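import numpy as np
import pytest

from brachyhet.materials import load_material
from brachyhet.phantom import PhantomConfig
from brachyhet.transport import run_simulation


@pytest.fixture(scope="session")
def water():
    return load_material("water")


@pytest.fixture(scope="session")
def bone():
    return load_material("cortical_bone")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230911)


@pytest.fixture(scope="session")
def hom_small():
    """Small homogeneous-water run shared by fast unit tests."""
    return run_simulation(PhantomConfig(), 200_000, seed=7)


@pytest.fixture(scope="session")
def hom_1e6():
    """Production-scale homogeneous-water reference run."""
    return run_simulation(PhantomConfig(), 1_000_000, seed=11)
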