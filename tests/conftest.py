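import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_net():
    """~50-node periodic Voronoi network (session-wide, read-only)."""
    from fibernet.fixtures import make_fixture

    return make_fixture("small_voronoi", seed=4)


@pytest.fixture(scope="session")
def beam_props():
    from fibernet.mechanics import BeamProperties

    return BeamProperties()
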