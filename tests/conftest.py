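import numpy as np
import pytest

from aridflux import GridSpec, WorldConfig, build_world
from aridflux.grid import GridField


@pytest.fixture(scope="session")
def world():
    """Default synthetic world, shared read-only across the session."""
    return build_world(WorldConfig(seed=0))


@pytest.fixture(scope="session")
def small_world():
    """A faster, coarser world for orchestration tests."""
    return build_world(WorldConfig(seed=3, nlat=8, nlon=16))


@pytest.fixture
def grid4x6():
    return GridSpec(np.array([-30.0, -10.0, 10.0, 30.0]),
                    np.array([-150.0, -90.0, -30.0, 30.0, 90.0, 150.0]))


@pytest.fixture
def uniform_field(grid4x6):
    return GridField(grid4x6, np.full(grid4x6.shape, 1000.0), units="g C m-2 yr-1")
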