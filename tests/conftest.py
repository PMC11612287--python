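import numpy as np
import pytest

from envmech.geometry import make_geometry
from envmech.mac_spatial import CapsuleRegion, PointPattern


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def cell_geometry():
    """A typical E. coli-scale capsule: 3 um long, 1 um wide."""
    return make_geometry(3000.0, 500.0, 0.0, (0.0, 0.0))


@pytest.fixture
def csr_pattern(cell_geometry, rng):
    region = CapsuleRegion(cell_geometry)
    pts = region.sample(100, rng)
    return PointPattern(points=pts, region=region, geometry=cell_geometry)
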