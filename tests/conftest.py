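import numpy as np
import pytest

from lobewise.mesh import icosphere
from lobewise.segmentation import FlairVolume


@pytest.fixture(scope="session")
def ico642():
    """642-vertex icosphere used by the surface-statistics tests."""
    return icosphere(subdivisions=3)


@pytest.fixture(scope="session")
def ico162():
    return icosphere(subdivisions=2)


@pytest.fixture()
def toy_volume():
    """1000 voxels: 990 at intensity 100 and a 10-voxel block at 200.

    The block is a single 26-connected component, so the whole-volume moments
    are mu=101, population SD=sqrt(99), and the 2.1 SD threshold labels
    exactly those 10 voxels.
    """
    data = np.full((10, 10, 10), 100.0)
    data[0, 0:2, 0:5] = 200.0
    return FlairVolume(data=data, mask=np.ones_like(data, dtype=bool),
                       voxel_size=(1.0, 1.0, 1.0))
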