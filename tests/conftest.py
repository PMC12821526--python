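import numpy as np
import pytest

from nbquant import NucleusParams, SegmentationParams


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def nuc_params():
    return NucleusParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ellipsoid(shape, semiaxes_um, voxel_size, value=120, background=2,
                   center_um=None):
    """Render a hard-edged ellipsoid on a uint8 canvas (test fixture)."""
    arr = np.full(shape, background, dtype=np.uint8)
    dz, dy, dx = voxel_size
    if center_um is None:
        center_um = ((shape[0] - 1) * dz / 2, (shape[1] - 1) * dy / 2,
                     (shape[2] - 1) * dx / 2)
    az, ay, ax = semiaxes_um
    zz = (np.arange(shape[0]) * dz - center_um[0])[:, None, None]
    yy = (np.arange(shape[1]) * dy - center_um[1])[None, :, None]
    xx = (np.arange(shape[2]) * dx - center_um[2])[None, None, :]
    inside = (zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax) ** 2 <= 1.0
    arr[inside] = value
    return arr, inside
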