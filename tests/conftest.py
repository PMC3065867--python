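import numpy as np
import pytest

from spectrecon.projector import (
    AcquisitionGeometry,
    CollimatorModel,
    SystemModel,
    Volume,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_geometry(shape, voxel=1.0, n_angles=12, orbit=None):
    """Geometry matched to a (nz, ny, nx) grid with square in-plane voxels."""
    nz, ny, nx = shape
    if orbit is None:
        orbit = max(ny, nx) * voxel  # comfortably outside the volume
    return AcquisitionGeometry(
        n_angles=n_angles,
        orbit_radius_cm=orbit,
        detector_bins=nx,
        detector_rows=nz,
        bin_size_cm=voxel,
    )


def make_model(shape, voxel=1.0, n_angles=12, mu=None, coll=None, orbit=None):
    geom = make_geometry(shape, voxel, n_angles, orbit)
    if coll is None:
        coll = CollimatorModel(enabled=False)
    return SystemModel(geom, coll, mu, shape, (voxel, voxel, voxel))


def compact_random_volume(shape, rng, voxel=1.0):
    """Random non-negative volume supported well inside the field of view,
    so rotations lose no mass."""
    nz, ny, nx = shape
    data = np.zeros(shape)
    data[
        nz // 4 : max(nz // 4 + 1, 3 * nz // 4),
        ny // 4 : 3 * ny // 4,
        nx // 4 : 3 * nx // 4,
    ] = rng.random((max(1, 3 * nz // 4 - nz // 4), ny // 2, nx // 2))
    return Volume(data, (voxel, voxel, voxel))
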