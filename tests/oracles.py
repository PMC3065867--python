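"""Naive reference implementations used as independent oracles.

These deliberately use explicit Python loops and enumerated matrices, not
the package's vectorised code paths.
"""

import math

import numpy as np

from spectrecon.projector import (
    AcquisitionGeometry,
    CollimatorModel,
    SystemModel,
)

SP1 = (1.0, 1.0, 1.0)


def naive_weighted_mean(f, window=3, spacing=SP1, selector=None):
    """Triple-loop inverse-distance weighted neighbour mean."""
    nz, ny, nx = f.shape
    h = window // 2
    out = np.zeros_like(f)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                num = den = 0.0
                for dz in range(-h, h + 1):
                    for dy in range(-h, h + 1):
                        for dx in range(-h, h + 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                                continue
                            if selector is not None and not selector(
                                f, (z, y, x), (dz, dy, dx)
                            ):
                                continue
                            w = 1.0 / math.sqrt(
                                (dz * spacing[2]) ** 2
                                + (dy * spacing[1]) ** 2
                                + (dx * spacing[0]) ** 2
                            )
                            num += w * f[zz, yy, xx]
                            den += w
                out[z, y, x] = num / den
    return out


def naive_median(f, window=3):
    """Triple-loop truncated-window median including the centre voxel."""
    nz, ny, nx = f.shape
    h = window // 2
    out = np.zeros_like(f)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                vals = [
                    f[zz, yy, xx]
                    for zz in range(max(0, z - h), min(nz, z + h + 1))
                    for yy in range(max(0, y - h), min(ny, y + h + 1))
                    for xx in range(max(0, x - h), min(nx, x + h + 1))
                ]
                out[z, y, x] = np.median(vals)
    return out


def toy_2x2_system():
    """A 1-slice 2x2 grid viewed at 0 and 90 degrees, with the system matrix
    enumerated by hand: at 0 deg each bin sums an x-column, at 90 deg each
    bin sums a y-row (the 2x2 rotation by 90 deg is an exact permutation)."""
    geom = AcquisitionGeometry(
        n_angles=2,
        orbit_radius_cm=4.0,
        detector_bins=2,
        detector_rows=1,
        bin_size_cm=1.0,
        angular_range_deg=180.0,
    )
    model = SystemModel(geom, CollimatorModel(enabled=False), None, (1, 2, 2), SP1)
    # voxel order (iy, ix): 0=(0,0) 1=(0,1) 2=(1,0) 3=(1,1)
    A = np.array(
        [
            [1, 0, 1, 0],  # angle 0, bin 0: x-column 0
            [0, 1, 0, 1],  # angle 0, bin 1
            [1, 1, 0, 0],  # angle 90, bin 0: y-row 0
            [0, 0, 1, 1],  # angle 90, bin 1
        ],
        dtype=float,
    )
    return geom, model, A
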