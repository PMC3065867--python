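"""Digital phantoms and a Poisson acquisition simulator.

Two classic image-quality phantoms are modelled:

* a hot-sphere phantom: a water cylinder (23.6 cm outer diameter) carrying
  five hollow spheres of 10/17/22/28/37 mm active diameter filled with a
  Tc-99m-water compound, mounted on a ring; the body water is inactive,
* a rod phantom: a 21.5 cm water tank with hot or cold cylindrical rods of
  graded diameters, or a uniform fill for homogeneity/noise tests.

Each builder returns the activity distribution, the attenuation map (water
inside the body, derived from the same CT-to-mu conversion as the projector),
a CT-like anatomical volume on the SPECT grid (air / body water / glass
sphere shells with partial-volume fractions) and the ground-truth geometry
used by the metrics module.  Voxels straddling object boundaries receive
partial-volume fractions via 3x supersampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projector import (
    MU_WATER_140KEV,
    AcquisitionGeometry,
    CollimatorModel,
    ProjectionSet,
    Volume,
    forward_project,
)

__all__ = [
    "SphereSpec",
    "RodSpec",
    "PhantomGeometry",
    "SpherePhantomSpec",
    "RodPhantomSpec",
    "build_sphere_phantom",
    "build_rod_phantom",
    "simulate_acquisition",
    "default_geometry",
]

HU_AIR = -1000.0
HU_WATER = 0.0
HU_GLASS = 1000.0
SHELL_THICKNESS_CM = 0.2


@dataclass
class SphereSpec:
    """Ground truth for one sphere: centre (x, y, z) in cm from the volume
    centre, active radius in cm and activity concentration."""

    centre_cm: tuple[float, float, float]
    radius_cm: float
    activity: float


@dataclass
class RodSpec:
    """Ground truth for one axial rod (cylinder along z)."""

    centre_cm: tuple[float, float]
    radius_cm: float
    activity: float


@dataclass
class PhantomGeometry:
    """Truth geometry handed to the metrics module."""

    body_radius_cm: float
    spheres: list[SphereSpec] = field(default_factory=list)
    rods: list[RodSpec] = field(default_factory=list)
    background_activity: float = 0.0


@dataclass
class SpherePhantomSpec:
    """Hot-sphere phantom layout.

    Defaults follow the physical insert (10/17/22/28/37 mm active sphere
    diameters in a 23.6 cm body) on a 128x128x64 grid with 0.47 cm voxels.
    Spheres sit on a ring at ``ring_radius_fraction`` of the body radius,
    evenly spaced in angle and ordered by size; exact mounting positions of
    the physical insert are not modelled.  Centres snap to voxel centres by
    default so that even the smallest sphere owns at least one voxel centre.
    """

    body_diameter_cm: float = 23.6
    sphere_diameters_mm: tuple[float, ...] = (10.0, 17.0, 22.0, 28.0, 37.0)
    sphere_activity: float = 1.0
    background_activity: float = 0.0
    ring_radius_fraction: float = 0.6
    start_angle_deg: float = 90.0
    voxel_size_cm: float = 0.47
    grid_shape: tuple[int, int, int] = (64, 128, 128)
    snap_to_grid: bool = True
    supersample: int = 3


@dataclass
class RodPhantomSpec:
    """Rod (resolution / homogeneity) phantom layout."""

    tank_diameter_cm: float = 21.5
    hot_rod_diameters_mm: tuple[float, ...] = (4.7, 5.9, 7.3, 9.2, 11.4, 14.3, 17.9, 22.3)
    cold_rod_diameters_mm: tuple[float, ...] = (5.9, 7.3, 9.2, 11.4, 14.3, 17.9, 22.3)
    mode: str = "uniform"  # hot | cold | uniform
    rod_activity: float = 1.0
    background_activity: float = 0.25
    ring_radius_fraction: float = 0.6
    voxel_size_cm: float = 0.47
    grid_shape: tuple[int, int, int] = (64, 128, 128)
    supersample: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("hot", "cold", "uniform"):
            raise ValueError("mode must be one of hot, cold, uniform")


# ---------------------------------------------------------------------------
# Supersampled masks
# ---------------------------------------------------------------------------

def _axis_coords(n: int, step: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * step


def _subgrid(n: int, step: float, supersample: int) -> np.ndarray:
    """Supersample point coordinates along one axis, shape (n, supersample)."""
    base = _axis_coords(n, step)
    offs = (np.arange(supersample) - (supersample - 1) / 2.0) * (step / supersample)
    return base[:, None] + offs[None, :]


def sphere_fraction(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centre_cm: tuple[float, float, float],
    radius_cm: float,
    supersample: int = 3,
) -> np.ndarray:
    """Per-voxel volume fraction inside a sphere, by supersampling.

    Evaluated only within the sphere's bounding box to keep memory modest.
    """
    nz, ny, nx = shape
    dx, dy, dz = spacing
    cx, cy, cz = centre_cm

    def _rng(c, step, n, r):
        centre = (n - 1) / 2.0
        lo = max(0, int(np.floor((c - r) / step + centre)) - 1)
        hi = min(n, int(np.ceil((c + r) / step + centre)) + 2)
        return lo, hi

    z0, z1 = _rng(cz, dz, nz, radius_cm)
    y0, y1 = _rng(cy, dy, ny, radius_cm)
    x0, x1 = _rng(cx, dx, nx, radius_cm)
    zs = _subgrid(nz, dz, supersample)[z0:z1] - cz
    ys = _subgrid(ny, dy, supersample)[y0:y1] - cy
    xs = _subgrid(nx, dx, supersample)[x0:x1] - cx
    inside = (
        (zs**2)[:, None, None, :, None, None]
        + (ys**2)[None, :, None, None, :, None]
        + (xs**2)[None, None, :, None, None, :]
    ) <= radius_cm**2
    out = np.zeros(shape)
    out[z0:z1, y0:y1, x0:x1] = inside.mean(axis=(3, 4, 5))
    return out


def cylinder_fraction(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centre_cm: tuple[float, float],
    radius_cm: float,
    supersample: int = 3,
) -> np.ndarray:
    """Per-voxel fraction inside an axial cylinder spanning the full z extent."""
    nz, ny, nx = shape
    dx, dy, dz = spacing
    cx, cy = centre_cm
    ys = _subgrid(ny, dy, supersample) - cy
    xs = _subgrid(nx, dx, supersample) - cx
    inside = ((ys**2)[:, None, :, None] + (xs**2)[None, :, None, :]) <= radius_cm**2
    frac2d = inside.mean(axis=(2, 3))
    return np.broadcast_to(frac2d, (nz, ny, nx)).copy()


def _snap(value: float, step: float, n: int) -> float:
    centre = (n - 1) / 2.0
    return (round(value / step + centre) - centre) * step


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _check_disjoint_spheres(spheres: list[SphereSpec], body_radius: float) -> None:
    for i, a in enumerate(spheres):
        ra = np.array(a.centre_cm)
        if np.hypot(ra[0], ra[1]) + a.radius_cm > body_radius:
            raise ValueError(f"sphere {i} extends outside the phantom body")
        for b in spheres[i + 1 :]:
            if np.linalg.norm(ra - np.array(b.centre_cm)) < a.radius_cm + b.radius_cm:
                raise ValueError("spheres overlap")


def build_sphere_phantom(
    spec: SpherePhantomSpec,
) -> tuple[Volume, Volume, Volume, PhantomGeometry]:
    """Build the hot-sphere phantom.

    Returns ``(activity, mu, anatomical, truth_geometry)`` on a common grid.
    """
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_cm
    spacing = (v, v, v)
    body_r = spec.body_diameter_cm / 2.0
    ring_r = spec.ring_radius_fraction * body_r

    spheres: list[SphereSpec] = []
    n_sph = len(spec.sphere_diameters_mm)
    for k, d_mm in enumerate(spec.sphere_diameters_mm):
        ang = np.deg2rad(spec.start_angle_deg + 360.0 * k / n_sph)
        cx, cy = ring_r * np.cos(ang), ring_r * np.sin(ang)
        cz = 0.0
        if spec.snap_to_grid:
            cx = _snap(cx, v, nx)
            cy = _snap(cy, v, ny)
            cz = _snap(cz, v, nz)
        spheres.append(SphereSpec((cx, cy, cz), d_mm / 20.0, spec.sphere_activity))
    _check_disjoint_spheres(spheres, body_r)

    body = cylinder_fraction(spec.grid_shape, spacing, (0.0, 0.0), body_r, spec.supersample)
    activity = spec.background_activity * body
    shell = np.zeros(spec.grid_shape)
    for s in spheres:
        frac = sphere_fraction(spec.grid_shape, spacing, s.centre_cm, s.radius_cm, spec.supersample)
        activity = activity + (s.activity - spec.background_activity) * frac
        outer = sphere_fraction(
            spec.grid_shape, spacing, s.centre_cm, s.radius_cm + SHELL_THICKNESS_CM, spec.supersample
        )
        shell += outer - frac

    mu = MU_WATER_140KEV * body
    anatomical = HU_AIR * (1.0 - body) + (HU_GLASS - HU_WATER) * shell

    truth = PhantomGeometry(body_r, spheres=spheres, background_activity=spec.background_activity)
    return (
        Volume(activity, spacing),
        Volume(mu, spacing),
        Volume(anatomical, spacing),
        truth,
    )


def build_rod_phantom(
    spec: RodPhantomSpec,
) -> tuple[Volume, Volume, Volume, PhantomGeometry]:
    """Build the rod phantom (hot rods, cold rods, or uniform fill)."""
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_cm
    spacing = (v, v, v)
    tank_r = spec.tank_diameter_cm / 2.0
    ring_r = spec.ring_radius_fraction * tank_r

    body = cylinder_fraction(spec.grid_shape, spacing, (0.0, 0.0), tank_r, spec.supersample)
    mu = MU_WATER_140KEV * body
    anatomical = HU_AIR * (1.0 - body)

    rods: list[RodSpec] = []
    if spec.mode == "uniform":
        activity = spec.rod_activity * body
        truth = PhantomGeometry(tank_r, rods=rods, background_activity=spec.rod_activity)
        return (
            Volume(activity, spacing),
            Volume(mu, spacing),
            Volume(anatomical, spacing),
            truth,
        )

    diams = spec.hot_rod_diameters_mm if spec.mode == "hot" else spec.cold_rod_diameters_mm
    n_rod = len(diams)
    background = spec.background_activity if spec.mode == "hot" else spec.rod_activity
    rod_value = spec.rod_activity if spec.mode == "hot" else 0.0
    activity = background * body
    for k, d_mm in enumerate(diams):
        ang = np.deg2rad(90.0 + 360.0 * k / n_rod)
        cx, cy = ring_r * np.cos(ang), ring_r * np.sin(ang)
        r = d_mm / 20.0
        if np.hypot(cx, cy) + r > tank_r:
            raise ValueError(f"rod {k} extends outside the tank")
        frac = cylinder_fraction(spec.grid_shape, spacing, (cx, cy), r, spec.supersample)
        activity = activity + (rod_value - background) * frac
        rods.append(RodSpec((cx, cy), r, rod_value))

    truth = PhantomGeometry(tank_r, rods=rods, background_activity=background)
    return (
        Volume(np.maximum(activity, 0.0), spacing),
        Volume(mu, spacing),
        Volume(anatomical, spacing),
        truth,
    )


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------

def default_geometry(
    grid_shape: tuple[int, int, int],
    voxel_size_cm: float,
    n_angles: int = 128,
    orbit_radius_cm: float = 24.0,
) -> AcquisitionGeometry:
    """Circular-orbit 360-degree geometry matched to the phantom grid
    (detector bins = in-plane matrix, rows = axial slices, 128 angles,
    24 cm radius of rotation by default)."""
    nz, ny, nx = grid_shape
    return AcquisitionGeometry(
        n_angles=n_angles,
        orbit_radius_cm=orbit_radius_cm,
        detector_bins=nx,
        detector_rows=nz,
        bin_size_cm=voxel_size_cm,
    )


def simulate_acquisition(
    activity: Volume,
    mu: Volume | None,
    geom: AcquisitionGeometry,
    coll: CollimatorModel,
    total_counts: float,
    seed: int,
) -> ProjectionSet:
    """Noiseless forward projection scaled to ``total_counts`` expected
    detected counts, followed by independent per-bin Poisson draws."""
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    clean = forward_project(activity, mu, geom, coll)
    total = float(clean.data.sum())
    if total <= 0:
        raise ValueError("activity projects to zero counts; nothing to simulate")
    scale = total_counts / total
    rng = np.random.default_rng(seed)
    # FFT-based blurring leaves O(1e-16) noise around exact zeros
    noisy = rng.poisson(np.maximum(scale * clean.data, 0.0)).astype(np.float64)
    return ProjectionSet(
        noisy,
        geom,
        clean.angles_deg,
        meta={"seed": int(seed), "total_counts": float(total_counts), "scale": scale},
    )
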