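"""OSEM and one-step-late (OSL) Bayesian SPECT reconstruction.

The OSEM update for subset ``S_n`` is

    f_j^new = f_j^old / (sum_{i in S_n} a_ij) * sum_{i in S_n} a_ij p_i / q_i,

with ``q = A f^old`` the estimated projections.  The OSL algorithm replaces
the sensitivity normaliser with a prior-dependent penalty factor

    c_j^P = 1 / (sum_{i in S_n} a_ij + beta * dU/df_j |_{f^old}),

evaluated at the previous iterate, so the update stays multiplicative:
``f^new = f^old * c^P * c^L``.  Three penalties are provided in their
relative (scale-free) form:

* quadratic smoothing: penalty term ``beta * (f_j - A_j) / A_j`` with ``A_j``
  an inverse-distance weighted mean over the neighbourhood,
* median root: same form with the neighbourhood median ``M_j``; it penalises
  deviations from local monotonicity rather than from local uniformity,
* Bowsher (anatomical): the smoothing form, but ``A_j`` averages only the
  ``B`` neighbours most similar to the centre voxel in a co-registered
  anatomical (CT-like) image, which confines smoothing to anatomical regions.

OSEM is the ``prior_type='none'`` / ``beta=0`` path of the same update, so
the algebraic reduction OSL(beta=0) == OSEM holds bitwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .projector import CollimatorModel, ProjectionSet, SystemModel, Volume

__all__ = [
    "SubsetScheme",
    "PriorConfig",
    "ReconConfig",
    "BowsherSelection",
    "make_subsets",
    "neighbourhood_offsets",
    "weighted_neighbour_mean",
    "neighbourhood_median",
    "smoothing_penalty_factor",
    "mrp_penalty_factor",
    "bowsher_select",
    "bowsher_penalty_factor",
    "osem_update",
    "osl_update",
    "run_reconstruction",
    "gaussian_postfilter",
    "poisson_log_likelihood",
]

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SubsetScheme:
    """An ordered partition of the angle indices into subsets."""

    n_subsets: int
    subsets: list[list[int]]

    def __post_init__(self) -> None:
        if self.n_subsets != len(self.subsets):
            raise ValueError("n_subsets does not match the subset list")
        flat = sorted(i for s in self.subsets for i in s)
        if any(len(s) == 0 for s in self.subsets):
            raise ValueError("subsets must be non-empty")
        if flat != list(range(len(flat))):
            raise ValueError("subsets must partition the full angle set")


def _bit_reversal(n: int) -> list[int]:
    bits = n.bit_length() - 1
    return [int(format(i, f"0{bits}b")[::-1], 2) if bits else 0 for i in range(n)]


def _greedy_separation_order(n: int) -> list[int]:
    order = [0]
    remaining = set(range(1, n))
    while remaining:
        last = order[-1]
        pick = max(remaining, key=lambda i: (min(abs(i - last), n - abs(i - last)), -i))
        order.append(pick)
        remaining.remove(pick)
    return order


def make_subsets(n_angles: int, n_subsets: int) -> SubsetScheme:
    """Interleaved angular subsets in a maximally separated processing order.

    Subset ``m`` holds angles ``{m, m + n_subsets, m + 2 n_subsets, ...}``.
    For power-of-two subset counts the processing order is the bit-reversal
    permutation; otherwise a greedy max-angular-separation order is used.
    """
    if n_angles < 1 or n_subsets < 1:
        raise ValueError("n_angles and n_subsets must be >= 1")
    if n_angles % n_subsets != 0:
        divisors = [d for d in range(1, n_angles + 1) if n_angles % d == 0]
        raise ValueError(
            f"n_subsets={n_subsets} does not divide n_angles={n_angles}; "
            f"valid subset counts: {divisors}"
        )
    base = [list(range(m, n_angles, n_subsets)) for m in range(n_subsets)]
    if n_subsets & (n_subsets - 1) == 0:
        order = _bit_reversal(n_subsets)
    else:
        order = _greedy_separation_order(n_subsets)
    return SubsetScheme(n_subsets, [base[m] for m in order])


@dataclass
class PriorConfig:
    """Configuration of the OSL penalty.

    ``neighbourhood`` is the odd cubic window edge (3 means 3x3x3, i.e. 26
    neighbours plus the centre).  Prior weights are the inverse Euclidean
    distance (in cm) from the centre voxel, renormalised over the neighbours
    actually present (window truncated at the volume border).
    """

    prior_type: str = "none"
    beta: float = 0.3
    neighbourhood: int = 3
    bowsher_scan: int = 18
    bowsher_B: int = 9
    anatomical: Volume | None = None

    def __post_init__(self) -> None:
        if self.prior_type not in ("none", "smooth", "mrp", "bowsher"):
            raise ValueError(f"unknown prior_type {self.prior_type!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.neighbourhood < 3 or self.neighbourhood % 2 == 0:
            raise ValueError("neighbourhood must be an odd integer >= 3")
        n_in_window = self.neighbourhood**3 - 1
        if not (1 <= self.bowsher_B <= self.bowsher_scan <= n_in_window):
            raise ValueError("require 1 <= bowsher_B <= bowsher_scan <= window size - 1")
        if self.prior_type == "bowsher" and self.anatomical is None:
            raise ValueError("bowsher prior requires an anatomical volume")


@dataclass
class ReconConfig:
    """Full reconstruction configuration (defaults mirror the study protocol:
    16 subsets, 5 iterations, beta = 0.3, 3x3x3 neighbourhood, Bowsher 18/9)."""

    n_iterations: int = 5
    n_subsets: int = 16
    prior: PriorConfig = field(default_factory=PriorConfig)
    collimator: CollimatorModel = field(default_factory=CollimatorModel)
    attenuation: Volume | None = None
    initial_value: float | None = None
    postfilter_fwhm_cm: float = 0.0
    epsilon: float = 1e-8
    grid_shape: tuple[int, int, int] | None = None
    spacing: tuple[float, float, float] | None = None
    track_likelihood: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.postfilter_fwhm_cm < 0:
            raise ValueError("postfilter_fwhm_cm must be >= 0")


# ---------------------------------------------------------------------------
# Neighbourhood machinery
# ---------------------------------------------------------------------------

def neighbourhood_offsets(window: int = 3) -> list[tuple[int, int, int]]:
    """All (dz, dy, dx) offsets of the cubic window, centre excluded,
    ordered by (Euclidean distance, lexicographic offset)."""
    h = window // 2
    offs = [
        (dz, dy, dx)
        for dz in range(-h, h + 1)
        for dy in range(-h, h + 1)
        for dx in range(-h, h + 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    offs.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o))
    return offs


def _offset_weights(offsets, spacing) -> np.ndarray:
    dx, dy, dz = spacing
    return np.array(
        [1.0 / math.sqrt((o[0] * dz) ** 2 + (o[1] * dy) ** 2 + (o[2] * dx) ** 2) for o in offsets]
    )


def _shifted(padded: np.ndarray, off, shape, h: int) -> np.ndarray:
    """View of the padded array giving neighbour values f[j + off]."""
    dz, dy, dx = off
    nz, ny, nx = shape
    return padded[h + dz : h + dz + nz, h + dy : h + dy + ny, h + dx : h + dx + nx]


def weighted_neighbour_mean(
    f: np.ndarray,
    offsets,
    weights: np.ndarray,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Inverse-distance weighted neighbour mean ``A_j``.

    Weights are renormalised over the neighbours present in the volume (and,
    if ``selection`` is given, over the selected offsets only).
    """
    h = max(max(abs(c) for c in o) for o in offsets)
    padded = np.pad(f, h)
    mask = np.pad(np.ones(f.shape), h)
    num = np.zeros(f.shape)
    den = np.zeros(f.shape)
    for k, (off, w) in enumerate(zip(offsets, weights)):
        valid = _shifted(mask, off, f.shape, h)
        if selection is not None:
            valid = valid * selection[k]
        num += w * valid * _shifted(padded, off, f.shape, h)
        den += w * valid
    return num / np.maximum(den, np.finfo(np.float64).tiny)


def neighbourhood_median(f: np.ndarray, window: int = 3) -> np.ndarray:
    """Median over the cubic window including the centre voxel, truncated at
    the volume border."""
    h = window // 2
    padded = np.pad(f.astype(np.float64), h, constant_values=np.nan)
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window, window))
    return np.nanmedian(view.reshape(f.shape + (-1,)), axis=-1)


# ---------------------------------------------------------------------------
# Penalty factors
# ---------------------------------------------------------------------------

def _penalty_factor(sens, beta, f, ref, epsilon):
    """1 / (sensitivity + beta (f - ref)/max(ref, eps)), denominator floored.

    The floor guards the known OSL failure mode where a large beta drives the
    denominator non-positive; clamped voxels are counted and logged.
    """
    floor = epsilon * max(float(np.mean(sens)), np.finfo(np.float64).tiny)
    den = sens + beta * (f - ref) / np.maximum(ref, epsilon)
    clamped = int(np.count_nonzero(den < floor))
    if clamped:
        log.debug("OSL penalty denominator clamped at %d voxels", clamped)
    return 1.0 / np.maximum(den, floor)


def smoothing_penalty_factor(
    f_old: Volume,
    prior: PriorConfig,
    sensitivity: np.ndarray,
    epsilon: float,
    offsets=None,
) -> np.ndarray:
    """Quadratic smoothing penalty factor (relative form)."""
    if offsets is None:
        offsets = neighbourhood_offsets(prior.neighbourhood)
    weights = _offset_weights(offsets, f_old.spacing)
    A = weighted_neighbour_mean(f_old.data, offsets, weights)
    return _penalty_factor(sensitivity, prior.beta, f_old.data, A, epsilon)


def mrp_penalty_factor(
    f_old: Volume, prior: PriorConfig, sensitivity: np.ndarray, epsilon: float
) -> np.ndarray:
    """Median root penalty factor: pulls voxels towards the window median."""
    M = neighbourhood_median(f_old.data, prior.neighbourhood)
    return _penalty_factor(sensitivity, prior.beta, f_old.data, M, epsilon)


@dataclass
class BowsherSelection:
    """Precomputed Bowsher neighbour selection.

    ``mask[k]`` flags, per voxel, whether scanned offset ``k`` is among the
    ``B`` anatomically most similar neighbours.  The selection depends only on
    the anatomical image, so it is computed once per reconstruction.
    """

    offsets: list[tuple[int, int, int]]
    mask: np.ndarray  # (n_scan,) + volume shape, bool


def bowsher_select(anatomical: Volume, prior: PriorConfig) -> BowsherSelection:
    """Select, per voxel, the ``bowsher_B`` scanned neighbours with the
    smallest absolute anatomical difference to the centre voxel.

    The ``bowsher_scan`` nearest in-window offsets are examined (18 with the
    default 3x3x3 window: the face and edge neighbours).  Ties in anatomical
    difference are broken by smaller centre distance, then lexicographic
    offset order.  Border voxels with fewer than ``B`` in-volume candidates
    keep all available ones.
    """
    offsets = neighbourhood_offsets(prior.neighbourhood)[: prior.bowsher_scan]
    ct = anatomical.data
    h = prior.neighbourhood // 2
    padded = np.pad(ct, h, constant_values=np.inf)
    shape = ct.shape
    diffs = np.empty((len(offsets),) + shape)
    for k, off in enumerate(offsets):
        nb = _shifted(padded, off, shape, h)
        d = np.abs(nb - ct)
        d[~np.isfinite(d)] = np.inf
        diffs[k] = d
    # offsets are pre-ordered by (distance, lex), so a stable argsort on the
    # anatomical difference realises the tie-break rule
    order = np.argsort(diffs, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(len(offsets)).reshape((-1,) + (1,) * ct.ndim), axis=0)
    mask = (ranks < prior.bowsher_B) & np.isfinite(diffs)
    return BowsherSelection(offsets, mask)


def bowsher_penalty_factor(
    f_old: Volume,
    prior: PriorConfig,
    selection: BowsherSelection,
    sensitivity: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """Anatomical (Bowsher) penalty factor: the smoothing form with ``A_j``
    averaged over the selected neighbours only."""
    weights = _offset_weights(selection.offsets, f_old.spacing)
    A = weighted_neighbour_mean(f_old.data, selection.offsets, weights, selection.mask)
    return _penalty_factor(sensitivity, prior.beta, f_old.data, A, epsilon)


# ---------------------------------------------------------------------------
# Updates
# ---------------------------------------------------------------------------

def _prior_factor(
    f: Volume,
    prior: PriorConfig | None,
    sens: np.ndarray,
    epsilon: float,
    selection: BowsherSelection | None,
) -> np.ndarray:
    floor = epsilon * max(float(np.mean(sens)), np.finfo(np.float64).tiny)
    if prior is None or prior.prior_type == "none":
        return 1.0 / np.maximum(sens, floor)
    if prior.prior_type == "smooth":
        return smoothing_penalty_factor(f, prior, sens, epsilon)
    if prior.prior_type == "mrp":
        return mrp_penalty_factor(f, prior, sens, epsilon)
    if prior.prior_type == "bowsher":
        if selection is None:
            selection = bowsher_select(prior.anatomical, prior)
        return bowsher_penalty_factor(f, prior, selection, sens, epsilon)
    raise ValueError(f"unknown prior_type {prior.prior_type!r}")


def _osl_step(
    f_data: np.ndarray,
    p: ProjectionSet,
    subset,
    model: SystemModel,
    prior: PriorConfig | None,
    epsilon: float,
    selection: BowsherSelection | None,
    spacing,
):
    subset = list(subset)
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    q = model.forward(f_data, subset)
    ratio = p.data[subset] / np.maximum(q, epsilon)
    c_l = model.back(ratio, subset)
    sens = model.subset_sensitivity(subset)
    c_p = _prior_factor(Volume(f_data, spacing), prior, sens, epsilon, selection)
    return f_data * c_p * c_l, q


def _check_update_inputs(f_old: Volume, p: ProjectionSet, model: SystemModel) -> None:
    if f_old.shape != model.grid_shape:
        raise ValueError("image grid does not match the system model")
    if p.data.shape[1:] != (model.grid_shape[0], model.grid_shape[2]):
        raise ValueError("projection shape does not match the system model")


def osem_update(
    f_old: Volume, p: ProjectionSet, subset, model: SystemModel, epsilon: float = 1e-8
) -> Volume:
    """One OSEM subiteration: multiply by the back-projected measured/estimated
    projection ratio, normalised by the subset sensitivity."""
    _check_update_inputs(f_old, p, model)
    new, _ = _osl_step(f_old.data, p, subset, model, None, epsilon, None, f_old.spacing)
    return f_old.copy_with(new)


def osl_update(
    f_old: Volume,
    p: ProjectionSet,
    subset,
    model: SystemModel,
    prior: PriorConfig,
    epsilon: float = 1e-8,
    selection: BowsherSelection | None = None,
) -> Volume:
    """One OSL subiteration: the OSEM correction factor times the penalty
    factor of the configured prior, both evaluated at the previous iterate."""
    _check_update_inputs(f_old, p, model)
    new, _ = _osl_step(f_old.data, p, subset, model, prior, epsilon, selection, f_old.spacing)
    return f_old.copy_with(new)


def poisson_log_likelihood(p_data: np.ndarray, q_data: np.ndarray, epsilon: float = 1e-12) -> float:
    """Poisson data log-likelihood sum(p ln q - q), constants dropped."""
    q = np.maximum(q_data, epsilon)
    return float(np.sum(p_data * np.log(q) - q))


def gaussian_postfilter(vol: Volume, fwhm_cm: float) -> Volume:
    """3-D Gaussian smoothing given as full-width at half maximum (cm).

    ``sigma = FWHM / (2 sqrt(2 ln 2))`` converted per-axis by voxel spacing;
    zero FWHM is the identity; total counts are preserved away from borders.
    """
    if fwhm_cm < 0:
        raise ValueError("fwhm_cm must be >= 0")
    if fwhm_cm == 0:
        return vol.copy_with(vol.data.copy())
    from .projector import _diffuse  # same variance-exact kernel chain

    sigma = fwhm_cm * FWHM_TO_SIGMA
    dx, dy, dz = vol.spacing
    out = vol.data
    for axis, sp in ((0, dz), (1, dy), (2, dx)):
        out = _diffuse(out, (sigma / sp) ** 2, axes=(axis,))
    return vol.copy_with(out)


def run_reconstruction(
    p: ProjectionSet,
    cfg: ReconConfig,
    model: SystemModel | None = None,
) -> Volume:
    """Run a full OSEM/OSL reconstruction.

    Starts from a uniform positive volume (total measured counts per voxel),
    loops ``n_iterations`` over all subsets in the scheme's processing order,
    and applies the Gaussian post-filter if ``postfilter_fwhm_cm > 0``.
    Per-subiteration records (iteration, subset, min/max voxel and, for
    full-data subsets or when ``track_likelihood`` is set, the Poisson
    log-likelihood) are stored in the returned volume's ``meta['log']``.
    """
    geom = p.geometry
    if model is None:
        if cfg.attenuation is not None:
            grid_shape = cfg.attenuation.shape
            spacing = cfg.attenuation.spacing
        else:
            if cfg.grid_shape is None or cfg.spacing is None:
                raise ValueError(
                    "grid_shape and spacing are required when no attenuation map is given"
                )
            grid_shape = cfg.grid_shape
            spacing = cfg.spacing
        model = SystemModel(geom, cfg.collimator, cfg.attenuation, grid_shape, spacing)
    grid_shape = model.grid_shape
    spacing = model.spacing
    scheme = make_subsets(geom.n_angles, cfg.n_subsets)

    selection = None
    prior = cfg.prior
    if prior is not None and prior.prior_type == "bowsher":
        if not Volume(np.zeros(grid_shape), spacing).same_grid(prior.anatomical):
            raise ValueError("anatomical volume grid does not match the reconstruction grid")
        selection = bowsher_select(prior.anatomical, prior)

    init = cfg.initial_value
    if init is None:
        init = max(float(p.data.sum()) / np.prod(grid_shape), cfg.epsilon)
    if init <= 0:
        raise ValueError("initial_value must be positive")
    f = np.full(grid_shape, init)

    records = []
    full = geom.n_angles
    for it in range(cfg.n_iterations):
        for s_idx, subset in enumerate(scheme.subsets):
            f, q = _osl_step(f, p, subset, model, prior, cfg.epsilon, selection, spacing)
            rec = {
                "iteration": it,
                "subset": s_idx,
                "min": float(f.min()),
                "max": float(f.max()),
            }
            if len(subset) == full:
                rec["log_likelihood"] = poisson_log_likelihood(p.data[subset], q)
            elif cfg.track_likelihood:
                rec["log_likelihood"] = poisson_log_likelihood(p.data, model.forward(f))
            records.append(rec)
            log.debug("iter %d subset %d: min=%g max=%g", it, s_idx, rec["min"], rec["max"])

    out = Volume(f, spacing, {"log": records, "prior": prior.prior_type if prior else "none"})
    if cfg.postfilter_fwhm_cm > 0:
        out = gaussian_postfilter(out, cfg.postfilter_fwhm_cm)
        out.meta.setdefault("postfilter_fwhm_cm", cfg.postfilter_fwhm_cm)
    return out
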