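# Methods

This note records the models, numerical choices and limitations behind
`spectrecon` — what the projector, the reconstruction updates, the phantoms
and the metrics actually compute, and why the open design points were
settled the way they were.

## System model

The projector implements parallel-beam, circular-orbit SPECT on a voxel
grid indexed `[z, y, x]` with square in-plane voxels. Per gantry angle the
operator chain is:

1. **Rotation.** The volume is rotated about the axial axis so the detector
   lies on the +y side, using bilinear interpolation expressed as a cached
   sparse matrix. Matrix columns are renormalised to unit sum
   (mass-preserving rotation): every voxel fully inside the field deposits
   exactly its value into the rotated frame, which makes per-angle
   projection sums conserve counts to machine precision for compactly
   supported activity. Voxels rotating out of the square field keep their
   partial weight — those counts are genuinely lost, which is the documented
   boundary rule. The back-projector applies the transpose of the same
   matrix, so the adjoint is exact rather than an independent
   discretisation; the dot-product identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to
   ~1e-16 with and without attenuation and collimator blur, and the
   multiplicative EM updates inherit that consistency.

2. **Attenuation.** Transmission factors are computed by summing the rotated
   attenuation map along the projection columns, with a half-voxel self
   term: `factor_j = exp(−Δ·(μ_j/2 + Σ downstream μ))`. The μ-map comes
   either from the phantom builders (water at 0.1537 cm⁻¹ for 140 keV) or
   from `ct_to_mu`, a bilinear HU conversion with the breakpoint at water:
   linear from air (−1000 HU → 0) to water (0 HU → μ_water(E)), and half
   that slope above 0 HU toward bone. μ_water(E) is log-log interpolated
   from an embedded table of narrow-beam water values.

3. **Collimator response.** The distance-dependent PSF is Gaussian with
   σ(d) = σ₀ + slope·d (defaults σ₀ = 0.18 cm, slope = 0.025, an LEHR-like
   parallel-hole response; both configurable — they are generic defaults,
   not a calibration of any particular camera). It is applied as
   *incremental Gaussian diffusion*: sweeping planes from farthest to
   nearest the detector, the accumulated projection is blurred after each
   plane by the variance increment σ(d_m)² − σ(d_m+1)², so plane *m* ends up
   carrying exactly σ(d_m)².

### Why the diffusion kernel is the discrete heat kernel

The per-plane variance increments are far below one pixel² (≈0.04 px² at
0.47 cm voxels), where truncated sampled Gaussians blur much less than their
nominal σ, and positive variance-matched 3-tap kernels carry the wrong
fourth moment, so a chain of many small steps visibly disagrees with a
single blur of the total width. The diffusion step is therefore implemented
spectrally: per axis, a circular convolution with multiplier
`exp(−V(1 − cos ω))`, whose space-domain kernel is the modified-Bessel heat
kernel `e^(−V) I_k(V)`. This kernel is

* strictly positive — the implicit system matrix stays non-negative, so the
  EM likelihood guarantees survive;
* symmetric and unit-sum — exactly self-adjoint and count-preserving;
* an exact semigroup with exactly additive variance — chaining increments
  equals one blur of the summed variance to machine precision, and the
  measured second moment of a blurred point source equals σ(d)².

The boundary rule is periodic wrap rather than zero padding. All phantom
content and its blur tails live well inside the detector extent at the
widths used (σ ≤ ~1.1 cm over a 30 cm field), so wrap-around is negligible;
users projecting objects near the field edge should enlarge the grid.

## Reconstruction

OSEM and the OSL Bayesian variants share one update path:
`f ← f · c^P · c^L`, with `c^L` the back-projected measured/estimated
projection ratio over the subset and `c^P = 1/(subset sensitivity + β·T)`
the penalty factor. For OSEM (or β = 0) the penalty term `T` is zero and
`c^P` is the reciprocal subset sensitivity — the two algorithms are the same
code path, so their equivalence at β = 0 is bitwise.

The penalty terms are *relative* (scale-free):

* smoothing: `T = (f_j − A_j)/A_j` with `A_j` the inverse-distance weighted
  mean over the 26 neighbours of the 3×3×3 window. The weights are
  normalised to unit sum over the neighbours actually present (the window
  truncates at the volume border); without that normalisation a uniform
  image would not be a fixed point.
* median root: `T = (f_j − M_j)/M_j`, `M_j` the median over the full 27-voxel
  window including the centre, truncated at borders. The median of a locally
  monotone neighbourhood is the centre value, so ramps pass unpenalised —
  the edge-preserving property.
* Bowsher (anatomical): the smoothing form with `A_j` averaged over the
  B = 9 of the 18 nearest offsets (face + edge neighbours) whose anatomical
  values are closest to the centre voxel's. Ties in anatomical difference
  break by smaller centre distance, then lexicographic offset; the selection
  depends only on the anatomical image and is precomputed once per
  reconstruction. Inside the selected set the same inverse-distance weights
  are used (uniform weighting would also be defensible; inverse-distance
  keeps the prior consistent with the smoothing case it reduces to). Border
  voxels with fewer than B in-volume candidates keep all of them.

Numerical safeguards: estimated projections and the reference values
`A_j`/`M_j` are floored at ε (default 1e-8) before division, and the OSL
denominator is floored at ε × mean(sensitivity) — the known OSL failure mode
where a large β drives the denominator non-positive; clamped voxel counts
are logged at debug level. The initial estimate is a uniform volume at
(total measured counts)/(number of voxels); multiplicative updates cannot
leave zero, so the start must be positive. Subsets interleave angles
(subset m takes angles m, m+S, …) and are processed in bit-reversal order
for power-of-two subset counts (a greedy max-angular-separation order
otherwise). The Poisson log-likelihood Σ(p ln q − q) is recorded per
subiteration whenever the subset spans all angles (MLEM), where it comes
free from the update's own forward projection; for subset runs it is only
computed on request, since it would otherwise double the cost.

The optional post-filter is a 3-D Gaussian given as FWHM
(σ = FWHM/(2√(2 ln 2)), converted per axis by voxel spacing), built from the
same heat-kernel primitive. Following the phantom protocol it is applied to
plain OSEM runs only when requested; the Bayesian runs are left unfiltered.

## Phantoms and simulation

Two digital phantoms emulate standard image-quality hardware:

* **Hot-sphere phantom**: a 23.6 cm water cylinder with five hollow spheres
  of 10/17/22/28/37 mm active diameter filled hot, body cold. Spheres sit on
  a ring at 60% of the body radius, evenly spaced, ordered by size; the
  physical insert's exact mounting positions are not modelled, and centres
  snap to voxel centres by default so the smallest sphere's ROI always owns
  at least one voxel centre.
* **Rod phantom**: a 21.5 cm tank with hot or cold axial rods of graded
  diameters, or a uniform fill for homogeneity/noise studies.

Object masks are rendered with 3× supersampling, giving partial-volume
fractions at boundaries accurate to well under 1% in total volume. The
anatomical volume is generated directly on the emission grid: air at
−1000 HU, body water at 0 HU, and 2 mm glass sphere shells at +1000 HU with
partial-volume fractions — the shells are what the Bowsher prior sees, as
the sphere interiors are water like the body. Acquisition simulation scales
the noiseless forward projection to a target total count and draws
independent Poisson counts per bin with a recorded seed.

What the simulation deliberately omits: scatter, septal penetration,
detector energy response, and model mismatch — the reconstruction uses the
same PSF and attenuation as the simulation (an "inverse crime"). Passing
studies therefore demonstrate the algorithmic behaviour of the priors under
ideal modelling, not clinical performance; on real data the resolution
recovery is less complete and the artefact/contrast balance shifts.

## Metrics

* **Contrast**: `C = (A_sph − A_bg)/(A_sph + A_bg)` with voxel-centre-in-
  circle ROIs on the axial slice through each sphere centre. The hot ROI is
  a disc of 0.8× the true radius; the background annulus runs from 1.2× to
  1.6× the radius. The gap between 0.8r and 1.2r belongs to neither ROI: an
  annulus starting at the hot ROI edge would overlap the sphere rim, so even
  the ground-truth phantom could not reach C = 1 on a zero background. With
  the gap, the truth volume scores exactly 1.0 for spheres larger than a few
  voxels (the 17 mm sphere keeps a small partial-volume residue). ROI masks
  are built once from the truth geometry and shared across all
  reconstructions of a study.
* **Profiles**: trilinear interpolation along a line through the sphere
  centre (default +x, half-voxel steps), optionally with the top-hat truth
  profile scaled to the reconstruction's maximum.
* **Ringing index**: with P_centre the mean over the central 20% of the
  object half-width and P_edge the mean of the maxima of the left and right
  in-object flanks, the index is max(0, (P_edge − P_centre)/P_edge). A
  top-hat or any single-peaked profile scores 0; a profile whose centre has
  collapsed to half its edge peaks scores 0.5.
* **Interior coefficient of variation**: std/mean over the phantom body
  eroded by 2 cm with (dilated) inserts removed; NaN when the region mean is
  not meaningfully positive.

## Study sizes

The bundled studies run on a 64×64 in-plane matrix of 0.47 cm voxels
(30 cm field of view, 32 slices), 128 angles on a 24 cm circular orbit, and
2×10⁶ detected counts, with 16 subsets × 5 iterations, β = 0.3, 3×3×3
neighbourhoods and Bowsher 18/9. Keeping the clinical voxel size while
halving the matrix preserves the sphere-to-PSF-to-voxel ratios that the
ringing artefact depends on; at 0.94 cm voxels the largest sphere spans only
four voxels and the artefact cannot be expressed at all. The MLEM
monotonicity check runs 20 one-subset iterations on a 64×64×8 slab of the
same phantom.

## Observed behaviour and known limitations

Under these study conditions the package reproduces the qualitative
published picture: only RR rings on the largest sphere (index ≈ 0.12, all
priors 0), contrast always orders NORR < SMOOTH < MRP, the anatomical prior
gives the best contrast on the large spheres, and uniform-region noise
orders SMOOTH < MRP < RR. Two margins are worth knowing about, both
seed-stable and persisting in the noiseless limit (they are properties of
the study conditions, not noise):

* On the 28 mm sphere MRP's contrast slightly exceeds RR's (≈0.936 vs
  0.931). That sphere sits at the resolution limit where RR's edge
  overshoots have not yet merged into a single peak; the unresolved central
  dip costs RR inner-ROI mean that the median root prior recovers. On
  physical acquisitions — higher counts, scatter background, imperfect PSF
  modelling — RR retains a contrast edge over MRP on all sphere sizes.
* The SMOOTH/MRP noise ordering is tight (≈0.081 vs 0.084) and inverts at
  coarser voxels, where each voxel collects more counts and the median pull
  becomes the stronger suppressor.

Other limitations: parallel-beam circular orbits only (no fan/cone beam,
no non-circular orbits), no scatter or septal-penetration modelling, no
DICOM/Interfile ingestion (NIfTI and a raw float32 + JSON sidecar dialect
are supported), and the Bowsher prior is only as good as the anatomical
image — with sphere interiors CT-identical to the body, all anatomical
guidance comes from the partial-volume shells.
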