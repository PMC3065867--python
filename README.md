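# spectrecon

Iterative SPECT reconstruction with distance-dependent collimator-response
modelling and one-step-late (OSL) Bayesian priors, together with the digital
phantoms and metrics needed to study the Gibbs-like **ringing artefacts**
that collimator correction can carve into hot objects.

Collimator response correction ("resolution recovery", RR) sharpens
reconstructed SPECT images and lowers noise, but the deconvolution it
performs overshoots at edges: large hot spheres come out with a dark hole in
the middle and a two-peaked line profile. This package implements and
compares five reconstruction methods on simulated phantom acquisitions:

| label  | method |
|--------|--------|
| NORR   | OSEM without collimator modelling |
| RR     | OSEM with collimator modelling |
| SMOOTH | OSL with a quadratic smoothing prior |
| MRP    | OSL with the median root prior |
| AMAP   | OSL with the anatomical (Bowsher) prior guided by a CT-like image |

## The algorithms

The OSEM update for subset *Sₙ* of the projections *p* is

```
f_j^new = f_j^old / (Σ_{i∈Sₙ} a_ij) · Σ_{i∈Sₙ} a_ij · p_i / Σ_k a_ik f_k^old
```

where `a_ij` is the probability that an emission in voxel *j* is detected in
projection pixel *i*. The system model is rotation-based: per angle the
volume is rotated so the detector is axis-aligned (a mass-preserving
bilinear sparse operator), attenuated by summing the rotated μ-map along
projection columns, and blurred plane-by-plane with incremental Gaussian
diffusion so each plane receives the collimator PSF width σ(d) = σ₀ + k·d
for its distance *d* from the detector. The back-projector is the exact
adjoint of the forward operator.

The OSL Bayesian update multiplies the image with the OSEM correction factor
`c^L` and a penalty factor

```
c_j^P = 1 / (Σ_{i∈Sₙ} a_ij + β · (f_j − R_j) / R_j)
```

where the reference `R_j` is the inverse-distance weighted neighbourhood
mean (smoothing prior), the 3×3×3 neighbourhood median (median root prior),
or the weighted mean over the *B* = 9 of 18 scanned neighbours most similar
to the centre voxel in a co-registered anatomical image (Bowsher prior).
β is the Bayesian weight (default 0.3).

Contrast is evaluated with concentric circular ROIs:
`C = (A_sph − A_bg)/(A_sph + A_bg)`, and ringing with a profile-based index
measuring the relative dip of the sphere centre below the in-object edge
peaks (0 = no artefact, → 1 = deep hole).

## Worked example

Simulate the hot-sphere phantom (five spheres of 10–37 mm active diameter
in a 23.6 cm water cylinder, spheres hot, body cold) on a 64×64×32 grid of
0.47 cm voxels, acquire 2×10⁶ counts over 128 angles at a 24 cm orbit, and
reconstruct with all five methods (16 subsets × 5 iterations):

```python
from spectrecon import SpherePhantomSpec
from spectrecon.io import StudyConfig, run_study

spec = SpherePhantomSpec(grid_shape=(32, 64, 64), voxel_size_cm=0.47)
res = run_study(StudyConfig(phantom=spec, total_counts=2e6, seed=1))
df = res.metrics
print(df[df.diameter_mm == 37.0][["method", "contrast", "ringing"]]
      .to_string(index=False))
```

```
method  contrast  ringing
  NORR  0.797477 0.000000
    RR  0.968541 0.124938
   MRP  0.951061 0.000000
SMOOTH  0.919784 0.000000
  AMAP  0.998996 0.000000
```

Read: without collimator modelling (NORR) the 37 mm sphere recovers only
~0.80 contrast because unmodelled blur spills activity out of the sphere.
Resolution recovery (RR) restores contrast to 0.97 but rings — the profile
through the sphere dips ~12% below its edge peaks. All three Bayesian
priors suppress the dip to zero; the anatomical prior does so while keeping
the highest contrast, the smoothing prior trades the most contrast for it.

The same driver runs a uniform-cylinder noise study (`RodPhantomSpec` with
`mode="uniform"`), where the interior coefficient of variation orders
SMOOTH < MRP < RR — the priors' noise suppression.

A command-line interface mirrors the library:

```
spectrecon phantom --type spheres --out-dir ph/
spectrecon simulate --activity ph/activity.f32 --mu ph/mu.f32 --seed 1 --out ph/proj.f32
spectrecon recon --projections ph/proj.f32 --mu ph/mu.f32 --prior mrp --out ph/recon_MRP.f32
spectrecon metrics --study-dir ph/ --geometry ph/geometry.json --out ph/table.csv
spectrecon study --seed 1 --out-dir study/
```

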