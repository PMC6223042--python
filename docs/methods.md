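# Methods

This note documents the models, defaults and numerical choices behind
`cbcthm`: what each stage assumes, which parameters matter, what the
synthetic phantom does and does not emulate, and where the design was
genuinely open.

## Problem and workflow

A planning CT (pCT, the HU reference) and a cone-beam CT (CBCT, HU-corrupt)
of the same subject are given. The workflow estimates a spatial transform
`T` mapping CBCT (fixed-image) points into the pCT (moving image), resamples
the pCT through `T` onto the CBCT grid, and replaces each CBCT intensity by
the deformed-pCT intensity of equal cumulative probability. Four arms are
compared: rigid alignment only (`RR-MI`) and rigid + deformable registration
under NCC, MI or NMI (`DR-NCC`, `DR-MI`, `DR-NMI`). All statistics treat the
deformed pCT as the reference.

## Coordinate and image model

Volumes are scalar HU grids indexed `(z, y, x)` with per-axis spacing and an
origin in mm; the physical position of voxel `(i, j, k)` is
`origin + index·spacing`. No rotation is stored on images; orientation is
the transforms' business. Background air is exactly −1000 HU after
preprocessing. File I/O (NIfTI, MetaImage) goes through SimpleITK.

## Preprocessing

Body segmentation thresholds at −700 HU (pCT) / −600 HU (CBCT), closes with
a radius-2 structuring element (edge-padded so anatomy touching the axial
volume boundary is not eroded), keeps the largest 3D connected component
(which removes couch remnants without manual cropping), and fills interior
holes so internal gas (rectum) stays inside the body mask. Exterior voxels
are set to −1000 HU. The operation is idempotent, and lowering the
threshold can only grow the mask.

## Transforms

*Rigid*: `T(x) = R(x − c) + c + t` with Euler angles about the z/y/x axes
and the fixed-volume centre as `c`.

*Deformable*: uniform cubic B-spline free-form deformation. A control grid
(origin/spacing/shape of its own) carries displacement vectors; the dense
displacement is the separable cubic B-spline tensor-product interpolation,
evaluated either through precomputed 4³-tap weights (during optimization,
where the same weights also give the analytic parameter gradient) or
through `scipy.ndimage.map_coordinates(order=3, prefilter=False)` on the
coefficient arrays (dense resampling); the two paths agree to machine
precision. Because the basis weights form a convex combination, the dense
field never exceeds the largest control displacement — this bounds the
ground-truth warp and underlies its fold-free guarantee.

*Composite*: `T(x) = T_rigid(x) + u(x)` with the deformation grid defined
on the fixed image. The rigid stage's output is composed into, not merely
used to initialize, the deformable result.

## Similarity metrics

All metrics compare fixed values `I_F(x_i)` with interpolated moving values
`I_M(T(x_i))` over a sampling domain restricted to the fixed-image body
mask (otherwise the dominant air background swamps the statistics).

* NCC is the Pearson correlation of the two samples; constant samples raise
  a degenerate-sample error rather than returning NaN.
* MI/NMI use a joint histogram over equal-width bins spanning each sample's
  intensity range (64 bins by default). For optimization the histogram is
  Parzen-windowed with cubic B-spline kernels on both intensity axes, which
  makes the metrics differentiable in the moving values; entropies are in
  nats (NMI is base-invariant; MI values are internal to the optimizer).
  Hard binning is available and is what the test-suite oracles use.

Analytic gradients: for NCC the closed-form derivative of the correlation;
for MI/NMI the standard kernel-derivative form — terms proportional to the
kernel-derivative sums vanish because cubic B-spline derivative weights sum
to zero. Values clamped to the histogram range receive zero gradient.

## Optimization (ASGD)

Each iteration draws a fresh random subset of fixed-mask voxel sites
(2048 by default, with ±half-voxel jitter), computes the metric gradient
with respect to the transform parameters through the chain
`dM/dparam = Σ_i (dM/dm_i) ∇I_M(T(x_i)) · ∂T/∂param`, and ascends with step
`a/(A + t)^α`, A = 20, α = 0.602, 256 iterations per level. The gain `a` is
auto-scaled so the first update moves the largest parameter by a prescribed
physical length (2 mm at full resolution, ×4/×2 at the coarser levels);
rigid angles are optimized in arc-length units (scaled by the mean lever
arm of the mask) so rotations and translations share one step size. Three
safeguards matter in practice:

* **Trust cap** — every update is bounded at the current decayed step
  length, so one noisy gradient cannot throw the iterate.
* **Polyak averaging** — parameters are averaged over the last quarter of
  each level's iterations, damping sampling noise.
* **No-harm guard** — each level keeps its result only if it improves a
  held-out 16384-site metric evaluation by more than 1e−3; otherwise the
  level is reverted. Without this, stochastic gradients drift visibly when
  the images are already aligned (the gradient is then pure noise). The
  guard judges MI-driven levels by NMI: raw Parzen MI can be inflated by a
  degenerate warp that sharpens the intensity histogram without improving
  alignment, and NMI normalizes that artifact out.

*Multi-resolution*: 3 levels, decimation factors (4, 2, 1) with Gaussian
pre-smoothing sigmas (4, 2, 0.5) expressed in units of the smallest voxel
size and converted per axis to physically isotropic smoothing — CT slices
are ~3× thicker than the in-plane pitch, and smoothing "per voxel" would
over-blur exactly the axis with the least information. The B-spline grid
spacing follows (×4, ×2, ×1) of the final 32 mm; each refinement samples
the previous dense field at the new control points and prefilters
(`spline_filter`) into interpolating coefficients.

Every random draw comes from `SeedSequence`-derived generators, so a given
configuration and seed reproduces results bit-for-bit.

## Histogram matching

Cumulative histograms of CBCT and deformed pCT are built over 1024
equal-width bins inside the intersection of the CBCT body mask and the
deformed-pCT body support (the two fields of view differ — the pCT covers
more slices — and unequal coverage would bias the CDFs). The mapping sends
each source level to the lowest reference level of equal cumulative value,
linearly interpolated between bin edges and made monotone by a running
maximum; it is applied to the whole CBCT body, leaving the −1000 background
pinned. Matching is 3D over the volume, not slice-wise. The map is accurate
to about half a bin wherever the histograms have mass; across empty-bin
runs (sparse distribution tails) the inversion is arbitrary within the gap.
Re-deriving the LUT from the corrected volume is a near fixed point (≤1% of
voxels move by more than 1 HU).

## Evaluation

* `V_err`: root-mean-square HU difference over the masked evaluation
  domain (CBCT body ∩ deformed-pCT body).
* Binned MAE: voxels are binned by their *reference* HU into 20-HU bins
  whose centres sit at multiples of 20 (half-open `[c−10, c+10)`); each bin
  reports mean |ΔHU|, its voxel count, and the tissue class of its centre
  (air < −400 ≤ soft tissue < 250 ≤ soft bone ≤ 600 < bone; boundary values
  go to the upper class by the half-open convention, with 600 HU kept in
  soft bone). Empty bins are undefined (NaN), never zero.
* Uniformity RMSD: 10×10-pixel axial ROIs inside a single tissue, ≥5 per
  tissue, placed by a deterministic greedy scan. Per pair, RMSD is across
  that pair's ROIs; per cohort, it is across subjects of the per-subject
  mean ROI value — the only reading that yields one RMSD per tissue per
  algorithm column.

## The phantom: what it emulates and what it does not

One synthetic subject is an elliptical soft-tissue body (muscle, +50 HU)
with a subcutaneous fat ring (−100 HU), two femoral heads (bone +900 HU
core, soft-bone +400 HU rim), and a rectal gas pocket (−980 HU), with ±6%
axial taper so the anatomy genuinely varies along z. Soft tissue carries a
smooth random texture field (25 HU, 8 mm correlation) plus white HU jitter
(8 HU) — the texture is what makes deformable registration identifiable
away from tissue boundaries. Grids follow clinical protocols: pCT
0.8496 × 0.8496 × 3 mm; CBCT 0.8789 × 0.8789 × 2.5 mm, axially cropped to
~40% of the pCT extent. The default pCT grid is 48 × 160 × 160 (a compact
pelvis-like field of view chosen so a full four-arm cohort runs in minutes
on one CPU; a 48 × 96 × 96 variant at 1.42 mm in-plane pitch serves the
registration-recovery experiments).

The CBCT is derived from the pCT by a random smooth B-spline warp (control
spacing 48 mm, uniform ±8 mm control displacements, zeroed on a two-layer
border band — amplitude below half the control spacing keeps the warp
fold-free), resampling onto the CBCT grid, and, inside the warped body,
`v → v·s(x) + b + ε` with a −60 HU global shift `b`, a multiplicative
cupping field `s` (10% central depression modulated by a seeded
low-frequency random field, 40 mm scale), and Gaussian noise ε (σ = 20 HU).
These magnitudes were chosen to land the uncorrected volume error in the
several-tens-of-HU regime typical of clinical cone-beam imaging.

Not emulated: projection-domain physics (real scatter is object-dependent
and not multiplicative-smooth), metal or motion artifacts, couch structures,
truncation, patient-realistic organ shapes, and inter-subject anatomical
variability (subjects differ only by seed). Passing tests therefore show
that the pipeline recovers the *kind* of deformation and intensity
distortion it models, at phantom scale — not clinical performance on
patient data.

## Degenerate inputs and tie-breaks

Constant metric samples and empty masks raise errors rather than returning
NaN; constant volumes get a widened single-bin histogram; CDF inversion
breaks ties toward the lowest intensity; label resampling is
nearest-neighbour and can only lose, never invent, label codes; points
mapping outside the moving image are excluded from metrics and filled with
−1000 HU in resampling.

## Known limitations

* No regularization term on the deformation (smoothness comes only from the
  32 mm control-grid resolution), and no diffeomorphic or
  inverse-consistency guarantee for the *estimated* transform.
* Registration accuracy along z is intrinsically poorer (2.5–3 mm slices vs
  ~0.9 mm in-plane); the residual error after recovery is dominated by the
  z component.
* Histogram matching is global: spatially varying HU errors (cupping) are
  corrected only to the extent the global intensity distribution reflects
  them; the residual after correction is mostly noise plus the uncompensated
  spatial pattern.
* The CLI's real-data path expects user-supplied ROI boxes for the
  uniformity statistics; automatic placement requires a label map, which
  only the phantom provides.
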