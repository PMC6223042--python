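"""Synthetic pelvis phantom: paired pCT / CBCT volumes with known ground truth.

Real planning-CT / cone-beam-CT pairs for prostate radiotherapy are not
shipped with this package, so every pipeline stage is exercised on a
parametric digital phantom instead: an elliptical soft-tissue body with a
subcutaneous fat layer, two femoral heads (cortical bone core with a
soft-bone rim), and a rectal gas pocket, at realistic HU levels. The phantom
provides what patient data cannot — the exact tissue label map, the exact
deformation between the two time points, and the exact artifact fields —
which turns registration and intensity-correction accuracy into measurable
quantities.

The CBCT of a pair is derived from the pCT by (1) warping it with a smooth
random B-spline deformation (the "anatomy change" between planning and
treatment), (2) resampling onto a coarser, axially shorter CBCT grid, and
(3) degrading intensities inside the body with a global HU shift, a smooth
multiplicative shading/cupping field, and additive Gaussian noise — the
hallmarks of scatter-contaminated cone-beam acquisitions. No projection
physics is simulated; the artifact model is purely image-domain.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import AIR_HU, ImageVolume, LabelVolume, RoiBox, save_rois, write_volume
from .transforms import BSplineTransform, SpatialTransform, save_transform

__all__ = [
    "PhantomSpec",
    "PhantomSpecError",
    "generate_pct",
    "make_ground_truth_warp",
    "degrade_to_cbct",
    "place_rois",
    "generate_pair",
]

# Tissue-class intervals used by the evaluation stage; phantom tissue means
# must sit inside the class their label maps to.
_CLASS_INTERVALS = {
    "air": (-np.inf, -400.0),
    "fat": (-400.0, 250.0),
    "muscle": (-400.0, 250.0),
    "soft_bone": (250.0, 600.0),
    "bone": (600.0, np.inf),
    "rectal_gas": (-np.inf, -400.0),
}


class PhantomSpecError(ValueError):
    """A PhantomSpec field violates its invariants; the message names it."""


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic pCT/CBCT pair.

    Geometry defaults give a small pelvis-like phantom; voxel sizes follow
    typical clinical protocols (pCT 0.8496 x 0.8496 x 3 mm, CBCT
    0.8789 x 0.8789 x 2.5 mm) with the CBCT axially cropped to ~40% of the
    pCT extent, mirroring the shorter cone-beam scan range.
    """

    # pCT grid
    shape: tuple[int, int, int] = (48, 160, 160)
    spacing: tuple[float, float, float] = (3.0, 0.8496, 0.8496)
    # body / organ geometry (mm)
    body_semiaxes: tuple[float, float] = (60.0, 65.0)  # (y, x)
    fat_inner_fraction: float = 0.80  # fat ring between this radius fraction and 1
    femoral_offset_mm: float = 35.0
    femoral_bone_radius_mm: float = 12.0
    femoral_rim_radius_mm: float = 16.0
    rectal_center_mm: tuple[float, float] = (30.0, 0.0)  # (y, x) offset from centre
    rectal_semiaxes_mm: tuple[float, float, float] = (18.0, 10.0, 8.0)  # (z, y, x)
    # intensities (HU)
    tissue_means: dict = dataclasses.field(
        default_factory=lambda: {
            "air": -1000.0,
            "fat": -100.0,
            "muscle": 50.0,
            "soft_bone": 400.0,
            "bone": 900.0,
            "rectal_gas": -980.0,
        }
    )
    jitter_hu: float = 8.0  # per-voxel Gaussian HU jitter inside tissues
    texture_hu: float = 25.0  # smooth anatomical texture, soft tissue only
    texture_scale_mm: float = 8.0
    # ground-truth deformation
    deformation_amplitude_mm: float = 8.0
    deformation_grid_mm: float = 48.0
    # CBCT degradation
    cbct_spacing: tuple[float, float, float] = (2.5, 0.8789, 0.8789)
    axial_crop_fraction: float = 0.4
    cbct_shift_hu: float = -60.0
    shading_amplitude: float = 0.10  # fractional cupping depth at body centre
    shading_scale_mm: float = 40.0  # correlation length of the random modulation
    noise_sigma_hu: float = 20.0
    # reproducibility
    seed: int = 0
    # ROI placement
    roi_size: int = 10
    rois_per_tissue: int = 5

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(s <= 0 for s in self.cbct_spacing):
            raise PhantomSpecError("spacing: all components must be strictly positive")
        if any(n < 8 for n in self.shape):
            raise PhantomSpecError("shape: each axis needs at least 8 voxels")
        if not (0 < self.axial_crop_fraction <= 1):
            raise PhantomSpecError("axial_crop_fraction: must be in (0, 1]")
        if self.deformation_amplitude_mm < 0:
            raise PhantomSpecError("deformation_amplitude_mm: must be non-negative")
        if self.deformation_amplitude_mm >= self.deformation_grid_mm / 2:
            raise PhantomSpecError(
                "deformation_amplitude_mm: must be below half of deformation_grid_mm "
                "to guarantee an invertible, fold-free warp"
            )
        if not (0 < self.fat_inner_fraction < 1):
            raise PhantomSpecError("fat_inner_fraction: must be in (0, 1)")
        if self.jitter_hu < 0 or self.texture_hu < 0 or self.noise_sigma_hu < 0:
            raise PhantomSpecError("jitter_hu/texture_hu/noise_sigma_hu: must be non-negative")
        for name, mean in self.tissue_means.items():
            lo, hi = _CLASS_INTERVALS[name]
            if not (lo <= mean < hi if np.isfinite(hi) else lo <= mean):
                raise PhantomSpecError(
                    f"tissue_means[{name!r}]: {mean} HU outside its tissue-class interval"
                )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent seeded generator for one named stage of the phantom."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


# stream ids for the per-stage RNGs
_STREAM_JITTER, _STREAM_TEXTURE, _STREAM_WARP, _STREAM_SHADING, _STREAM_NOISE = range(5)


def _body_radius2(spec: PhantomSpec, zz, yy, xx):
    """Squared normalized in-plane radius of the body surface at each voxel.

    The body cross-section is an ellipse whose semi-axes taper slowly along z
    (±6%), giving the anatomy a genuine 3D shape so axial displacements are
    observable in the image.
    """
    nz = spec.shape[0]
    cz = (nz - 1) / 2.0
    taper = 1.0 - 0.06 * np.cos(np.pi * (zz - cz) / max(nz - 1, 1))
    ay = spec.body_semiaxes[0] * taper
    ax = spec.body_semiaxes[1] * taper
    cy = (spec.shape[1] - 1) / 2.0 * spec.spacing[1]
    cx = (spec.shape[2] - 1) / 2.0 * spec.spacing[2]
    y_mm = yy * spec.spacing[1] - cy
    x_mm = xx * spec.spacing[2] - cx
    return (y_mm / ay) ** 2 + (x_mm / ax) ** 2


def _build_labels(spec: PhantomSpec) -> LabelVolume:
    nz, ny, nx = spec.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nx, dtype=float),
        indexing="ij",
    )
    r2 = _body_radius2(spec, zz, yy, xx)
    body = r2 <= 1.0

    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[body] = LabelVolume.MUSCLE
    fat_ring = body & (np.sqrt(r2) > spec.fat_inner_fraction)
    labels[fat_ring] = LabelVolume.FAT

    sz, sy, sx = spec.spacing
    cz_mm = (nz - 1) / 2.0 * sz
    cy_mm = (ny - 1) / 2.0 * sy
    cx_mm = (nx - 1) / 2.0 * sx
    z_mm = zz * sz - cz_mm
    y_mm = yy * sy - cy_mm
    x_mm = xx * sx - cx_mm

    # femoral heads: bone cores with soft-bone rims, elongated along z
    for side in (-1.0, 1.0):
        d2 = (
            (z_mm / 2.2) ** 2
            + y_mm**2
            + (x_mm - side * spec.femoral_offset_mm) ** 2
        )
        rim = body & (d2 <= spec.femoral_rim_radius_mm**2)
        core = body & (d2 <= spec.femoral_bone_radius_mm**2)
        labels[rim] = LabelVolume.SOFT_BONE
        labels[core] = LabelVolume.BONE

    # rectal gas pocket (posterior midline)
    az, ayg, axg = spec.rectal_semiaxes_mm
    gy, gx = spec.rectal_center_mm
    g2 = ((z_mm / az) ** 2 + ((y_mm - gy) / ayg) ** 2 + ((x_mm - gx) / axg) ** 2)
    labels[body & (g2 <= 1.0)] = LabelVolume.RECTAL_GAS

    return LabelVolume(labels, spec.spacing, (0.0, 0.0, 0.0))


def _smooth_noise(rng: np.random.Generator, shape, spacing, scale_mm: float) -> np.ndarray:
    """Zero-mean, unit-std Gaussian random field with ~scale_mm correlation."""
    white = rng.standard_normal(shape)
    sigma = [scale_mm / s for s in spacing]
    field = ndimage.gaussian_filter(white, sigma=sigma, mode="nearest")
    sd = field.std()
    return field / sd if sd > 0 else field


def _render_hu(spec: PhantomSpec, labels: LabelVolume) -> ImageVolume:
    data = np.full(spec.shape, AIR_HU)
    jitter_rng = spec.rng(_STREAM_JITTER)
    texture_rng = spec.rng(_STREAM_TEXTURE)

    for code, name in LabelVolume.NAMES.items():
        sel = labels.data == code
        if code == LabelVolume.AIR or not sel.any():
            continue
        data[sel] = spec.tissue_means[name]

    inside = labels.body_support()
    if spec.texture_hu > 0:
        soft = (labels.data == LabelVolume.FAT) | (labels.data == LabelVolume.MUSCLE)
        tex = _smooth_noise(texture_rng, spec.shape, spec.spacing, spec.texture_scale_mm)
        data[soft] += spec.texture_hu * tex[soft]
    if spec.jitter_hu > 0:
        jit = jitter_rng.standard_normal(spec.shape) * spec.jitter_hu
        data[inside] += jit[inside]
    return ImageVolume(data, spec.spacing, (0.0, 0.0, 0.0))


def place_rois(
    labels: LabelVolume,
    label_code: int,
    n: int = 5,
    size: int = 10,
    min_separation: int = 20,
    max_per_slice: int = 2,
) -> list[RoiBox]:
    """Deterministically place n axis-aligned size x size boxes inside a label.

    Greedy scan: slices are visited from the volume middle outward; on each
    slice every position whose full box lies inside the label mask is a
    candidate, taken in (row, col) order subject to a minimum in-plane
    separation from boxes already chosen on that slice. The scan order is a
    pure function of the label map, so placements are reproducible.
    """
    nz, ny, nx = labels.shape
    mask = labels.data == label_code
    tissue = LabelVolume.NAMES.get(label_code, str(label_code))
    chosen: list[RoiBox] = []

    mid = nz // 2
    slice_order = sorted(range(nz), key=lambda z: (abs(z - mid), z))
    for z in slice_order:
        if len(chosen) >= n:
            break
        sl = mask[z]
        if not sl.any():
            continue
        # integral image -> exact count of in-label pixels per candidate box
        s = np.zeros((ny + 1, nx + 1), dtype=np.int64)
        s[1:, 1:] = np.cumsum(np.cumsum(sl.astype(np.int64), axis=0), axis=1)
        win = (
            s[size:, size:] - s[:-size, size:] - s[size:, :-size] + s[:-size, :-size]
        )  # win[r, c] = count over rows [r, r+size), cols [c, c+size)
        rows, cols = np.nonzero(win == size * size)
        taken: list[tuple[int, int]] = []
        for r, c in zip(rows, cols):
            if len(chosen) >= n or len(taken) >= max_per_slice:
                break
            if all(max(abs(r - tr), abs(c - tc)) >= min_separation for tr, tc in taken):
                chosen.append(RoiBox(z, int(r), int(c), size, size, tissue))
                taken.append((int(r), int(c)))
    return chosen


def generate_pct(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume, list[RoiBox]]:
    """Render the planning-CT phantom: HU volume, label map and ROI boxes.

    Deterministic for a fixed ``spec.seed``. ROI boxes are auto-placed inside
    the fat ring and the muscle compartment (``spec.rois_per_tissue`` each).
    """
    spec.validate()
    labels = _build_labels(spec)
    vol = _render_hu(spec, labels)
    rois = place_rois(labels, LabelVolume.FAT, n=spec.rois_per_tissue, size=spec.roi_size)
    rois += place_rois(labels, LabelVolume.MUSCLE, n=spec.rois_per_tissue, size=spec.roi_size)
    return vol, labels, rois


def make_ground_truth_warp(spec: PhantomSpec) -> BSplineTransform:
    """Random smooth B-spline warp with known control-point displacements.

    Control displacements are drawn uniformly in ±amplitude per component and
    zeroed on a two-layer border band, so the warp vanishes at the volume
    boundary; since the dense field is a convex combination of control
    displacements, its magnitude never exceeds the amplitude, and amplitude
    below half the control spacing keeps the warp fold-free.
    """
    spec.validate()
    lo = np.zeros(3)
    hi = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    warp = BSplineTransform.create_for_domain(lo, hi, spec.deformation_grid_mm)
    rng = spec.rng(_STREAM_WARP)
    amp = spec.deformation_amplitude_mm
    coeffs = rng.uniform(-amp, amp, size=warp.coefficients.shape)
    for axis in range(1, 4):
        sl = [slice(None)] * 4
        sl[axis] = slice(0, 2)
        coeffs[tuple(sl)] = 0.0
        sl[axis] = slice(-2, None)
        coeffs[tuple(sl)] = 0.0
    warp.coefficients = coeffs
    return warp


def _cbct_grid(spec: PhantomSpec) -> tuple[tuple[int, int, int], tuple[float, ...], tuple[float, ...]]:
    """CBCT grid (shape, spacing, origin): coarser voxels, shorter z coverage."""
    pct_extent = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    extent = pct_extent.copy()
    extent[0] *= spec.axial_crop_fraction
    sp = np.asarray(spec.cbct_spacing)
    n = np.floor(extent / sp).astype(int) + 1
    covered = (n - 1) * sp
    origin = (pct_extent - covered) / 2.0  # centred inside the pCT volume
    return tuple(int(v) for v in n), tuple(sp), tuple(origin)


def degrade_to_cbct(
    pct: ImageVolume,
    labels: LabelVolume,
    warp: SpatialTransform,
    spec: PhantomSpec,
) -> ImageVolume:
    """Warp + resample the pCT onto the CBCT grid and corrupt its intensities.

    Inside-body voxels are transformed ``v -> v * s(x) + b + eps`` where
    ``s`` is a smooth multiplicative shading field (radial cupping modulated
    by a seeded low-frequency random field), ``b`` the global HU shift and
    ``eps`` Gaussian noise; everything outside the warped body stays at
    -1000 HU. Deterministic for fixed ``spec.seed``.
    """
    from .registration import resample  # local import to avoid a cycle

    spec.validate()
    pct.require_same_grid(labels)
    shape, spacing, origin = _cbct_grid(spec)
    reference = ImageVolume(np.zeros(shape), spacing, origin)

    warped = resample(pct, warp, reference, interpolation="linear", fill=AIR_HU)
    labels_warped = resample_labels(labels, warp, reference)
    body = labels_warped.body_support()

    data = warped.data.copy()
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=float), np.arange(ny, dtype=float), np.arange(nx, dtype=float),
        indexing="ij",
    )
    # normalized in-plane radius w.r.t. the body semi-axes
    y_mm = yy * spacing[1] + origin[1] - ((spec.shape[1] - 1) / 2.0 * spec.spacing[1])
    x_mm = xx * spacing[2] + origin[2] - ((spec.shape[2] - 1) / 2.0 * spec.spacing[2])
    rho2 = np.clip((y_mm / spec.body_semiaxes[0]) ** 2 + (x_mm / spec.body_semiaxes[1]) ** 2, 0, 1)

    if spec.shading_amplitude > 0:
        mod = _smooth_noise(spec.rng(_STREAM_SHADING), shape, spacing, spec.shading_scale_mm)
        shading = 1.0 - spec.shading_amplitude * (1.0 - rho2) * (1.0 + 0.4 * mod)
    else:
        shading = np.ones(shape)

    noise = (
        spec.rng(_STREAM_NOISE).standard_normal(shape) * spec.noise_sigma_hu
        if spec.noise_sigma_hu > 0
        else np.zeros(shape)
    )
    data[body] = data[body] * shading[body] + spec.cbct_shift_hu + noise[body]
    data[~body] = AIR_HU
    return ImageVolume(data, spacing, origin)


def resample_labels(labels: LabelVolume, warp: SpatialTransform, reference: ImageVolume) -> LabelVolume:
    """Nearest-neighbour resampling of a label map through a transform."""
    from .registration import resample

    as_img = ImageVolume(labels.data.astype(np.float64), labels.spacing, labels.origin)
    warped = resample(as_img, warp, reference, interpolation="nearest", fill=LabelVolume.AIR)
    return LabelVolume(np.rint(warped.data).astype(np.int32), reference.spacing, reference.origin)


def generate_pair(spec: PhantomSpec) -> dict:
    """Generate the complete phantom study unit for one synthetic subject.

    Returns a dict with keys ``pct``, ``labels``, ``rois`` (on the pCT grid),
    ``warp`` (ground-truth pCT->CBCT deformation ... mapping CBCT-grid points
    into the pCT), ``cbct``, ``labels_cbct`` and ``rois_cbct`` (ROIs placed on
    the warped label map, i.e. on the CBCT grid).
    """
    pct, labels, rois = generate_pct(spec)
    warp = make_ground_truth_warp(spec)
    cbct = degrade_to_cbct(pct, labels, warp, spec)
    labels_cbct = resample_labels(labels, warp, cbct)
    rois_cbct = place_rois(labels_cbct, LabelVolume.FAT, n=spec.rois_per_tissue, size=spec.roi_size)
    rois_cbct += place_rois(labels_cbct, LabelVolume.MUSCLE, n=spec.rois_per_tissue, size=spec.roi_size)
    return {
        "pct": pct,
        "labels": labels,
        "rois": rois,
        "warp": warp,
        "cbct": cbct,
        "labels_cbct": labels_cbct,
        "rois_cbct": rois_cbct,
    }


def save_pair(pair: dict, out_dir: str | Path) -> None:
    """Write a generated pair to disk (NIfTI volumes, JSON warp and ROIs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(pair["pct"], out / "pct.nii.gz")
    write_volume(pair["labels"], out / "labels.nii.gz")
    write_volume(pair["cbct"], out / "cbct.nii.gz")
    write_volume(pair["labels_cbct"], out / "labels_cbct.nii.gz")
    save_transform(pair["warp"], out / "warp.json")
    save_rois(pair["rois"], out / "rois_pct.json")
    save_rois(pair["rois_cbct"], out / "rois_cbct.json")
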