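"""Rigid and multi-resolution B-spline registration driven by ASGD.

The registration follows the classic intensity-based recipe for aligning a
planning CT (moving image) to a cone-beam CT (fixed image):

1. a rigid 6-DOF pre-alignment maximizing mutual information;
2. a 3-level multi-resolution cubic B-spline free-form deformation whose
   control-point displacements maximize NCC, MI or NMI, the control grid
   living on the fixed image and being refined (coarse to fine) per level.

Both stages are optimized with adaptive stochastic gradient descent (ASGD):
each iteration draws a fresh random subset of fixed-image voxel sites
(mask-restricted, with sub-voxel jitter), evaluates the metric and its
analytic gradient with respect to the transform parameters there, and takes
an ascent step of decaying length ``a / (A + t)^alpha``. The gain ``a`` is
auto-scaled from the first gradients so that the first step moves points by
a prescribed physical length. Parameters are averaged over the final
quarter of the iterations to damp sampling noise. Every random draw comes
from a generator seeded by the configuration, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .image import AIR_HU, ImageVolume
from .metrics import (
    DegenerateSampleError,
    SamplingDomain,
    mutual_information_value_and_moving_gradient,
    ncc_value_and_moving_gradient,
    sample_volume,
)
from .transforms import (
    BSplineTransform,
    CompositeTransform,
    IdentityTransform,
    RigidTransform,
    SpatialTransform,
)

__all__ = [
    "RegistrationConfig",
    "NoOverlapError",
    "register_rigid",
    "register_bspline",
    "resample",
]


class NoOverlapError(RuntimeError):
    """Fixed and moving domains do not overlap at initialization."""


@dataclasses.dataclass
class RegistrationConfig:
    """Hyperparameters shared by the rigid and deformable stages.

    ``metric`` selects the similarity driving the deformable stage (the
    rigid stage always uses MI). Pyramid levels are described coarsest
    first: ``downsample_factors[i]`` decimates each axis and
    ``smoothing_sigmas[i]`` is the Gaussian pre-smoothing in voxels. The
    B-spline control-grid spacing at level i is
    ``grid_spacing_mm * grid_schedule[i]``.
    """

    metric: str = "ncc"  # "ncc" | "mi" | "nmi"
    levels: int = 3
    smoothing_sigmas: tuple[float, ...] = (4.0, 2.0, 0.5)
    downsample_factors: tuple[int, ...] = (4, 2, 1)
    grid_spacing_mm: float = 32.0
    grid_schedule: tuple[float, ...] = (4.0, 2.0, 1.0)
    iterations: int = 256
    samples_per_iteration: int = 2048
    bins: int = 64
    asgd_A: float = 20.0
    asgd_alpha: float = 0.602
    initial_step_mm: float = 2.0
    # per-level multiplier on initial_step_mm (coarsest first)
    step_schedule: tuple[float, ...] = (4.0, 2.0, 1.0)
    validation_samples: int = 16384
    # a level is kept only if it beats the level-start metric by this margin
    # on the held-out sample; otherwise it is reverted (guards against
    # stochastic drift when the images are already aligned)
    guard_margin: float = 1e-3
    averaging_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.metric not in ("ncc", "mi", "nmi"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.levels < 1 or self.samples_per_iteration < 1 or self.bins < 2:
            raise ValueError("levels >= 1, samples >= 1 and bins >= 2 required")
        if (
            len(self.smoothing_sigmas) < self.levels
            or len(self.downsample_factors) < self.levels
            or len(self.step_schedule) < self.levels
            or len(self.grid_schedule) < self.levels
        ):
            raise ValueError("need a sigma, factor, step and grid entry per level")
        for v in (self.asgd_A, self.asgd_alpha, self.initial_step_mm):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("ASGD rates must be finite and positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


# -- resampling ------------------------------------------------------------

def resample(
    moving: ImageVolume,
    transform: SpatialTransform,
    reference: ImageVolume,
    interpolation: str = "linear",
    fill: float = AIR_HU,
) -> ImageVolume:
    """Pull the moving image onto the reference grid through a transform.

    Every reference voxel centre x is mapped to T(x) and the moving image is
    interpolated there (``linear`` for HU, ``nearest`` for label maps);
    points mapping outside the moving image receive ``fill``.
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    pts = reference.grid_points()
    mapped = transform.apply(pts)
    idx = moving.physical_to_indices(mapped)
    values = ndimage.map_coordinates(
        moving.data, idx.T, order=order, mode="grid-constant", cval=fill
    )
    n = np.asarray(moving.shape, dtype=float)
    outside = ~np.all((idx >= 0.0) & (idx <= n - 1.0), axis=1)
    values[outside] = fill
    return ImageVolume(values.reshape(reference.shape), reference.spacing, reference.origin)


# -- pyramid ---------------------------------------------------------------

@dataclasses.dataclass
class _Level:
    fixed: ImageVolume
    moving: ImageVolume
    moving_grad: tuple[np.ndarray, np.ndarray, np.ndarray]  # d/dz, d/dy, d/dx (HU/mm)
    mask: np.ndarray | None
    f_range: tuple[float, float]
    m_range: tuple[float, float]


def _decimate(vol: ImageVolume, sigma: float, factor: int) -> ImageVolume:
    """Gaussian-smooth and decimate one pyramid level.

    ``sigma`` is expressed in units of the smallest voxel size and converted
    per axis to physical-isotropic smoothing, so a coarse slice spacing (z is
    typically 3x the in-plane pitch) is not blurred three times harder than
    the in-plane axes.
    """
    if sigma > 0:
        sp = np.asarray(vol.spacing)
        data = ndimage.gaussian_filter(vol.data, sigma=sigma * sp.min() / sp, mode="nearest")
    else:
        data = vol.data
    data = data[::factor, ::factor, ::factor]
    spacing = tuple(s * factor for s in vol.spacing)
    return ImageVolume(data.copy(), spacing, vol.origin)


def _build_level(
    fixed: ImageVolume,
    moving: ImageVolume,
    fixed_mask: np.ndarray | None,
    sigma: float,
    factor: int,
) -> _Level:
    fx = _decimate(fixed, sigma, factor)
    mv = _decimate(moving, sigma, factor)
    mask = None
    if fixed_mask is not None:
        mask = np.asarray(fixed_mask, dtype=bool)[::factor, ::factor, ::factor]
        if not mask.any():
            mask = None
    grad = np.gradient(mv.data, *mv.spacing)
    fvals = fx.data[mask] if mask is not None else fx.data
    f_range = (float(fvals.min()), float(fvals.max()))
    m_range = (float(mv.data.min()), float(mv.data.max()))
    if f_range[1] <= f_range[0]:
        f_range = (f_range[0] - 0.5, f_range[1] + 0.5)
    if m_range[1] <= m_range[0]:
        m_range = (m_range[0] - 0.5, m_range[1] + 0.5)
    return _Level(fx, mv, tuple(grad), mask, f_range, m_range)


def _metric_and_sample_gradient(
    level: _Level, cfg: RegistrationConfig, f: np.ndarray, m: np.ndarray, metric: str
) -> tuple[float, np.ndarray]:
    if metric == "ncc":
        return ncc_value_and_moving_gradient(f, m)
    return mutual_information_value_and_moving_gradient(
        f, m, cfg.bins, level.f_range, level.m_range, normalized=(metric == "nmi")
    )


def _moving_gradient_at(level: _Level, mapped: np.ndarray) -> np.ndarray:
    idx = level.moving.physical_to_indices(mapped)
    out = np.empty((len(mapped), 3))
    for d in range(3):
        out[:, d] = ndimage.map_coordinates(
            level.moving_grad[d], idx.T, order=1, mode="grid-constant", cval=0.0
        )
    return out


class _Asgd:
    """Stochastic ascent with decaying step ``a / (A + t)^alpha``.

    The gain ``a`` is auto-scaled so the first update moves the largest
    parameter by ``step_mm`` (parameters are pre-scaled to millimetre
    units). Each update is additionally trust-bounded at the current decayed
    step length: gradient spikes cannot throw the iterate, while a vanishing
    gradient near the optimum still yields vanishing updates.
    """

    def __init__(self, cfg: RegistrationConfig, step_mm: float):
        self.A = cfg.asgd_A
        self.alpha = cfg.asgd_alpha
        self.step_mm = step_mm
        self.gain: float | None = None
        self.t = 0

    def update(self, grad: np.ndarray) -> np.ndarray:
        gmax = float(np.abs(grad).max())
        if self.gain is None:
            self.gain = self.step_mm * (self.A + 1.0) ** self.alpha / max(gmax, 1e-12)
        decay = (self.A + 1.0 + self.t) ** (-self.alpha)
        self.t += 1
        upd = (self.gain * decay) * grad
        cap = self.step_mm * (self.A + 1.0) ** self.alpha * decay
        m = float(np.abs(upd).max())
        if m > cap:
            upd *= cap / m
        return upd


def _draw(level: _Level, cfg: RegistrationConfig, rng: np.random.Generator) -> SamplingDomain:
    return SamplingDomain.random(
        level.fixed, cfg.samples_per_iteration, rng, mask=level.mask, jitter=True
    )


def _validation_metric(
    level: _Level,
    cfg: RegistrationConfig,
    dom: SamplingDomain,
    metric: str,
    mapper,
) -> float:
    """Metric value on a held-out domain (shared across one level's guard).

    Stochastic optimization can drift when the images are already aligned
    (the gradient is then pure sampling noise); each level's result is
    therefore accepted only if it does not lower the metric on this fixed
    validation sample, otherwise the level is reverted.
    """
    mapped = mapper(dom.points)
    m, inside = sample_volume(level.moving, mapped, order=1)
    if not inside.any():
        return -np.inf
    f = dom.values[inside]
    # raw Parzen MI can be inflated by degenerate intensity sharpening, so
    # MI-driven levels are judged by NMI, which normalizes that artifact out
    guard_metric = "nmi" if metric != "ncc" else "ncc"
    try:
        value, _ = _metric_and_sample_gradient(level, cfg, f, m[inside], guard_metric)
    except DegenerateSampleError:
        return -np.inf
    return value


# -- rigid stage -----------------------------------------------------------

def register_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    cfg: RegistrationConfig,
    fixed_mask: np.ndarray | None = None,
) -> RigidTransform:
    """Rigid 6-DOF pre-alignment maximizing mutual information.

    Angles are optimized in arc-length units (scaled by the mean lever arm
    of the sampled sites) so rotations and translations share one step size.
    """
    cfg.validate()
    rng = cfg.rng(stream=101)
    center = tuple(fixed.center())
    params = np.zeros(6)  # (arc_z, arc_y, arc_x, tz, ty, tx), all in mm

    for lvl_idx in range(cfg.levels):
        factor = cfg.downsample_factors[lvl_idx]
        level = _build_level(fixed, moving, fixed_mask, cfg.smoothing_sigmas[lvl_idx], factor)
        lever = _lever_arm(level, center)
        scales = np.array([lever, lever, lever, 1.0, 1.0, 1.0])
        opt = _Asgd(cfg, step_mm=cfg.initial_step_mm * cfg.step_schedule[lvl_idx])
        val_dom = SamplingDomain.random(
            level.fixed, cfg.validation_samples, cfg.rng(stream=111 + lvl_idx),
            mask=level.mask, jitter=False,
        )

        def rigid_at(p):
            return RigidTransform(tuple(p[:3] / lever), tuple(p[3:]), center)

        start_params = params.copy()
        v0 = _validation_metric(level, cfg, val_dom, "mi", rigid_at(start_params).apply)
        history = []
        n_avg = max(1, int(cfg.iterations * cfg.averaging_fraction))
        for it in range(cfg.iterations):
            dom = _draw(level, cfg, rng)
            t = RigidTransform(tuple(params[:3] / lever), tuple(params[3:]), center)
            mapped = t.apply(dom.points)
            m, inside = sample_volume(level.moving, mapped, order=1)
            if inside.sum() < max(10, 0.01 * len(dom)):
                if it == 0 and lvl_idx == 0:
                    raise NoOverlapError("no overlap between fixed and moving domains")
                continue  # pathological draw; skip
            f = dom.values[inside]
            m = m[inside]
            value, dmetric_dm = _metric_and_sample_gradient(level, cfg, f, m, "mi")
            mv_grad = _moving_gradient_at(level, mapped[inside])
            jac = t.jacobian_parameters(dom.points[inside])  # (n, 3, 6)
            per_point = dmetric_dm[:, None] * mv_grad  # (n, 3)
            grad = np.einsum("nd,ndk->k", per_point, jac) / scales
            params = params + opt.update(grad)
            if cfg.iterations - it <= n_avg:
                history.append(params.copy())
        params = np.mean(history, axis=0) if history else params
        v1 = _validation_metric(level, cfg, val_dom, "mi", rigid_at(params).apply)
        if v1 < v0 + cfg.guard_margin:  # no-harm guard: keep level-start alignment
            params = start_params

    return RigidTransform(tuple(params[:3] / lever), tuple(params[3:]), center)


def _lever_arm(level: _Level, center) -> float:
    if level.mask is not None:
        idx = np.argwhere(level.mask)
    else:
        idx = np.indices(level.fixed.shape).reshape(3, -1).T
    pts = level.fixed.indices_to_physical(idx)
    r = np.linalg.norm(pts - np.asarray(center), axis=1).mean()
    return max(float(r), 1.0)


# -- deformable stage ------------------------------------------------------

def _refit_coefficients(deform: BSplineTransform, new_grid: BSplineTransform) -> None:
    """Carry a deformation over to a finer control grid.

    The previous dense field is sampled at the new control-point locations
    and prefiltered into interpolating cubic B-spline coefficients, so the
    refined transform reproduces the coarse field up to the (small)
    approximation error of the resampling.
    """
    shape = new_grid.coefficients.shape[1:]
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    pts = idx * np.asarray(new_grid.grid_spacing) + np.asarray(new_grid.grid_origin)
    disp = deform.displacement(pts)  # (N, 3)
    for d in range(3):
        field = disp[:, d].reshape(shape)
        new_grid.coefficients[d] = ndimage.spline_filter(field, order=3, mode="nearest")


def register_bspline(
    fixed: ImageVolume,
    moving: ImageVolume,
    init: SpatialTransform | None,
    cfg: RegistrationConfig,
    fixed_mask: np.ndarray | None = None,
) -> CompositeTransform:
    """Multi-resolution B-spline free-form registration.

    ``init`` (typically the rigid stage's result) is composed into the
    returned transform: T(x) = init(x) + u(x) with the deformation grid on
    the fixed image. The grid is refined per pyramid level following
    ``cfg.grid_schedule`` and the control-point displacements maximize
    ``cfg.metric`` by ASGD with stochastic site resampling.
    """
    cfg.validate()
    base = init if init is not None else IdentityTransform()
    rng = cfg.rng(stream=202)
    lo, hi = fixed.physical_extent()

    deform: BSplineTransform | None = None
    for lvl_idx in range(cfg.levels):
        factor = cfg.downsample_factors[lvl_idx]
        level = _build_level(fixed, moving, fixed_mask, cfg.smoothing_sigmas[lvl_idx], factor)
        spacing = cfg.grid_spacing_mm * cfg.grid_schedule[lvl_idx]
        new_deform = BSplineTransform.create_for_domain(lo, hi, spacing)
        if deform is not None:
            _refit_coefficients(deform, new_deform)
        deform = new_deform
        coeffs = deform.coefficients
        gshape = coeffs.shape[1:]
        gsize = int(np.prod(gshape))

        opt = _Asgd(cfg, step_mm=cfg.initial_step_mm * cfg.step_schedule[lvl_idx])
        val_dom = SamplingDomain.random(
            level.fixed, cfg.validation_samples, cfg.rng(stream=222 + lvl_idx),
            mask=level.mask, jitter=False,
        )

        def mapper(pts, _deform=deform):
            return base.apply(pts) + _deform.displacement(pts)

        start_coeffs = coeffs.copy()
        v0 = _validation_metric(level, cfg, val_dom, cfg.metric, mapper)
        history = []
        n_avg = max(1, int(cfg.iterations * cfg.averaging_fraction))
        for it in range(cfg.iterations):
            dom = _draw(level, cfg, rng)
            i0, w, _ = deform.support(dom.points)
            disp = _displacement_from_support(coeffs, i0, w)
            mapped = base.apply(dom.points) + disp
            m, inside = sample_volume(level.moving, mapped, order=1)
            if inside.sum() < max(10, 0.01 * len(dom)):
                if it == 0 and lvl_idx == 0:
                    raise NoOverlapError("no overlap between fixed and moving domains")
                continue
            f = dom.values[inside]
            value, dmetric_dm = _metric_and_sample_gradient(level, cfg, f, m[inside], cfg.metric)
            mv_grad = _moving_gradient_at(level, mapped[inside])
            per_point = dmetric_dm[:, None] * mv_grad  # (n, 3): dMetric/dT(x)
            grad = _scatter_gradient(per_point, i0[inside], w[inside], gshape)
            coeffs += opt.update(grad).reshape(coeffs.shape)
            if cfg.iterations - it <= n_avg:
                history.append(coeffs.copy())
        if history:
            coeffs[...] = np.mean(history, axis=0)
        v1 = _validation_metric(level, cfg, val_dom, cfg.metric, mapper)
        if v1 < v0 + cfg.guard_margin:  # no-harm guard: discard a level that wandered
            coeffs[...] = start_coeffs

    assert deform is not None
    return CompositeTransform(base, deform)


def _displacement_from_support(coeffs: np.ndarray, i0: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Displacement at sample points from precomputed 4-tap weights, (N, 3)."""
    nz, ny, nx = coeffs.shape[1:]
    flat = coeffs.reshape(3, -1)
    out = np.zeros((len(i0), 3))
    for a in range(4):
        iz = i0[:, 0] - 1 + a
        wz = w[:, 0, a]
        for b in range(4):
            iy = i0[:, 1] - 1 + b
            wab = wz * w[:, 1, b]
            for c in range(4):
                ix = i0[:, 2] - 1 + c
                wt = wab * w[:, 2, c]
                lin = (iz * ny + iy) * nx + ix
                out += wt[:, None] * flat[:, lin].T
    return out


def _scatter_gradient(
    per_point: np.ndarray, i0: np.ndarray, w: np.ndarray, gshape: tuple[int, ...]
) -> np.ndarray:
    """Accumulate dMetric/d(coefficients): (3, prod(gshape)) flattened."""
    nz, ny, nx = gshape
    size = nz * ny * nx
    grad = np.zeros((3, size))
    for a in range(4):
        iz = i0[:, 0] - 1 + a
        wz = w[:, 0, a]
        for b in range(4):
            iy = i0[:, 1] - 1 + b
            wab = wz * w[:, 1, b]
            for c in range(4):
                ix = i0[:, 2] - 1 + c
                wt = wab * w[:, 2, c]
                lin = (iz * ny + iy) * nx + ix
                for d in range(3):
                    grad[d] += np.bincount(lin, weights=wt * per_point[:, d], minlength=size)
    return grad
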