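"""Spatial transforms: rigid 6-DOF and cubic B-spline free-form deformation.

All transforms map *fixed-image* physical points (mm, ``(z, y, x)`` order) to
*moving-image* physical points, the convention used throughout intensity-based
registration: to resample the moving image onto the fixed grid one evaluates
the moving image at ``T(x)`` for every fixed voxel centre ``x``.

The B-spline free-form deformation follows the standard uniform cubic
B-spline tensor-product model: a coarse control-point grid carries
displacement vectors and the dense displacement at a point is the separable
cubic B-spline interpolation of those vectors. The displacement at any point
is a convex combination of the 4x4x4 surrounding control displacements, so
the field magnitude never exceeds the largest control displacement.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SpatialTransform",
    "IdentityTransform",
    "RigidTransform",
    "BSplineTransform",
    "CompositeTransform",
    "bspline_weights",
    "bspline_weights_derivative",
    "save_transform",
    "load_transform",
]


class SpatialTransform:
    """Base class: maps (N, 3) physical points to (N, 3) physical points."""

    kind = "base"

    def apply(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


class IdentityTransform(SpatialTransform):
    kind = "identity"

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float)

    def to_dict(self) -> dict:
        return {"kind": self.kind}


def _euler_matrices(angles: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Rotation matrix and per-angle derivatives in (z, y, x) component order.

    ``angles = (az, ay, ax)`` are rotations about the physical z, y and x axes
    applied as R = Rz @ Ry @ Rx.
    """
    az, ay, ax = [float(a) for a in angles]

    def rot(c, s, axis):
        # rotation about `axis` expressed on (z, y, x) component vectors
        m = np.eye(3)
        if axis == "z":  # mixes (y, x) components
            m[1, 1], m[1, 2], m[2, 1], m[2, 2] = c, -s, s, c
        elif axis == "y":  # mixes (z, x)
            m[0, 0], m[0, 2], m[2, 0], m[2, 2] = c, s, -s, c
        else:  # x: mixes (z, y)
            m[0, 0], m[0, 1], m[1, 0], m[1, 1] = c, -s, s, c
        return m

    def drot(c, s, axis):
        m = np.zeros((3, 3))
        if axis == "z":
            m[1, 1], m[1, 2], m[2, 1], m[2, 2] = -s, -c, c, -s
        elif axis == "y":
            m[0, 0], m[0, 2], m[2, 0], m[2, 2] = -s, c, -c, -s
        else:
            m[0, 0], m[0, 1], m[1, 0], m[1, 1] = -s, -c, c, -s
        return m

    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    Rz, Ry, Rx = rot(cz, sz, "z"), rot(cy, sy, "y"), rot(cx, sx, "x")
    R = Rz @ Ry @ Rx
    dR = [
        drot(cz, sz, "z") @ Ry @ Rx,
        Rz @ drot(cy, sy, "y") @ Rx,
        Rz @ Ry @ drot(cx, sx, "x"),
    ]
    return R, dR


@dataclasses.dataclass
class RigidTransform(SpatialTransform):
    """6-DOF rigid transform: T(x) = R (x - c) + c + t.

    ``angles`` are Euler angles (rad) about the z, y, x axes, ``translation``
    in mm, both in ``(z, y, x)`` order; ``center`` is the rotation centre.
    """

    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # explicit rotation matrix overriding the Euler angles (used by inverse())
    matrix_override: np.ndarray | None = None
    kind = "rigid"

    def __post_init__(self) -> None:
        self.angles = tuple(float(a) for a in self.angles)  # type: ignore[assignment]
        self.translation = tuple(float(t) for t in self.translation)  # type: ignore[assignment]
        self.center = tuple(float(c) for c in self.center)  # type: ignore[assignment]

    def matrix(self) -> np.ndarray:
        if self.matrix_override is not None:
            return np.asarray(self.matrix_override, dtype=float)
        return _euler_matrices(np.asarray(self.angles))[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        c = np.asarray(self.center)
        out = (pts - c) @ self.matrix().T + c + np.asarray(self.translation)
        return out

    def jacobian_parameters(self, points: np.ndarray) -> np.ndarray:
        """dT/d(params) at each point; shape (N, 3, 6), params (az,ay,ax,tz,ty,tx)."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.center)
        _, dR = _euler_matrices(np.asarray(self.angles))
        n = pts.shape[0]
        jac = np.zeros((n, 3, 6))
        for k in range(3):
            jac[:, :, k] = pts @ dR[k].T
        for k in range(3):
            jac[:, k, 3 + k] = 1.0
        return jac

    def inverse(self) -> "RigidTransform":
        """Exact inverse: x = R^T (y - c - t) + c, as a rigid transform."""
        R = self.matrix()
        t = np.asarray(self.translation)
        return RigidTransform(
            angles=(0.0, 0.0, 0.0),
            translation=tuple(-(R.T @ t)),
            center=self.center,
            matrix_override=R.T,
        )

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "angles": list(self.angles),
            "translation": list(self.translation),
            "center": list(self.center),
        }
        if self.matrix_override is not None:
            d["matrix_override"] = np.asarray(self.matrix_override).tolist()
        return d


def bspline_weights(frac: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis weights for offsets (-1, 0, 1, 2).

    ``frac`` is the fractional part of the grid coordinate; returns (N, 4)
    non-negative weights summing to 1.
    """
    f = np.asarray(frac, dtype=float)
    f2, f3 = f * f, f * f * f
    w = np.empty(f.shape + (4,))
    w[..., 0] = (1 - f) ** 3 / 6.0
    w[..., 1] = (3 * f3 - 6 * f2 + 4) / 6.0
    w[..., 2] = (-3 * f3 + 3 * f2 + 3 * f + 1) / 6.0
    w[..., 3] = f3 / 6.0
    return w


def bspline_weights_derivative(frac: np.ndarray) -> np.ndarray:
    """d/dt of the four cubic B-spline weights (per unit grid coordinate)."""
    f = np.asarray(frac, dtype=float)
    f2 = f * f
    d = np.empty(f.shape + (4,))
    d[..., 0] = -((1 - f) ** 2) / 2.0
    d[..., 1] = (9 * f2 - 12 * f) / 6.0
    d[..., 2] = (-9 * f2 + 6 * f + 3) / 6.0
    d[..., 3] = f2 / 2.0
    return d


@dataclasses.dataclass
class BSplineTransform(SpatialTransform):
    """Cubic B-spline free-form deformation: T(x) = x + u(x).

    ``coefficients`` has shape (3, nz, ny, nx): per-component control-point
    displacement vectors (mm) on a regular grid with its own origin/spacing.
    A point with grid coordinate u (continuous control-point index) draws on
    control points floor(u)-1 .. floor(u)+2 per axis; valid support therefore
    requires u in [1, n-3]. Queries outside are clamped, extending the field
    constantly past the grid margin.
    """

    grid_origin: tuple[float, float, float]
    grid_spacing: tuple[float, float, float]
    coefficients: np.ndarray
    kind = "bspline"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 4 or self.coefficients.shape[0] != 3:
            raise ValueError("coefficients must have shape (3, nz, ny, nx)")
        if any(n < 4 for n in self.coefficients.shape[1:]):
            raise ValueError("control grid needs at least 4 points per axis")
        self.grid_origin = tuple(float(v) for v in self.grid_origin)  # type: ignore[assignment]
        self.grid_spacing = tuple(float(v) for v in self.grid_spacing)  # type: ignore[assignment]

    @classmethod
    def create_for_domain(
        cls,
        lo: np.ndarray,
        hi: np.ndarray,
        grid_spacing_mm: float | tuple[float, float, float],
    ) -> "BSplineTransform":
        """Zero transform whose control grid supports the physical box [lo, hi]."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        spacing = np.asarray(_triple(grid_spacing_mm), dtype=float)
        origin = lo - spacing
        n = np.ceil((hi - origin) / spacing).astype(int) + 3
        n = np.maximum(n, 4)
        coeffs = np.zeros((3, *n))
        return cls(tuple(origin), tuple(spacing), coeffs)

    def grid_coords(self, points: np.ndarray) -> np.ndarray:
        """Continuous control-grid coordinates, clamped to valid support."""
        pts = np.asarray(points, dtype=float)
        u = (pts - np.asarray(self.grid_origin)) / np.asarray(self.grid_spacing)
        n = np.asarray(self.coefficients.shape[1:], dtype=float)
        return np.clip(u, 1.0, n - 3.0)

    def support(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis base index i0 (N, 3), weights (N, 3, 4), d-weights (N, 3, 4)."""
        u = self.grid_coords(points)
        i0 = np.floor(u).astype(np.int64)
        n = np.asarray(self.coefficients.shape[1:])
        i0 = np.minimum(i0, n - 3)  # u == n-3 exactly still needs i0+2 <= n-1
        f = u - i0
        return i0, bspline_weights(f), bspline_weights_derivative(f)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Dense displacement u(x) at (N, 3) physical points, in mm."""
        u = self.grid_coords(points)
        out = np.empty((u.shape[0], 3))
        coords = u.T.copy()
        for d in range(3):
            out[:, d] = ndimage.map_coordinates(
                self.coefficients[d], coords, order=3, prefilter=False, mode="nearest"
            )
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.displacement(points)

    def max_coefficient(self) -> float:
        return float(np.abs(self.coefficients).max())

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "grid_origin": list(self.grid_origin),
            "grid_spacing": list(self.grid_spacing),
            "grid_shape": list(self.coefficients.shape[1:]),
            "coefficients": self.coefficients.reshape(3, -1).T.tolist(),
        }


@dataclasses.dataclass
class CompositeTransform(SpatialTransform):
    """Rigid pre-alignment plus a B-spline deformation on the fixed domain.

    ``T(x) = base(x) + deform.displacement(x)`` — the deformation field is
    parameterized on the fixed image (where its control grid lives) and adds
    to the rigidly mapped point.
    """

    base: SpatialTransform
    deform: BSplineTransform
    kind = "composite"

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.base.apply(points) + self.deform.displacement(points)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "base": self.base.to_dict(), "deform": self.deform.to_dict()}


def _triple(v) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    return tuple(arr)  # type: ignore[return-value]


# -- serialization ---------------------------------------------------------

def save_transform(t: SpatialTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps(t.to_dict()))


def transform_from_dict(d: dict) -> SpatialTransform:
    kind = d["kind"]
    if kind == "identity":
        return IdentityTransform()
    if kind == "rigid":
        ovr = d.get("matrix_override")
        return RigidTransform(
            tuple(d["angles"]),
            tuple(d["translation"]),
            tuple(d["center"]),
            matrix_override=None if ovr is None else np.asarray(ovr, dtype=float),
        )
    if kind == "bspline":
        shape = tuple(d["grid_shape"])
        coeffs = np.asarray(d["coefficients"], dtype=float).T.reshape(3, *shape)
        return BSplineTransform(tuple(d["grid_origin"]), tuple(d["grid_spacing"]), coeffs)
    if kind == "composite":
        base = transform_from_dict(d["base"])
        deform = transform_from_dict(d["deform"])
        assert isinstance(deform, BSplineTransform)
        return CompositeTransform(base, deform)
    raise ValueError(f"unknown transform kind {kind!r}")


def load_transform(path: str | Path) -> SpatialTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))
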