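"""Intensity similarity metrics: NCC, MI and NMI, with analytic gradients.

All three metrics compare fixed-image values ``I_F(x_i)`` with moving-image
values ``I_M(T(x_i))`` over a sampling domain of fixed-image sites:

* NCC — the Pearson correlation of the two value samples,
  ``sum((f - fbar)(m - mbar)) / sqrt(sum((f - fbar)^2) sum((m - mbar)^2))``.
* MI — ``H(I_F) + H(I_M) - H(I_F, I_M)`` with entropies (in nats) taken from
  a joint intensity histogram.
* NMI — ``(H(I_F) + H(I_M)) / H(I_F, I_M)``, algebraically
  ``1 + MI / H(I_F, I_M)``.

For optimization the joint histogram is Parzen-windowed with cubic B-spline
kernels on both intensity axes, which makes MI/NMI differentiable in the
moving-image values; the per-sample derivatives implemented here are the
standard ones obtained by differentiating the entropies through the kernel
(the normalization terms vanish because the kernel-derivative weights sum
to zero). A ``nearest`` kernel (hard binning) is also available and is what
the brute-force oracles in the test-suite use.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .image import ImageVolume
from .transforms import SpatialTransform, bspline_weights, bspline_weights_derivative

__all__ = [
    "DegenerateSampleError",
    "SamplingDomain",
    "JointHistogram",
    "metric_ncc",
    "build_joint_histogram",
    "metric_mi",
    "metric_nmi",
    "sample_volume",
]


class DegenerateSampleError(ValueError):
    """The sample admits no metric value (constant values / empty overlap)."""


def sample_volume(
    vol: ImageVolume, points: np.ndarray, order: int = 1, fill: float = -1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate a volume at physical points.

    Returns ``(values, inside)`` where ``inside`` flags points whose index
    coordinates lie within the voxel-centre bounding box of the volume;
    outside points receive ``fill``.
    """
    idx = vol.physical_to_indices(points)
    n = np.asarray(vol.shape, dtype=float)
    inside = np.all((idx >= 0.0) & (idx <= n - 1.0), axis=1)
    values = ndimage.map_coordinates(
        vol.data, idx.T, order=order, mode="grid-constant", cval=fill
    )
    return values, inside


@dataclasses.dataclass
class SamplingDomain:
    """Fixed-image sites over which a metric is evaluated.

    ``points`` are physical coordinates (mm, zyx); ``values`` are the fixed
    image interpolated there once at construction, so repeated metric
    evaluations against different transforms reuse them.
    """

    points: np.ndarray
    values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.points) != len(self.values):
            raise ValueError("points/values length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def full_grid(cls, fixed: ImageVolume, mask: np.ndarray | None = None) -> "SamplingDomain":
        """Every voxel centre of the fixed image (optionally mask-restricted)."""
        pts = fixed.grid_points()
        vals = fixed.data.reshape(-1)
        if mask is not None:
            sel = np.asarray(mask, dtype=bool).reshape(-1)
            pts, vals = pts[sel], vals[sel]
        if len(pts) == 0:
            raise DegenerateSampleError("empty sampling domain")
        return cls(pts, vals)

    @classmethod
    def random(
        cls,
        fixed: ImageVolume,
        count: int,
        rng: np.random.Generator,
        mask: np.ndarray | None = None,
        jitter: bool = True,
    ) -> "SamplingDomain":
        """Uniform random voxel sites (with sub-voxel jitter) inside the mask."""
        if mask is None:
            flat = np.arange(int(np.prod(fixed.shape)))
        else:
            flat = np.flatnonzero(np.asarray(mask, dtype=bool).reshape(-1))
        if flat.size == 0:
            raise DegenerateSampleError("empty sampling domain")
        pick = rng.choice(flat, size=int(count), replace=flat.size < count)
        idx = np.stack(np.unravel_index(pick, fixed.shape), axis=1).astype(float)
        if jitter:
            idx = idx + rng.uniform(-0.5, 0.5, size=idx.shape)
            idx = np.clip(idx, 0.0, np.asarray(fixed.shape, dtype=float) - 1.0)
        pts = fixed.indices_to_physical(idx)
        vals = ndimage.map_coordinates(fixed.data, idx.T, order=1, mode="nearest")
        return cls(pts, vals)


def _paired_samples(
    fixed: ImageVolume,
    moving: ImageVolume,
    transform: SpatialTransform,
    dom: SamplingDomain,
) -> tuple[np.ndarray, np.ndarray]:
    mapped = transform.apply(dom.points)
    m, inside = sample_volume(moving, mapped, order=1)
    if not inside.any():
        raise DegenerateSampleError("no sampled point maps inside the moving image")
    return dom.values[inside], m[inside]


# -- NCC -------------------------------------------------------------------

def _ncc_from_values(f: np.ndarray, m: np.ndarray) -> float:
    fd = f - f.mean()
    md = m - m.mean()
    bb = float(fd @ fd)
    cc = float(md @ md)
    if bb <= 0.0 or cc <= 0.0:
        raise DegenerateSampleError("degenerate sample: zero intensity variance")
    return float((fd @ md) / np.sqrt(bb * cc))


def metric_ncc(
    fixed: ImageVolume,
    moving: ImageVolume,
    transform: SpatialTransform,
    dom: SamplingDomain,
) -> float:
    """Normalized correlation coefficient over the sampling domain, in [-1, 1]."""
    f, m = _paired_samples(fixed, moving, transform, dom)
    if len(f) < 2:
        raise DegenerateSampleError("need at least 2 overlapping samples")
    return _ncc_from_values(f, m)


def ncc_value_and_moving_gradient(f: np.ndarray, m: np.ndarray) -> tuple[float, np.ndarray]:
    """NCC and its derivative w.r.t. each moving-image sample value."""
    fd = f - f.mean()
    md = m - m.mean()
    bb = float(fd @ fd)
    cc = float(md @ md)
    if bb <= 0.0 or cc <= 0.0:
        raise DegenerateSampleError("degenerate sample: zero intensity variance")
    aa = float(fd @ md)
    root = np.sqrt(bb * cc)
    value = aa / root
    grad = fd / root - (aa / (np.sqrt(bb) * cc**1.5)) * md
    return float(value), grad


# -- joint histogram / MI / NMI -------------------------------------------

def _intensity_coords(values: np.ndarray, lo: float, hi: float, bins: int):
    """Continuous bin coordinate t (bin centres at integers), clamped so the
    4-tap cubic kernel support stays inside [0, bins-1]."""
    width = (hi - lo) / bins
    t = (np.clip(values, lo, hi) - lo) / width - 0.5
    t = np.clip(t, 1.0, float(bins - 2))
    i0 = np.minimum(np.floor(t).astype(np.int64), bins - 3)
    frac = t - i0
    return i0, frac, width


@dataclasses.dataclass
class JointHistogram:
    """Normalized joint intensity distribution of a fixed/moving sample pair."""

    p: np.ndarray  # (bins_f, bins_m), sums to 1
    f_edges: np.ndarray
    m_edges: np.ndarray
    kernel: str = "bspline3"
    n_samples: int = 0

    def marginal_fixed(self) -> np.ndarray:
        return self.p.sum(axis=1)

    def marginal_moving(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @staticmethod
    def _entropy(p: np.ndarray) -> float:
        q = p[p > 0]
        return float(-(q * np.log(q)).sum())

    def entropy_fixed(self) -> float:
        return self._entropy(self.marginal_fixed())

    def entropy_moving(self) -> float:
        return self._entropy(self.marginal_moving())

    def entropy_joint(self) -> float:
        return self._entropy(self.p.ravel())


def _joint_probability(
    f: np.ndarray, m: np.ndarray, bins: int, f_range, m_range, kernel: str
) -> np.ndarray:
    n = len(f)
    if kernel == "nearest":
        wf = np.clip(((f - f_range[0]) / (f_range[1] - f_range[0]) * bins).astype(int), 0, bins - 1)
        wm = np.clip(((m - m_range[0]) / (m_range[1] - m_range[0]) * bins).astype(int), 0, bins - 1)
        counts = np.bincount(wf * bins + wm, minlength=bins * bins).astype(float)
        return counts.reshape(bins, bins) / n
    i0f, ff, _ = _intensity_coords(f, *f_range, bins)
    i0m, fm, _ = _intensity_coords(m, *m_range, bins)
    wf = bspline_weights(ff)
    wm = bspline_weights(fm)
    acc = np.zeros(bins * bins)
    for a in range(4):
        rows = i0f - 1 + a
        for b in range(4):
            cols = i0m - 1 + b
            acc += np.bincount(
                rows * bins + cols, weights=wf[:, a] * wm[:, b], minlength=bins * bins
            )
    return acc.reshape(bins, bins) / n


def _ranges(values: np.ndarray) -> tuple[float, float]:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:  # constant image: widen so a single bin catches everything
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def build_joint_histogram(
    fixed: ImageVolume,
    moving: ImageVolume,
    transform: SpatialTransform,
    dom: SamplingDomain,
    bins: int = 32,
    kernel: str = "bspline3",
    f_range: tuple[float, float] | None = None,
    m_range: tuple[float, float] | None = None,
) -> JointHistogram:
    """Parzen-windowed (or hard-binned) joint histogram over the domain.

    Bin ranges default to the min/max of each value sample; equal-width bins.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    f, m = _paired_samples(fixed, moving, transform, dom)
    f_range = f_range or _ranges(f)
    m_range = m_range or _ranges(m)
    p = _joint_probability(f, m, bins, f_range, m_range, kernel)
    return JointHistogram(
        p=p,
        f_edges=np.linspace(*f_range, bins + 1),
        m_edges=np.linspace(*m_range, bins + 1),
        kernel=kernel,
        n_samples=len(f),
    )


def metric_mi(h: JointHistogram) -> float:
    """Mutual information H(F) + H(M) - H(F, M), in nats."""
    return h.entropy_fixed() + h.entropy_moving() - h.entropy_joint()


def metric_nmi(h: JointHistogram) -> float:
    """Normalized mutual information (H(F) + H(M)) / H(F, M)."""
    hj = h.entropy_joint()
    if hj <= 1e-12:
        raise DegenerateSampleError("degenerate sample: zero joint entropy")
    return (h.entropy_fixed() + h.entropy_moving()) / hj


def mutual_information_value_and_moving_gradient(
    f: np.ndarray,
    m: np.ndarray,
    bins: int,
    f_range: tuple[float, float],
    m_range: tuple[float, float],
    normalized: bool = False,
) -> tuple[float, np.ndarray]:
    """MI (or NMI) of a value sample pair and d(metric)/d(moving values).

    Uses cubic-B-spline Parzen windows on both intensity axes. The gradient
    follows from differentiating the entropies through the moving kernel;
    terms proportional to ``sum_b dkernel/dt`` drop out because those weight
    derivatives sum to zero.
    """
    n = len(f)
    i0f, ff, _ = _intensity_coords(f, *f_range, bins)
    i0m, fm, width_m = _intensity_coords(m, *m_range, bins)
    wf = bspline_weights(ff)
    wm = bspline_weights(fm)
    dwm = bspline_weights_derivative(fm)

    acc = np.zeros(bins * bins)
    for a in range(4):
        rows = i0f - 1 + a
        for b in range(4):
            cols = i0m - 1 + b
            acc += np.bincount(rows * bins + cols, weights=wf[:, a] * wm[:, b], minlength=bins * bins)
    p = acc.reshape(bins, bins) / n
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)

    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        logpm = np.where(pm > 0, np.log(np.where(pm > 0, pm, 1.0)), 0.0)
    hf = JointHistogram._entropy(pf)
    hm = JointHistogram._entropy(pm)
    hj = JointHistogram._entropy(p.ravel())
    mi = hf + hm - hj

    logp_flat = logp.ravel()
    # d(-HJ)/dm_i and dHM/dm_i assembled per sample from the 4x4 kernel support
    g_joint = np.zeros(n)  # sum_ab wf * dwm * log p(a, b)
    g_marg = np.zeros(n)  # sum_b dwm * log pm(b)
    for b in range(4):
        cols = i0m - 1 + b
        g_marg += dwm[:, b] * logpm[cols]
        for a in range(4):
            rows = i0f - 1 + a
            g_joint += wf[:, a] * dwm[:, b] * logp_flat[rows * bins + cols]
    scale = 1.0 / (n * width_m)
    if not normalized:
        value = mi
        grad = scale * (g_joint - g_marg)
    else:
        if hj <= 1e-12:
            raise DegenerateSampleError("degenerate sample: zero joint entropy")
        value = (hf + hm) / hj
        d_hm = -scale * g_marg
        d_hj = -scale * g_joint
        grad = (d_hm * hj - (hf + hm) * d_hj) / (hj * hj)
    # clamped samples sit on the histogram edge; give them no gradient
    clamped = (m <= m_range[0]) | (m >= m_range[1])
    grad[clamped] = 0.0
    return float(value), grad
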