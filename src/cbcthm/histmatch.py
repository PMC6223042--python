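"""Cumulative-histogram matching of CBCT intensities to a reference CT.

After registration has put the planning CT onto the CBCT grid, the CBCT's
HU distribution is corrected by monotone remapping: each CBCT value is
replaced by the reference (deformed pCT) value with the same cumulative
probability. Histograms are restricted to the body mask — the -1000 HU air
background would otherwise dominate both CDFs and flatten the map — and the
mapping is realized as a piecewise-linear lookup table over equal-width
bins, inverted at the lowest reference level reaching each cumulative value.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .image import ImageVolume
from .preprocess import BodyMask

__all__ = [
    "CumulativeHistogram",
    "IntensityMapping",
    "build_cdf",
    "compute_matching_lut",
    "apply_mapping",
    "match_histograms",
]

DEFAULT_BINS = 1024


@dataclasses.dataclass
class CumulativeHistogram:
    """Equal-width histogram with its normalized CDF over masked voxels."""

    edges: np.ndarray  # bins + 1 edges, HU
    counts: np.ndarray  # per-bin voxel counts
    cdf: np.ndarray  # bins values in (0, 1], non-decreasing, ends at 1
    mask_voxels: int = 0

    @property
    def bins(self) -> int:
        return len(self.counts)


def build_cdf(vol: ImageVolume, mask: BodyMask, bins: int = DEFAULT_BINS) -> CumulativeHistogram:
    """Histogram + CDF of the masked intensities with equal-width bins."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    mask.require_same_grid(vol)
    values = vol.data[mask.data]
    if values.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:  # constant volume: unit step
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    cdf = np.cumsum(counts) / values.size
    return CumulativeHistogram(edges=edges, counts=counts, cdf=cdf, mask_voxels=int(values.size))


@dataclasses.dataclass
class IntensityMapping:
    """Monotone piecewise-linear HU -> HU lookup table.

    Inputs outside the knot range clamp to the nearest endpoint.
    """

    input_hu: np.ndarray
    output_hu: np.ndarray

    def __post_init__(self) -> None:
        self.input_hu = np.asarray(self.input_hu, dtype=float)
        self.output_hu = np.asarray(self.output_hu, dtype=float)
        if self.input_hu.shape != self.output_hu.shape or self.input_hu.ndim != 1:
            raise ValueError("input/output knot arrays must be 1D and equal length")
        if np.any(np.diff(self.input_hu) <= 0):
            raise ValueError("input knots must be strictly increasing")
        if np.any(np.diff(self.output_hu) < -1e-9):
            raise ValueError("mapping must be non-decreasing")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return np.interp(values, self.input_hu, self.output_hu)

    @classmethod
    def identity(cls, lo: float, hi: float) -> "IntensityMapping":
        return cls(np.array([lo, hi]), np.array([lo, hi]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"input_hu": self.input_hu.tolist(), "output_hu": self.output_hu.tolist()})
        )

    @classmethod
    def load(cls, path: str | Path) -> "IntensityMapping":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["input_hu"]), np.asarray(d["output_hu"]))


def _cdf_inverse(hist: CumulativeHistogram, q: np.ndarray) -> np.ndarray:
    """Smallest intensity whose CDF reaches q, linear between bin edges.

    The CDF is treated as piecewise-linear from (edge[0], 0) through
    (edge[i+1], cdf[i]); inversion interpolates on that polyline.
    """
    levels = np.concatenate(([0.0], hist.cdf))
    edges = hist.edges
    # keep only the first edge of each CDF plateau so that a query landing
    # exactly on a plateau inverts to the *lowest* intensity reaching it
    keep = np.concatenate(([True], np.diff(levels) > 0))
    return np.interp(np.clip(q, 0.0, 1.0), levels[keep], edges[keep])


def compute_matching_lut(
    source: CumulativeHistogram, reference: CumulativeHistogram
) -> IntensityMapping:
    """LUT sending each source level to the reference level of equal CDF."""
    src_levels = source.edges[1:]
    q = source.cdf
    out = _cdf_inverse(reference, q)
    inputs = np.concatenate(([source.edges[0]], src_levels))
    outputs = np.concatenate(([reference.edges[0]], out))
    outputs = np.maximum.accumulate(outputs)  # enforce monotonicity at plateaus
    # collapse duplicate input knots (cannot occur with equal-width bins, but
    # keep the construction safe for degenerate histograms)
    keep = np.concatenate(([True], np.diff(inputs) > 0))
    return IntensityMapping(inputs[keep], outputs[keep])


def apply_mapping(vol: ImageVolume, mapping: IntensityMapping, mask: BodyMask) -> ImageVolume:
    """Remap masked voxels through the LUT; outside-mask voxels unchanged."""
    mask.require_same_grid(vol)
    data = vol.data.copy()
    data[mask.data] = mapping(data[mask.data])
    return vol.copy(data=data)


def match_histograms(
    vol: ImageVolume,
    reference: ImageVolume,
    mask: BodyMask,
    reference_mask: BodyMask | None = None,
    bins: int = DEFAULT_BINS,
) -> tuple[ImageVolume, IntensityMapping]:
    """One-call correction: build both CDFs, derive the LUT, apply it."""
    ref_mask = reference_mask if reference_mask is not None else mask
    src = build_cdf(vol, mask, bins=bins)
    ref = build_cdf(reference, ref_mask, bins=bins)
    lut = compute_matching_lut(src, ref)
    return apply_mapping(vol, lut, mask), lut
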