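"""Body-mask extraction and background standardization.

Clinical pCT and CBCT exports carry couches and other non-patient content.
Here that clean-up is automatic: threshold the volume (default -700 HU for
pCT, -600 HU for CBCT), morphologically close the result, keep the largest
3D connected component (which discards couch fragments smaller than the
patient), fill interior holes so internal gas stays inside the body, and
set every exterior voxel to the standard air value of -1000 HU.

Note the shipped mask is the *hole-filled* one: voxels of internal gas are
inside the mask even though their HU is below the threshold used to build
its surface.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .image import AIR_HU, ImageVolume

__all__ = [
    "BodyMask",
    "NoBodyFoundError",
    "PCT_THRESHOLD_HU",
    "CBCT_THRESHOLD_HU",
    "extract_body_mask",
    "apply_background_fill",
    "preprocess_volume",
]

PCT_THRESHOLD_HU = -700.0
CBCT_THRESHOLD_HU = -600.0


class NoBodyFoundError(RuntimeError):
    """Thresholding left no foreground voxels to build a body mask from."""


@dataclasses.dataclass
class BodyMask:
    """Boolean body support on the grid of its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())

    same_grid = ImageVolume.same_grid
    require_same_grid = ImageVolume.require_same_grid

    @classmethod
    def from_array(cls, data: np.ndarray, like: ImageVolume) -> "BodyMask":
        return cls(data, like.spacing, like.origin)


def extract_body_mask(
    vol: ImageVolume,
    threshold: float = PCT_THRESHOLD_HU,
    closing_radius: int = 2,
) -> BodyMask:
    """Segment the body: threshold, close, largest component, fill holes.

    Parameters
    ----------
    vol : ImageVolume
        Volume in HU.
    threshold : float
        Voxels >= threshold seed the mask (-700 for pCT, -600 for CBCT).
    closing_radius : int
        Radius (voxels) of the morphological closing ball; 0 disables it.

    Raises
    ------
    NoBodyFoundError
        If no voxel reaches the threshold.
    """
    fg = vol.data >= threshold
    if not fg.any():
        raise NoBodyFoundError(f"no body found: no voxel >= {threshold} HU")
    if closing_radius > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        # edge-pad so closing does not erode anatomy touching the volume
        # boundary (the body usually spans the full axial extent)
        r = closing_radius
        padded = np.pad(fg, r, mode="edge")
        padded = ndimage.binary_closing(padded, structure=structure, iterations=r)
        fg = padded[r:-r, r:-r, r:-r]
        if not fg.any():  # pathological but possible on tiny inputs
            fg = vol.data >= threshold
    labeled, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
        fg = labeled == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return BodyMask.from_array(fg, vol)


def apply_background_fill(
    vol: ImageVolume, mask: BodyMask, fill: float = AIR_HU
) -> ImageVolume:
    """Return the volume with every outside-mask voxel set to ``fill``."""
    mask.require_same_grid(vol)
    data = vol.data.copy()
    data[~mask.data] = fill
    return vol.copy(data=data)


def preprocess_volume(
    vol: ImageVolume,
    threshold: float = PCT_THRESHOLD_HU,
    closing_radius: int = 2,
    fill: float = AIR_HU,
) -> tuple[ImageVolume, BodyMask]:
    """Full preprocessing: body mask + exterior fill. Idempotent."""
    mask = extract_body_mask(vol, threshold=threshold, closing_radius=closing_radius)
    return apply_background_fill(vol, mask, fill=fill), mask
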