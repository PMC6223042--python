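"""Volumetric image containers and file I/O.

The package works on 3D scalar grids of Hounsfield Units (HU). Arrays are
indexed ``(z, y, x)`` with 0-based indices; geometry is carried as a per-axis
voxel ``spacing`` and the physical ``origin`` of voxel ``(0, 0, 0)``, both in
millimetres, so the physical coordinate of index ``(i, j, k)`` is
``origin + index * spacing``. No rotation is stored on the image itself:
orientation differences between volumes are the business of spatial
transforms.

File I/O (NIfTI ``.nii``/``.nii.gz`` and MetaImage ``.mha``/``.mhd``) goes
through SimpleITK; note SimpleITK orders spacing/origin ``(x, y, z)`` while
this package orders them ``(z, y, x)``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "RoiBox",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "save_rois",
    "load_rois",
]

# HU of standard air; the canonical background fill value.
AIR_HU = -1000.0


class GridMismatchError(ValueError):
    """Two volumes that must share a grid (shape/spacing/origin) do not."""


def _as_triple(value) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(np.asarray(value, dtype=float)))
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar image in HU on a regular ``(z, y, x)`` grid.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values in HU, stored as float64.
    spacing : tuple of float
        Voxel size ``(sz, sy, sx)`` in mm; strictly positive.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "ImageVolume | LabelVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    # -- geometry ---------------------------------------------------------
    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (lower corner, upper corner) of voxel centres."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of every voxel centre, shape (N, 3), zyx order."""
        idx = np.indices(self.shape, dtype=np.float64).reshape(3, -1).T
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def indices_to_physical(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def physical_to_indices(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def center(self) -> np.ndarray:
        lo, hi = self.physical_extent()
        return (lo + hi) / 2.0

    def copy(self, data: np.ndarray | None = None) -> "ImageVolume":
        return ImageVolume(
            self.data.copy() if data is None else np.asarray(data, dtype=np.float64),
            self.spacing,
            self.origin,
        )

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.data)
        img.SetSpacing(tuple(self.spacing[::-1]))
        img.SetOrigin(tuple(self.origin[::-1]))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        data = sitk.GetArrayFromImage(img).astype(np.float64)
        return cls(data, tuple(img.GetSpacing())[::-1], tuple(img.GetOrigin())[::-1])


@dataclasses.dataclass
class LabelVolume:
    """Integer tissue-label map sharing grid metadata with its ImageVolume.

    Codes: 0 air, 1 fat, 2 muscle, 3 soft bone, 4 bone, 5 rectal gas.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    AIR, FAT, MUSCLE, SOFT_BONE, BONE, RECTAL_GAS = 0, 1, 2, 3, 4, 5
    NAMES = {0: "air", 1: "fat", 2: "muscle", 3: "soft_bone", 4: "bone", 5: "rectal_gas"}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        if self.data.ndim != 3:
            raise ValueError("label data must be 3D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def body_support(self) -> np.ndarray:
        """Boolean array of voxels inside the body (any non-air label)."""
        return self.data != self.AIR

    same_grid = ImageVolume.same_grid
    require_same_grid = ImageVolume.require_same_grid


@dataclasses.dataclass(frozen=True)
class RoiBox:
    """An axial, in-plane 10x10 (by default) region of interest.

    ``slice_index`` selects the z slice; ``row``/``col`` are the (y, x)
    indices of the upper-left corner; the box is half-open:
    rows ``[row, row + height)``, columns ``[col, col + width)``.
    """

    slice_index: int
    row: int
    col: int
    height: int = 10
    width: int = 10
    tissue: str = ""

    def extract(self, vol: ImageVolume) -> np.ndarray:
        nz, ny, nx = vol.shape
        if not (
            0 <= self.slice_index < nz
            and 0 <= self.row
            and self.row + self.height <= ny
            and 0 <= self.col
            and self.col + self.width <= nx
        ):
            raise IndexError(f"ROI {self} outside volume of shape {vol.shape}")
        return vol.data[
            self.slice_index,
            self.row : self.row + self.height,
            self.col : self.col + self.width,
        ]


# -- file I/O --------------------------------------------------------------

def write_volume(vol: ImageVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    if isinstance(vol, LabelVolume):
        img = sitk.GetImageFromArray(vol.data.astype(np.int16))
        img.SetSpacing(tuple(vol.spacing[::-1]))
        img.SetOrigin(tuple(vol.origin[::-1]))
    else:
        img = vol.to_sitk()
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    return ImageVolume.from_sitk(sitk.ReadImage(str(path)))


def read_label_volume(path: str | Path) -> LabelVolume:
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)
    return LabelVolume(
        np.rint(data).astype(np.int32),
        tuple(img.GetSpacing())[::-1],
        tuple(img.GetOrigin())[::-1],
    )


def save_rois(rois: list[RoiBox], path: str | Path) -> None:
    payload = [dataclasses.asdict(r) for r in rois]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rois(path: str | Path) -> list[RoiBox]:
    payload = json.loads(Path(path).read_text())
    return [RoiBox(**entry) for entry in payload]
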