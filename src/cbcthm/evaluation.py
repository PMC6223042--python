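"""Quantitative assessment of corrected CBCT volumes against a reference CT.

Three complementary measures, all computed over a shared masked domain with
the deformed planning CT as reference:

* volume error ``V_err`` — the root-mean-square HU difference over the
  masked volume;
* binned MAE — mean absolute HU error in 20-HU-wide bins of the *reference*
  HU value, each bin annotated with its tissue class (air < -400 HU <= soft
  tissue < 250 HU <= soft bone <= 600 HU < bone), which localizes errors by
  tissue type;
* spatial-uniformity RMSD — the root-mean-square difference between mean
  values of small (10x10 pixel) same-tissue ROIs in the reference and the
  test volume.

Bin edges are anchored at odd multiples of 10 HU so bin centres fall on
multiples of 20 (bins [-10, 10), [10, 30), ...), matching the convention of
counting voxels with reference HU in [c - 10, c + 10) toward the bin
centred at c.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .image import ImageVolume, RoiBox
from .preprocess import BodyMask

__all__ = [
    "TissueClass",
    "MaeBinTable",
    "EvaluationReport",
    "abs_difference",
    "volume_error",
    "classify_tissue",
    "mae_by_bin",
    "roi_mean",
    "uniformity_rmsd",
    "build_report",
]

AIR_BOUNDARY_HU = -400.0
SOFT_BONE_LOWER_HU = 250.0
BONE_BOUNDARY_HU = 600.0


class TissueClass:
    AIR = "air"
    SOFT_TISSUE = "soft tissue"
    SOFT_BONE = "soft bone"
    BONE = "bone"


def classify_tissue(hu: float) -> str:
    """Tissue class of a HU value: air < -400 <= soft < 250 <= soft bone <= 600 < bone."""
    if not np.isfinite(hu):
        raise ValueError("HU must be finite")
    if hu < AIR_BOUNDARY_HU:
        return TissueClass.AIR
    if hu < SOFT_BONE_LOWER_HU:
        return TissueClass.SOFT_TISSUE
    if hu <= BONE_BOUNDARY_HU:
        return TissueClass.SOFT_BONE
    return TissueClass.BONE


def abs_difference(ref: ImageVolume, test: ImageVolume) -> ImageVolume:
    """Voxelwise absolute HU difference |ref - test| on the shared grid."""
    ref.require_same_grid(test)
    return ref.copy(data=np.abs(ref.data - test.data))


def volume_error(ref: ImageVolume, test: ImageVolume, mask: BodyMask) -> float:
    """Root-mean-square HU difference over the masked volume (V_err)."""
    ref.require_same_grid(test)
    mask.require_same_grid(ref)
    if not mask.data.any():
        raise ValueError("empty mask")
    diff = ref.data[mask.data] - test.data[mask.data]
    return float(np.sqrt(np.mean(diff * diff)))


@dataclasses.dataclass
class MaeBinTable:
    """Per-bin mean absolute error, binned by reference HU.

    ``mae`` is NaN for bins with no voxels (undefined, never zero).
    """

    bin_centers: np.ndarray
    mae: np.ndarray
    n: np.ndarray
    tissue_class: list[str]
    bin_width: float = 20.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mae": self.mae,
                "n": self.n,
                "class": self.tissue_class,
            }
        )

    def overall_mae(self) -> float:
        occupied = self.n > 0
        return float((self.mae[occupied] * self.n[occupied]).sum() / self.n[occupied].sum())

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def mae_by_bin(
    ref: ImageVolume, test: ImageVolume, mask: BodyMask, bin_width: float = 20.0
) -> MaeBinTable:
    """Mean absolute HU error per reference-HU bin over the masked domain.

    Voxels are assigned to bins by their *reference* value; bin centres sit
    at multiples of ``bin_width`` (half-open bins [c - w/2, c + w/2)).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ref.require_same_grid(test)
    mask.require_same_grid(ref)
    if not mask.data.any():
        raise ValueError("empty mask")
    r = ref.data[mask.data]
    t = test.data[mask.data]
    err = np.abs(r - t)
    bin_idx = np.floor((r + bin_width / 2.0) / bin_width).astype(np.int64)
    lo, hi = int(bin_idx.min()), int(bin_idx.max())
    shifted = bin_idx - lo
    nbins = hi - lo + 1
    counts = np.bincount(shifted, minlength=nbins)
    sums = np.bincount(shifted, weights=err, minlength=nbins)
    with np.errstate(invalid="ignore"):
        mae = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(lo, hi + 1)) * bin_width
    classes = [classify_tissue(c) for c in centers]
    return MaeBinTable(centers.astype(float), mae, counts, classes, bin_width)


def roi_mean(vol: ImageVolume, roi: RoiBox) -> float:
    """Mean HU of the ROI's in-plane pixels on its slice."""
    return float(roi.extract(vol).mean())


def uniformity_rmsd(ref_means: list[float], test_means: list[float]) -> float:
    """Root-mean-square difference between paired lists of ROI means."""
    a = np.asarray(ref_means, dtype=float)
    b = np.asarray(test_means, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("ref/test mean lists must be nonempty and equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclasses.dataclass
class EvaluationReport:
    """Before/after-correction agreement statistics for one pCT/CBCT pair."""

    algorithm: str
    v_err_before: float
    v_err_after: float
    mae_before: MaeBinTable
    mae_after: MaeBinTable
    roi_table: pd.DataFrame  # tissue, ref_mean, before_mean, after_mean per ROI
    rmsd_before: dict  # tissue -> RMSD across this pair's ROIs
    rmsd_after: dict

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "v_err_before": self.v_err_before,
            "v_err_after": self.v_err_after,
            "mae_before": self.mae_before.to_dataframe().to_dict(orient="list"),
            "mae_after": self.mae_after.to_dataframe().to_dict(orient="list"),
            "roi_table": self.roi_table.to_dict(orient="list"),
            "rmsd_before": self.rmsd_before,
            "rmsd_after": self.rmsd_after,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True))

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        def table(entry):
            return MaeBinTable(
                np.asarray(entry["bin_center"], dtype=float),
                np.asarray(entry["mae"], dtype=float),
                np.asarray(entry["n"], dtype=np.int64),
                list(entry["class"]),
            )

        return cls(
            algorithm=d["algorithm"],
            v_err_before=d["v_err_before"],
            v_err_after=d["v_err_after"],
            mae_before=table(d["mae_before"]),
            mae_after=table(d["mae_after"]),
            roi_table=pd.DataFrame(d["roi_table"]),
            rmsd_before=d["rmsd_before"],
            rmsd_after=d["rmsd_after"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "EvaluationReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_report(
    pct_def: ImageVolume,
    cbct: ImageVolume,
    cbct_corr: ImageVolume,
    mask: BodyMask,
    rois: list[RoiBox],
    algo_id: str = "",
) -> EvaluationReport:
    """Assemble the full evaluation for one pair on its shared grid.

    ``pct_def`` is the deformed planning CT (the reference), ``cbct`` the
    uncorrected and ``cbct_corr`` the histogram-matched CBCT; all three and
    the mask must live on the same (CBCT) grid. ROI boxes are indexed on
    that grid too.
    """
    v_before = volume_error(pct_def, cbct, mask)
    v_after = volume_error(pct_def, cbct_corr, mask)
    mae_before = mae_by_bin(pct_def, cbct, mask)
    mae_after = mae_by_bin(pct_def, cbct_corr, mask)

    rows = []
    for roi in rois:
        rows.append(
            {
                "tissue": roi.tissue,
                "slice": roi.slice_index,
                "row": roi.row,
                "col": roi.col,
                "ref_mean": roi_mean(pct_def, roi),
                "before_mean": roi_mean(cbct, roi),
                "after_mean": roi_mean(cbct_corr, roi),
            }
        )
    roi_table = pd.DataFrame(
        rows, columns=["tissue", "slice", "row", "col", "ref_mean", "before_mean", "after_mean"]
    )
    rmsd_before: dict = {}
    rmsd_after: dict = {}
    for tissue, grp in roi_table.groupby("tissue"):
        rmsd_before[tissue] = uniformity_rmsd(list(grp.ref_mean), list(grp.before_mean))
        rmsd_after[tissue] = uniformity_rmsd(list(grp.ref_mean), list(grp.after_mean))
    return EvaluationReport(
        algorithm=algo_id,
        v_err_before=v_before,
        v_err_after=v_after,
        mae_before=mae_before,
        mae_after=mae_after,
        roi_table=roi_table,
        rmsd_before=rmsd_before,
        rmsd_after=rmsd_after,
    )


def plot_mae(report: EvaluationReport, path: str | Path) -> None:
    """Save a before/after MAE-by-bin plot (occupied bins only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for table, label in ((report.mae_before, "before HM"), (report.mae_after, "after HM")):
        occ = table.n > 0
        ax.plot(table.bin_centers[occ], table.mae[occ], marker=".", lw=1, label=label)
    for x in (AIR_BOUNDARY_HU, SOFT_BONE_LOWER_HU, BONE_BOUNDARY_HU):
        ax.axvline(x, color="0.8", lw=0.8)
    ax.set_xlabel("reference HU (20-HU bins)")
    ax.set_ylabel("MAE [HU]")
    ax.set_title(report.algorithm)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
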