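"""Evaluation statistics against naive-loop oracles and worked examples."""

import math

import numpy as np
import pytest

import cbcthm as c
from cbcthm.evaluation import classify_tissue


def _full_mask(vol):
    return c.BodyMask(np.ones(vol.shape, dtype=bool), vol.spacing, vol.origin)


# -- naive-loop oracles ----------------------------------------------------

def verr_bruteforce(ref, test, mask):
    total, n = 0.0, 0
    nz, ny, nx = ref.shape
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                if mask[i, j, k]:
                    d = ref[i, j, k] - test[i, j, k]
                    total += d * d
                    n += 1
    return math.sqrt(total / n)


def mae_bruteforce(ref, test, mask, width=20.0):
    sums, counts = {}, {}
    nz, ny, nx = ref.shape
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                if mask[i, j, k]:
                    b = math.floor((ref[i, j, k] + width / 2) / width)
                    sums[b] = sums.get(b, 0.0) + abs(ref[i, j, k] - test[i, j, k])
                    counts[b] = counts.get(b, 0) + 1
    return {b * width: (sums[b] / counts[b], counts[b]) for b in sums}


# -- worked examples -------------------------------------------------------

def test_abs_difference_examples():
    ref = c.ImageVolume(np.full((2, 2, 2), 100.0))
    test = c.ImageVolume(np.full((2, 2, 2), 40.0))
    assert np.all(c.abs_difference(ref, test).data == 60.0)
    assert np.all(c.abs_difference(ref, ref).data == 0.0)
    assert np.array_equal(c.abs_difference(ref, test).data, c.abs_difference(test, ref).data)


def test_volume_error_examples():
    ref = c.ImageVolume(np.zeros((1, 1, 2)))
    test = c.ImageVolume(np.array([3.0, 4.0]).reshape(1, 1, 2))
    mask = _full_mask(ref)
    assert c.volume_error(ref, test, mask) == pytest.approx(math.sqrt(12.5), abs=1e-12)
    assert c.volume_error(ref, ref, mask) == 0.0
    const = c.ImageVolume(np.full((1, 1, 2), -7.0))
    assert c.volume_error(ref, const, mask) == pytest.approx(7.0, abs=1e-12)


@pytest.mark.parametrize(
    "hu,expected",
    [
        (-450.0, "air"),
        (-400.0, "soft tissue"),
        (0.0, "soft tissue"),
        (249.9, "soft tissue"),
        (250.0, "soft bone"),
        (400.0, "soft bone"),
        (600.0, "soft bone"),
        (600.1, "bone"),
        (800.0, "bone"),
    ],
)
def test_classify_tissue_boundaries(hu, expected):
    assert classify_tissue(hu) == expected


def test_mae_by_bin_worked_example():
    ref = c.ImageVolume(np.array([-500.0, 0.0, 300.0, 700.0]).reshape(1, 1, 4))
    test = c.ImageVolume(ref.data + 10.0)
    table = c.mae_by_bin(ref, test, _full_mask(ref))
    occupied = table.n > 0
    assert occupied.sum() == 4
    assert np.allclose(table.mae[occupied], 10.0)
    got = {
        ctr: cls
        for ctr, cls, n in zip(table.bin_centers, table.tissue_class, table.n)
        if n > 0
    }
    assert got == {-500.0: "air", 0.0: "soft tissue", 300.0: "soft bone", 700.0: "bone"}
    assert int(table.n.sum()) == 4  # partition property
    # unoccupied bins are undefined, never zero
    assert np.all(np.isnan(table.mae[~occupied]))


def test_mae_identical_volumes_zero():
    rng = np.random.default_rng(0)
    ref = c.ImageVolume(rng.normal(0, 200, (4, 4, 4)))
    table = c.mae_by_bin(ref, ref, _full_mask(ref))
    assert np.all(table.mae[table.n > 0] == 0.0)


def test_mae_matches_bruteforce_and_wide_bin_limit():
    rng = np.random.default_rng(5)
    ref = c.ImageVolume(rng.normal(0, 300, (6, 6, 6)))
    test = c.ImageVolume(ref.data + rng.normal(0, 40, (6, 6, 6)))
    mask = rng.random((6, 6, 6)) > 0.3
    bm = c.BodyMask(mask, ref.spacing, ref.origin)
    table = c.mae_by_bin(ref, test, bm)
    oracle = mae_bruteforce(ref.data, test.data, mask)
    for ctr, mae, n in zip(table.bin_centers, table.mae, table.n):
        if n > 0:
            assert mae == pytest.approx(oracle[ctr][0], abs=1e-10)
            assert n == oracle[ctr][1]
    assert int(table.n.sum()) == int(mask.sum())
    # one giant bin reproduces the overall MAE
    wide = c.mae_by_bin(ref, test, bm, bin_width=1e9)
    overall = np.abs(ref.data[mask] - test.data[mask]).mean()
    assert wide.overall_mae() == pytest.approx(overall, abs=1e-9)
    assert table.overall_mae() == pytest.approx(overall, abs=1e-9)


def test_volume_error_dominates_mae():
    rng = np.random.default_rng(8)
    ref = c.ImageVolume(rng.normal(0, 100, (5, 5, 5)))
    test = c.ImageVolume(ref.data + rng.normal(0, 30, (5, 5, 5)))
    mask = _full_mask(ref)
    verr = c.volume_error(ref, test, mask)
    assert verr == pytest.approx(verr_bruteforce(ref.data, test.data, mask.data), abs=1e-10)
    overall_mae = c.mae_by_bin(ref, test, mask).overall_mae()
    assert verr >= overall_mae >= 0.0


def test_roi_mean_examples():
    data = np.zeros((3, 12, 12))
    data[1, 1:11, 1:11] = np.arange(100, dtype=float).reshape(10, 10)
    vol = c.ImageVolume(data)
    assert c.roi_mean(vol, c.RoiBox(1, 1, 1)) == pytest.approx(49.5)
    const = c.ImageVolume(np.full((3, 12, 12), 50.0))
    assert c.roi_mean(const, c.RoiBox(0, 0, 0)) == 50.0
    with pytest.raises(IndexError):
        c.roi_mean(vol, c.RoiBox(1, 5, 5))  # 10x10 box exceeds the 12-px plane


def test_uniformity_rmsd_examples():
    assert c.uniformity_rmsd([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert c.uniformity_rmsd([0.0, 0.0], [3.0, 4.0]) == pytest.approx(math.sqrt(12.5))
    assert c.uniformity_rmsd([5.0], [2.0]) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        c.uniformity_rmsd([], [])
    with pytest.raises(ValueError):
        c.uniformity_rmsd([1.0], [1.0, 2.0])


def test_build_report_perfect_correction(tmp_path):
    rng = np.random.default_rng(4)
    ref = c.ImageVolume(rng.normal(0, 150, (4, 16, 16)))
    before = c.ImageVolume(ref.data - 60.0)
    mask = _full_mask(ref)
    rois = [c.RoiBox(2, 2, 2, 5, 5, "fat"), c.RoiBox(2, 9, 9, 5, 5, "muscle")]
    report = c.build_report(ref, before, ref, mask, rois, algo_id="DR-NCC")
    assert report.v_err_before == pytest.approx(60.0, abs=1e-9)
    assert report.v_err_after == 0.0
    assert np.all(report.mae_after.mae[report.mae_after.n > 0] == 0.0)
    assert all(v == 0.0 for v in report.rmsd_after.values())
    # serialization roundtrip
    path = tmp_path / "report.json"
    report.save(path)
    back = c.EvaluationReport.load(path)
    assert back.algorithm == "DR-NCC"
    assert back.v_err_before == pytest.approx(report.v_err_before)
    assert np.allclose(back.mae_before.bin_centers, report.mae_before.bin_centers)
    assert back.rmsd_after == report.rmsd_after
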