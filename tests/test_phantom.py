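"""Phantom generator: determinism, tissue fidelity, warp and degradation."""

import dataclasses

import numpy as np
import pytest

import cbcthm as c
from cbcthm.phantom import PhantomSpecError

from .conftest import small_spec

CLASS_INTERVALS = {
    c.LabelVolume.FAT: (-400.0, 250.0),
    c.LabelVolume.MUSCLE: (-400.0, 250.0),
    c.LabelVolume.SOFT_BONE: (250.0, 600.0),
    c.LabelVolume.BONE: (600.0, np.inf),
    c.LabelVolume.RECTAL_GAS: (-np.inf, -400.0),
}


def test_zero_noise_tissues_take_exact_means():
    spec = small_spec(jitter_hu=0.0, texture_hu=0.0)
    vol, labels, _ = c.generate_pct(spec)
    fat = vol.data[labels.data == c.LabelVolume.FAT]
    assert fat.size > 0 and np.all(fat == -100.0)
    outside = vol.data[labels.data == c.LabelVolume.AIR]
    assert np.all(outside == -1000.0)


def test_generation_is_deterministic():
    a = c.generate_pct(small_spec(seed=9))
    b = c.generate_pct(small_spec(seed=9))
    assert np.array_equal(a[0].data, b[0].data)
    assert np.array_equal(a[1].data, b[1].data)
    assert a[2] == b[2]


def test_soft_tissue_dominates_body():
    vol, labels, _ = c.generate_pct(small_spec())
    body_vals = vol.data[labels.body_support()]
    frac = np.mean((body_vals >= -400) & (body_vals < 250))
    assert frac >= 0.8


def test_labels_consistent_with_tissue_classes():
    vol, labels, _ = c.generate_pct(small_spec())
    for code, (lo, hi) in CLASS_INTERVALS.items():
        vals = vol.data[labels.data == code]
        assert vals.size > 0
        inside = np.mean((vals >= lo) & (vals < hi))
        assert inside >= 0.99, (code, inside)


def test_spec_validation_names_offending_field():
    with pytest.raises(PhantomSpecError, match="deformation_amplitude_mm"):
        small_spec(deformation_amplitude_mm=30.0, deformation_grid_mm=48.0).validate()
    with pytest.raises(PhantomSpecError, match="spacing"):
        small_spec(spacing=(0.0, 1.0, 1.0)).validate()
    with pytest.raises(PhantomSpecError, match="tissue_means"):
        spec = small_spec()
        spec.tissue_means["fat"] = 700.0
        spec.validate()


def test_roi_boxes_lie_inside_their_tissue():
    # clinical in-plane pitch: the subcutaneous fat ring must be >= 10 px wide
    _, labels, rois = c.generate_pct(
        c.PhantomSpec(shape=(32, 160, 160), spacing=(3.0, 0.8496, 0.8496), seed=3)
    )
    by_tissue = {"fat": 0, "muscle": 0}
    for roi in rois:
        code = {"fat": c.LabelVolume.FAT, "muscle": c.LabelVolume.MUSCLE}[roi.tissue]
        patch = labels.data[
            roi.slice_index, roi.row : roi.row + roi.height, roi.col : roi.col + roi.width
        ]
        assert patch.shape == (10, 10)
        assert np.all(patch == code)
        by_tissue[roi.tissue] += 1
    assert by_tissue["fat"] >= 5 and by_tissue["muscle"] >= 5


class TestGroundTruthWarp:
    def test_zero_amplitude_is_identity(self):
        warp = c.make_ground_truth_warp(small_spec(deformation_amplitude_mm=0.0))
        assert np.all(warp.coefficients == 0.0)

    def test_amplitude_bounds_dense_displacement(self):
        spec = small_spec(deformation_amplitude_mm=8.0)
        warp = c.make_ground_truth_warp(spec)
        vol, _, _ = c.generate_pct(spec)
        disp = warp.displacement(vol.grid_points()[::11])
        assert np.linalg.norm(disp, axis=1).max() <= 8.0 * np.sqrt(3) + 1e-9
        assert np.abs(disp).max() <= 8.0 + 1e-9

    def test_fixed_seed_reproduces_control_table(self):
        w1 = c.make_ground_truth_warp(small_spec(seed=5))
        w2 = c.make_ground_truth_warp(small_spec(seed=5))
        assert np.array_equal(w1.coefficients, w2.coefficients)

    def test_warp_is_fold_free(self):
        # positive Jacobian determinant at sampled interior points
        spec = small_spec()
        warp = c.make_ground_truth_warp(spec)
        vol, _, _ = c.generate_pct(spec)
        pts = vol.grid_points()[::203]
        eps = 0.25
        jac = np.empty((len(pts), 3, 3))
        for k in range(3):
            e = np.zeros(3)
            e[k] = eps
            jac[:, :, k] = (warp.apply(pts + e) - warp.apply(pts - e)) / (2 * eps)
        dets = np.linalg.det(jac)
        assert dets.min() > 0.0


class TestDegradeToCbct:
    def test_identity_degradation_preserves_volume(self):
        spec = small_spec(
            cbct_shift_hu=0.0,
            shading_amplitude=0.0,
            noise_sigma_hu=0.0,
            axial_crop_fraction=1.0,
            cbct_spacing=(3.0, 1.42, 1.42),
            deformation_amplitude_mm=0.0,
        )
        vol, labels, _ = c.generate_pct(spec)
        warp = c.make_ground_truth_warp(spec)
        out = c.degrade_to_cbct(vol, labels, warp, spec)
        assert out.shape == vol.shape
        assert np.allclose(out.data, vol.data, atol=1e-9)

    def test_pure_shift_changes_body_by_constant(self):
        spec = small_spec(
            cbct_shift_hu=-60.0,
            shading_amplitude=0.0,
            noise_sigma_hu=0.0,
            axial_crop_fraction=1.0,
            cbct_spacing=(3.0, 1.42, 1.42),
            deformation_amplitude_mm=0.0,
        )
        vol, labels, _ = c.generate_pct(spec)
        warp = c.make_ground_truth_warp(spec)
        out = c.degrade_to_cbct(vol, labels, warp, spec)
        body = labels.body_support()
        assert np.allclose(out.data[body] - vol.data[body], -60.0, atol=1e-9)
        assert np.all(out.data[~body] == -1000.0)

    def test_default_degradation_produces_large_volume_error(self, phantom_pair):
        from cbcthm.registration import resample

        cbct = phantom_pair["cbct"]
        deformed = resample(phantom_pair["pct"], phantom_pair["warp"], cbct)
        mask = c.BodyMask(
            phantom_pair["labels_cbct"].body_support(), cbct.spacing, cbct.origin
        )
        assert c.volume_error(deformed, cbct, mask) > 40.0

    def test_degradation_deterministic(self):
        spec = small_spec(seed=12)
        out1 = c.generate_pair(spec)["cbct"]
        out2 = c.generate_pair(spec)["cbct"]
        assert np.array_equal(out1.data, out2.data)


def test_pair_serialization(tmp_path, phantom_pair):
    from cbcthm.phantom import save_pair

    save_pair(phantom_pair, tmp_path)
    back = c.read_volume(tmp_path / "cbct.nii.gz")
    assert np.allclose(back.data, phantom_pair["cbct"].data, atol=1e-4)
    warp = c.load_transform(tmp_path / "warp.json")
    pts = phantom_pair["cbct"].grid_points()[::301]
    assert np.allclose(warp.apply(pts), phantom_pair["warp"].apply(pts), atol=1e-9)
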