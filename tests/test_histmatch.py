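"""Cumulative-histogram matching: CDFs, LUT inversion, application."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cbcthm as c
from cbcthm.histmatch import build_cdf, compute_matching_lut


def _vol_and_mask(values):
    values = np.asarray(values, dtype=float)
    vol = c.ImageVolume(values.reshape(1, 1, -1))
    mask = c.BodyMask(np.ones(vol.shape, dtype=bool), vol.spacing, vol.origin)
    return vol, mask


def test_constant_volume_gives_unit_step_cdf():
    vol, mask = _vol_and_mask([42.0] * 8)
    h = build_cdf(vol, mask, bins=4)
    assert h.cdf[-1] == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(h.cdf) >= 0)
    assert h.counts.sum() == 8


def test_two_level_cdf_counts():
    vol, mask = _vol_and_mask([0.0, 0.0, 10.0, 10.0])
    h = build_cdf(vol, mask, bins=2)
    assert np.allclose(h.cdf, [0.5, 1.0])
    assert h.mask_voxels == 4


def test_cdf_total_equals_mask_cardinality(phantom_pair):
    vol = phantom_pair["pct"]
    labels = phantom_pair["labels"]
    mask = c.BodyMask(labels.body_support(), vol.spacing, vol.origin)
    h = build_cdf(vol, mask, bins=256)
    assert h.counts.sum() == mask.count() == h.mask_voxels


def test_empty_mask_rejected():
    vol, _ = _vol_and_mask([1.0, 2.0])
    empty = c.BodyMask(np.zeros(vol.shape, dtype=bool), vol.spacing, vol.origin)
    with pytest.raises(ValueError):
        build_cdf(vol, empty, bins=4)


def test_matching_identical_histograms_is_identity():
    rng = np.random.default_rng(0)
    values = rng.normal(0, 100, 4000)
    vol, mask = _vol_and_mask(values)
    h = build_cdf(vol, mask, bins=128)
    lut = compute_matching_lut(h, h)
    half_bin = (h.edges[-1] - h.edges[0]) / 128 / 2
    # identity holds on the histogram's support (where voxel mass exists)
    probe = np.quantile(values, np.linspace(0.01, 0.99, 50))
    assert np.all(np.abs(lut(probe) - probe) <= half_bin + 1e-9)


def test_matching_inverts_constant_shift():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 80, 5000)
    src_vol, mask = _vol_and_mask(base)
    ref_vol, _ = _vol_and_mask(base + 100.0)
    src = build_cdf(src_vol, mask, bins=256)
    ref = build_cdf(ref_vol, mask, bins=256)
    lut = compute_matching_lut(src, ref)
    half_bin = (src.edges[-1] - src.edges[0]) / 256 / 2
    probe = np.linspace(np.percentile(base, 1), np.percentile(base, 99), 50)
    assert np.all(np.abs(lut(probe) - (probe + 100.0)) <= half_bin + 1e-9)


def test_two_step_histograms_match_level_to_level():
    src_vol, mask = _vol_and_mask([0.0] * 50 + [10.0] * 50)
    ref_vol, _ = _vol_and_mask([5.0] * 50 + [20.0] * 50)
    lut = compute_matching_lut(build_cdf(src_vol, mask, 64), build_cdf(ref_vol, mask, 64))
    assert lut(0.0) == pytest.approx(5.0, abs=0.5)
    assert lut(10.0) == pytest.approx(20.0, abs=0.5)


def test_apply_mapping_preserves_outside_and_counts():
    rng = np.random.default_rng(2)
    data = rng.normal(0, 50, (6, 8, 8))
    vol = c.ImageVolume(data)
    inside = np.zeros(vol.shape, dtype=bool)
    inside[2:4, 2:6, 2:6] = True
    mask = c.BodyMask(inside, vol.spacing, vol.origin)
    lut = c.IntensityMapping(np.array([-200.0, 200.0]), np.array([-100.0, 300.0]))
    out = c.apply_mapping(vol, lut, mask)
    assert np.array_equal(out.data[~inside], data[~inside])
    assert mask.count() == inside.sum()  # mass conservation: mask untouched
    assert out.shape == vol.shape


def test_identity_mapping_leaves_volume_unchanged():
    rng = np.random.default_rng(3)
    vol, mask = _vol_and_mask(rng.normal(0, 50, 500))
    lut = c.IntensityMapping.identity(-500, 500)
    out = c.apply_mapping(vol, lut, mask)
    assert np.allclose(out.data, vol.data)


def test_non_monotone_mapping_rejected():
    with pytest.raises(ValueError):
        c.IntensityMapping(np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 1.0]))


def test_lut_json_roundtrip(tmp_path):
    lut = c.IntensityMapping(np.array([-100.0, 0.0, 50.0]), np.array([-90.0, 5.0, 60.0]))
    lut.save(tmp_path / "lut.json")
    back = c.IntensityMapping.load(tmp_path / "lut.json")
    probe = np.linspace(-150, 100, 40)
    assert np.allclose(back(probe), lut(probe))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_matching_preserves_voxel_ordering(seed):
    rng = np.random.default_rng(seed)
    src_vol, mask = _vol_and_mask(rng.normal(0, 60, 2000))
    ref_vol, _ = _vol_and_mask(rng.gamma(4, 30, 2000) - 200)
    lut = compute_matching_lut(build_cdf(src_vol, mask, 128), build_cdf(ref_vol, mask, 128))
    probe = np.sort(rng.uniform(-250, 250, 100))
    mapped = lut(probe)
    assert np.all(np.diff(mapped) >= -1e-9)


def _sup_cdf_distance(a, b, mask, bins=1024):
    """Kolmogorov distance between two masked intensity CDFs."""
    vals_a = a.data[mask.data]
    vals_b = b.data[mask.data]
    lo = min(vals_a.min(), vals_b.min())
    hi = max(vals_a.max(), vals_b.max())
    edges = np.linspace(lo, hi, bins + 1)
    cdf_a = np.cumsum(np.histogram(vals_a, bins=edges)[0]) / vals_a.size
    cdf_b = np.cumsum(np.histogram(vals_b, bins=edges)[0]) / vals_b.size
    return float(np.abs(cdf_a - cdf_b).max())


def test_matched_phantom_cdfs_agree(phantom_pair):
    """After HM against the truth-warped pCT, the masked CDFs nearly coincide."""
    from cbcthm.registration import resample

    cbct = phantom_pair["cbct"]
    cbct_pp, cbct_mask = c.preprocess_volume(cbct, threshold=-600.0)
    deformed = resample(phantom_pair["pct"], phantom_pair["warp"], cbct_pp)
    corrected, _ = c.match_histograms(cbct_pp, deformed, cbct_mask, bins=1024)
    assert _sup_cdf_distance(corrected, deformed, cbct_mask) <= 0.02


def test_rematching_is_a_fixed_point(phantom_pair):
    """Recomputing the LUT from the corrected volume changes almost nothing."""
    from cbcthm.registration import resample

    cbct_pp, cbct_mask = c.preprocess_volume(phantom_pair["cbct"], threshold=-600.0)
    deformed = resample(phantom_pair["pct"], phantom_pair["warp"], cbct_pp)
    corrected, _ = c.match_histograms(cbct_pp, deformed, cbct_mask, bins=1024)
    corrected2, _ = c.match_histograms(corrected, deformed, cbct_mask, bins=1024)
    delta = np.abs(corrected2.data[cbct_mask.data] - corrected.data[cbct_mask.data])
    assert np.mean(delta > 1.0) <= 0.01
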