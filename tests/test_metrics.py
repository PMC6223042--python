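"""Similarity metrics against independent brute-force evaluations.

The oracles here are written as explicit loops over voxels/bins, sharing
only the binning convention with the implementation, never its code path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cbcthm as c
from cbcthm.metrics import DegenerateSampleError, SamplingDomain


# -- independent oracles ---------------------------------------------------

def ncc_bruteforce(f, m):
    fbar = sum(f) / len(f)
    mbar = sum(m) / len(m)
    num = sum((a - fbar) * (b - mbar) for a, b in zip(f, m))
    den = math.sqrt(
        sum((a - fbar) ** 2 for a in f) * sum((b - mbar) ** 2 for b in m)
    )
    return num / den


def joint_hist_bruteforce(f, m, bins):
    f_lo, f_hi = min(f), max(f)
    m_lo, m_hi = min(m), max(m)
    p = np.zeros((bins, bins))
    for a, b in zip(f, m):
        i = min(int((a - f_lo) / (f_hi - f_lo) * bins), bins - 1)
        j = min(int((b - m_lo) / (m_hi - m_lo) * bins), bins - 1)
        p[i, j] += 1.0
    return p / len(f)


def entropy_bruteforce(p):
    return -sum(v * math.log(v) for v in np.ravel(p) if v > 0)


def mi_nmi_bruteforce(f, m, bins):
    p = joint_hist_bruteforce(f, m, bins)
    hf = entropy_bruteforce(p.sum(axis=1))
    hm = entropy_bruteforce(p.sum(axis=0))
    hj = entropy_bruteforce(p)
    return hf + hm - hj, (hf + hm) / hj


def _volume_pair(rng, correlated=True):
    shape = tuple(rng.integers(4, 17, 3))
    f = rng.normal(0, 100, shape)
    m = 0.7 * f + rng.normal(0, 60, shape) if correlated else rng.normal(0, 100, shape)
    return c.ImageVolume(f), c.ImageVolume(m)


# -- worked examples -------------------------------------------------------

def _domain_for(values):
    """Four-site sampling domain with prescribed fixed values."""
    pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]], dtype=float)
    return SamplingDomain(pts, np.asarray(values, dtype=float))


def _line_volume(values):
    return c.ImageVolume(np.asarray(values, dtype=float).reshape(1, 1, -1))


def test_ncc_identical_images_is_one(phantom_pair):
    vol = phantom_pair["pct"]
    dom = SamplingDomain.full_grid(vol)
    assert c.metric_ncc(vol, vol, c.IdentityTransform(), dom) == pytest.approx(1.0, abs=1e-12)


def test_ncc_perfect_anticorrelation_is_minus_one():
    f = _line_volume([1, 2, 3, 4])
    m = _line_volume([4, 3, 2, 1])
    dom = SamplingDomain.full_grid(f)
    assert c.metric_ncc(f, m, c.IdentityTransform(), dom) == pytest.approx(-1.0, abs=1e-12)


def test_ncc_orthogonal_patterns_are_uncorrelated():
    f = _line_volume([0, 1, 0, 1])
    m = _line_volume([1, 1, 0, 0])
    dom = SamplingDomain.full_grid(f)
    assert c.metric_ncc(f, m, c.IdentityTransform(), dom) == pytest.approx(0.0, abs=1e-12)


def test_ncc_constant_image_raises():
    f = _line_volume([5, 5, 5, 5])
    m = _line_volume([1, 2, 3, 4])
    with pytest.raises(DegenerateSampleError):
        c.metric_ncc(f, m, c.IdentityTransform(), SamplingDomain.full_grid(f))


def test_joint_histogram_two_level_identical_is_diagonal():
    f = _line_volume([0, 0, 1, 1])
    h = c.build_joint_histogram(f, f, c.IdentityTransform(), SamplingDomain.full_grid(f), bins=2, kernel="nearest")
    assert np.allclose(h.p, np.diag([0.5, 0.5]))
    assert c.metric_mi(h) == pytest.approx(math.log(2), abs=1e-12)
    assert c.metric_nmi(h) == pytest.approx(2.0, abs=1e-12)


def test_joint_histogram_independent_patterns_uniform():
    f = _line_volume([0, 0, 1, 1])
    m = _line_volume([0, 1, 0, 1])
    h = c.build_joint_histogram(f, m, c.IdentityTransform(), SamplingDomain.full_grid(f), bins=2, kernel="nearest")
    assert np.allclose(h.p, np.full((2, 2), 0.25))
    assert c.metric_mi(h) == pytest.approx(0.0, abs=1e-12)
    assert c.metric_nmi(h) == pytest.approx(1.0, abs=1e-12)


def test_histogram_marginals_and_normalization():
    rng = np.random.default_rng(2)
    f, m = _volume_pair(rng)
    dom = SamplingDomain.full_grid(f)
    for kernel in ("nearest", "bspline3"):
        h = c.build_joint_histogram(f, m, c.IdentityTransform(), dom, bins=16, kernel=kernel)
        assert h.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(h.marginal_fixed(), h.p.sum(axis=1), atol=1e-12)
        assert np.allclose(h.marginal_moving(), h.p.sum(axis=0), atol=1e-12)
        for ent in (h.entropy_fixed(), h.entropy_moving(), h.entropy_joint()):
            assert ent >= 0.0


def test_metrics_match_bruteforce_on_random_volumes():
    rng = np.random.default_rng(7)
    for trial in range(10):
        f, m = _volume_pair(rng, correlated=trial % 2 == 0)
        dom = SamplingDomain.full_grid(f)
        ncc = c.metric_ncc(f, m, c.IdentityTransform(), dom)
        assert ncc == pytest.approx(
            ncc_bruteforce(list(f.data.ravel()), list(m.data.ravel())), abs=1e-10
        )
        h = c.build_joint_histogram(f, m, c.IdentityTransform(), dom, bins=12, kernel="nearest")
        mi_ref, nmi_ref = mi_nmi_bruteforce(
            list(f.data.ravel()), list(m.data.ravel()), 12
        )
        assert c.metric_mi(h) == pytest.approx(mi_ref, abs=1e-8)
        assert c.metric_nmi(h) == pytest.approx(nmi_ref, abs=1e-8)


def test_information_bounds_and_identities():
    rng = np.random.default_rng(11)
    for _ in range(5):
        f, m = _volume_pair(rng)
        dom = SamplingDomain.full_grid(f)
        h = c.build_joint_histogram(f, m, c.IdentityTransform(), dom, bins=16, kernel="nearest")
        mi = c.metric_mi(h)
        assert mi >= -1e-12
        assert mi <= min(h.entropy_fixed(), h.entropy_moving()) + 1e-12
        assert c.metric_nmi(h) == pytest.approx(1.0 + mi / h.entropy_joint(), abs=1e-12)


def test_nmi_degenerate_when_both_images_constant():
    f = _line_volume([3, 3, 3, 3])
    h = c.build_joint_histogram(
        f, f, c.IdentityTransform(), SamplingDomain.full_grid(f), bins=4, kernel="nearest"
    )
    # single-cell joint: entropies are zero -> NMI undefined
    assert h.entropy_joint() == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(DegenerateSampleError):
        c.metric_nmi(h)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.1, 50.0),
    offset=st.floats(-500.0, 500.0),
    seed=st.integers(0, 2**20),
)
def test_ncc_invariant_under_positive_affine_rescaling(scale, offset, seed):
    rng = np.random.default_rng(seed)
    f, m = _volume_pair(rng)
    dom = SamplingDomain.full_grid(f)
    base = c.metric_ncc(f, m, c.IdentityTransform(), dom)
    m2 = c.ImageVolume(m.data * scale + offset)
    assert c.metric_ncc(f, m2, c.IdentityTransform(), dom) == pytest.approx(base, abs=1e-10)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_mi_symmetric_under_image_swap(seed):
    rng = np.random.default_rng(seed)
    f, m = _volume_pair(rng)
    dom_f = SamplingDomain.full_grid(f)
    dom_m = SamplingDomain.full_grid(m)
    h_fm = c.build_joint_histogram(f, m, c.IdentityTransform(), dom_f, bins=10, kernel="nearest")
    h_mf = c.build_joint_histogram(m, f, c.IdentityTransform(), dom_m, bins=10, kernel="nearest")
    assert c.metric_mi(h_fm) == pytest.approx(c.metric_mi(h_mf), abs=1e-10)
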