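"""Feature extractor: discretization, first-order, GLCM, shape, wavelet."""

import itertools

import numpy as np
import pytest

from rtae.image_features import (
    DIRECTIONS_13,
    GLCM_NAMES,
    DiscretizationSpec,
    VolumeMask,
    discretize,
    extract_all,
    first_order_features,
    glcm_features,
    glcm_features_single,
    haar3d,
    haar3d_inverse,
    shape_features,
)
from rtae.synthetic_cohort import generate_lesion_volume


def cube(values):
    arr = np.asarray(values, dtype=float)
    return VolumeMask(arr, np.ones_like(arr, dtype=bool), (1, 1, 1))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def test_discretize_fixed_bin_width():
    vals = np.arange(256, dtype=float).reshape(4, 8, 8)
    lv = discretize(cube(vals), DiscretizationSpec(mode="fixed-bin-width", width=25))
    assert lv.min() == 1 and lv.max() == 11
    assert lv.flat[255] == 11  # 255 -> floor(255/25)+1


def test_discretize_fixed_bin_count_top_edge():
    vals = np.array([0, 1, 2, 3, 4], dtype=float).reshape(5, 1, 1)
    lv = discretize(cube(vals), DiscretizationSpec(mode="fixed-bin-count", bins=4))
    assert lv.ravel().tolist() == [1, 2, 3, 4, 4]  # max goes to bin 4, not 5


def test_discretize_constant_region():
    vals = np.full((3, 3, 3), 7.0)
    for spec in (DiscretizationSpec(), DiscretizationSpec(mode="fixed-bin-count", bins=8)):
        assert np.all(discretize(cube(vals), spec) == 1)


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def test_first_order_constant_region():
    fv = first_order_features(np.full(27, 5.0))
    assert fv["Mean"] == 5.0
    assert fv["Variance"] == 0.0
    assert fv["Entropy"] == 0.0
    assert fv["Energy"] == 27 * 25.0
    assert "Skewness" in fv.undefined and "Kurtosis" in fv.undefined


def test_first_order_two_equal_bins():
    fv = first_order_features(
        np.array([1.0, 1.0, 2.0, 2.0]), DiscretizationSpec(width=1.0)
    )
    assert fv["Entropy"] == pytest.approx(1.0)
    assert fv["Uniformity"] == pytest.approx(0.5)


def test_first_order_symmetry_and_names():
    fv = first_order_features(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    assert fv["Skewness"] == pytest.approx(0.0, abs=1e-12)
    assert len(fv) == 18 and len(set(fv.names)) == 18
    assert fv["RootMeanSquared"] == pytest.approx(np.sqrt(np.mean(np.arange(1, 6.0) ** 2)))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def test_glcm_constant_region():
    lv = np.ones((3, 3, 3), dtype=int)
    fv = glcm_features(lv, np.ones((3, 3, 3), bool))
    assert fv["JointEnergy"] == pytest.approx(1.0)
    assert fv["Contrast"] == pytest.approx(0.0)
    assert fv["JointEntropy"] == pytest.approx(0.0)


def test_glcm_alternating_strip_hand_matrix():
    """1D strip 1,2,1,2 with a single +x offset: P(1,2)=P(2,1)=0.5."""
    lv = np.array([1, 2, 1, 2], dtype=int).reshape(1, 1, 4)
    fv = glcm_features(lv, np.ones((1, 1, 4), bool), offsets=[(0, 0, 1)])
    assert fv["Contrast"] == pytest.approx(1.0)
    assert fv["JointEnergy"] == pytest.approx(0.5)
    assert fv["Correlation"] == pytest.approx(-1.0)


def glcm_bruteforce_oracle(levels, mask, offsets, distance=1):
    """Direction-averaged features from explicit voxel-pair enumeration."""
    per_dir = []
    shape = levels.shape
    for off in offsets:
        off = tuple(distance * o for o in off)
        n_lv = levels.max()
        P = np.zeros((n_lv, n_lv))
        for idx in itertools.product(*(range(s) for s in shape)):
            if not mask[idx]:
                continue
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= j < s for j, s in zip(nb, shape)) and mask[nb]:
                P[levels[idx] - 1, levels[nb] - 1] += 1
        if P.sum() == 0:
            continue
        P = P + P.T
        per_dir.append(glcm_features_single(P / P.sum()))
    out = {}
    for name in GLCM_NAMES:
        out[name] = float(np.mean([d[name] for d in per_dir]))
    return out


def test_glcm_matches_bruteforce_oracle(rng):
    vol = rng.integers(0, 80, size=(4, 4, 4)).astype(float)
    mask = rng.random((4, 4, 4)) > 0.2
    mask[0, 0, 0] = True
    vm = VolumeMask(vol, mask, (1, 1, 1))
    lv = discretize(vm, DiscretizationSpec(width=20))
    fv = glcm_features(lv, mask)
    oracle = glcm_bruteforce_oracle(lv, mask, DIRECTIONS_13)
    for name in GLCM_NAMES:
        assert fv[name] == pytest.approx(oracle[name], abs=1e-10), name


def test_glcm_probabilities_sum_and_symmetry(rng):
    from rtae.image_features import _cooccurrence

    lv = rng.integers(1, 5, size=(5, 5, 5))
    mask = np.ones((5, 5, 5), bool)
    for off in DIRECTIONS_13:
        P = _cooccurrence(lv, mask, off)
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P, P.T)


def test_glcm_single_voxel_undefined():
    lv = np.array([[[1]]])
    fv = glcm_features(lv, np.ones((1, 1, 1), bool))
    assert fv.undefined == set(GLCM_NAMES)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def test_shape_single_voxel():
    fv = shape_features(np.ones((1, 1, 1), bool), (1, 1, 1))
    assert fv["VoxelVolume"] == 1.0
    assert fv["SurfaceArea"] == 6.0
    assert fv["Maximum3DDiameter"] == 0.0


def test_shape_two_voxels_anisotropic():
    mask = np.zeros((1, 1, 2), bool)
    mask[0, 0, :] = True
    fv = shape_features(mask, (1, 1, 3))
    assert fv["Maximum3DDiameter"] == pytest.approx(3.0)
    assert fv["VoxelVolume"] == pytest.approx(6.0)
    # 2 voxels of 1x1x3 mm: exposed faces 2*(1*1) caps + 2*(1*3)*2 + 2*(3*1)*2
    assert fv["SurfaceArea"] == pytest.approx(2 * 1 + 4 * 3 + 4 * 3)


def test_sphericity_bounded_with_known_face_counting_bias():
    """Digitized balls: sphericity stays <= 1 and near the exposed-face
    limit. Staircase faces overestimate a sphere's area by ~3/2, so the
    face-counting sphericity of a ball tends to 2/3 rather than 1 — the
    documented bias of this surface estimator."""
    for radius in (4.0, 8.0, 12.0):
        vm = generate_lesion_volume((40, 40, 40), (1, 1, 1), radius, seed=0)
        fv = shape_features(vm.mask, vm.spacing)
        assert fv["Sphericity"] <= 1.0
        assert fv["Sphericity"] == pytest.approx(2 / 3, abs=0.05)


def test_sphericity_exact_for_cube():
    """A digitized cube has no staircase error: sphericity = (pi/6)^(1/3)."""
    mask = np.zeros((12, 12, 12), bool)
    mask[2:10, 2:10, 2:10] = True
    fv = shape_features(mask, (1, 1, 1))
    assert fv["Sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-12)


# ---------------------------------------------------------------------------
# Haar wavelet
# ---------------------------------------------------------------------------

def test_haar_constant_volume():
    bands = haar3d(np.full((4, 4, 4), 3.0))
    assert np.allclose(bands["LLL"], 3.0 * 2 * np.sqrt(2))
    for k, v in bands.items():
        if k != "LLL":
            assert np.allclose(v, 0.0)


def test_haar_parseval_and_inverse(rng):
    vol = rng.normal(size=(6, 6, 6))
    bands = haar3d(vol)
    energy = sum(np.sum(b**2) for b in bands.values())
    assert energy == pytest.approx(np.sum(vol**2), abs=1e-10)
    rec = haar3d_inverse(bands)
    assert np.allclose(rec, vol, atol=1e-10)


def test_haar_impulse_equal_magnitudes():
    vol = np.zeros((2, 2, 2))
    vol[0, 0, 0] = 5.0
    bands = haar3d(vol)
    for v in bands.values():
        assert abs(v[0, 0, 0]) == pytest.approx(5.0 / (2 * np.sqrt(2)))


def test_haar_odd_dims_padded():
    bands = haar3d(np.zeros((5, 4, 7)))
    assert bands["LLL"].shape == (3, 2, 4)


# ---------------------------------------------------------------------------
# extract_all
# ---------------------------------------------------------------------------

def test_extract_all_count_contract_and_determinism():
    vm = generate_lesion_volume((16, 16, 16), (1, 1, 1), 6.0, seed=3)
    fv = extract_all(vm)
    k_glcm = len(GLCM_NAMES)
    assert len(fv) == 18 + k_glcm + 4 + 8 * (18 + k_glcm)
    fv2 = extract_all(vm)
    assert fv.names == fv2.names
    assert all(
        (np.isnan(fv.values[n]) and np.isnan(fv2.values[n])) or fv.values[n] == fv2.values[n]
        for n in fv.names
    )


def test_extract_all_shift_invariant_features():
    """Adding a constant leaves variance and fixed-bin-count entropy alone."""
    vm = generate_lesion_volume((16, 16, 16), (1, 1, 1), 6.0, seed=3)
    shifted = VolumeMask(vm.intensities + 500.0 * vm.mask, vm.mask, vm.spacing)
    spec = DiscretizationSpec(mode="fixed-bin-count", bins=16)
    a = extract_all(vm, spec)
    b = extract_all(shifted, spec)
    for name in (
        "original_firstorder_Variance",
        "original_firstorder_Entropy",
        "original_firstorder_InterquartileRange",
        "original_glcm_Contrast",
    ):
        assert a[name] == pytest.approx(b[name], rel=1e-9), name


def test_extract_all_finite_on_synthetic_lesions():
    vm = generate_lesion_volume((20, 20, 20), (1, 1, 2), 7.0, seed=12)
    fv = extract_all(vm)
    defined = [n for n in fv.names if n not in fv.undefined]
    assert np.all(np.isfinite([fv.values[n] for n in defined]))
    assert not fv.undefined  # this lesion has texture everywhere
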