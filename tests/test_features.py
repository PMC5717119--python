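import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petprog.exceptions import DegenerateInputError
from petprog.features import (
    discretise,
    extract_all,
    glcm_features,
    glszm_features,
    histogram_distribution,
    histogram_features,
    ngtdm_coarseness,
    suv_stats,
)
from petprog.io import BinaryMask, PETVolume
from petprog.synthetic import PhantomSpec, generate_phantom

from oracles import brute_coarseness, brute_glcm_features, brute_glszm_features
from conftest import random_roi


def make_roi(values, spacing=(1.0, 1.0, 1.0), width=0.5):
    arr = np.asarray(values, dtype=float).reshape(1, 1, -1)
    vol = PETVolume(arr, spacing)
    mask = BinaryMask(np.ones(arr.shape, np.uint8), spacing)
    return discretise(vol, mask, width)


class TestDiscretise:
    def test_floor_arithmetic(self):
        assert list(make_roi([0.2, 0.7, 1.2]).bins) == [1, 2, 3]

    def test_bin_edge_goes_to_upper_bin(self):
        assert make_roi([0.5]).bins[0] == 2

    def test_constant_roi_single_occupied_bin(self):
        _, p = histogram_distribution(make_roi([1.1, 1.1, 1.1]))
        assert list(p) == [1.0]

    def test_empty_mask_degenerate(self):
        vol = PETVolume(np.ones((2, 2, 2)), (1, 1, 1))
        empty = BinaryMask(np.zeros((2, 2, 2), np.uint8), (1, 1, 1))
        with pytest.raises(DegenerateInputError):
            discretise(vol, empty)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_bin_covers_half_open_interval(self, v):
        b = int(make_roi([v, v]).bins[0])
        assert (b - 1) * 0.5 <= v < b * 0.5 or v == (b - 1) * 0.5


class TestSuvStats:
    def test_hand_arithmetic(self):
        stats = suv_stats(make_roi([2, 4, 6], spacing=(4.0, 4.0, 4.0)))
        assert stats == {
            "suv_max": 6.0,
            "suv_mean": 4.0,
            "mtv_ml": pytest.approx(0.192),
            "tlg": pytest.approx(0.768),
        }

    def test_scaling_law(self):
        a = suv_stats(make_roi([1.0, 2.0, 3.0]))
        b = suv_stats(make_roi([2.0, 4.0, 6.0]))
        assert b["suv_max"] == 2 * a["suv_max"]
        assert b["tlg"] == pytest.approx(2 * a["tlg"])
        assert b["mtv_ml"] == a["mtv_ml"]


class TestHistogram:
    def test_energy_on_three_bin_distribution(self):
        # bins {a,a,b,c}: P = {1/2, 1/4, 1/4} -> sum of squares = 0.375
        h = histogram_features(make_roi([0.1, 0.2, 0.6, 1.1]))
        assert h["hist_energy"] == pytest.approx(0.375)

    def test_single_bin_energy_one_entropy_zero(self):
        h = extract_all(
            PETVolume(np.full((1, 1, 4), 0.2), (1, 1, 1)),
            BinaryMask(np.ones((1, 1, 4), np.uint8), (1, 1, 1)),
        )
        assert h["hist_energy"] == 1.0
        assert h["hist_entropy"] == 0.0

    def test_kurtosis_of_symmetric_two_point_distribution(self):
        # {1,1,2,2}: fourth moment / variance^2 = 0.0625 / 0.0625 = 1
        h = histogram_features(make_roi([1.0, 1.0, 2.0, 2.0]))
        assert h["hist_kurtosis"] == pytest.approx(1.0)
        assert h["hist_skewness"] == pytest.approx(0.0)

    def test_gaussian_kurtosis_limit(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(100_000) + 10.0  # shift keeps SUV >= 0
        h = histogram_features(make_roi(draws))
        assert abs(h["hist_kurtosis"] - 3.0) < 0.1

    def test_constant_roi_degenerate_for_shape_moments(self):
        with pytest.raises(DegenerateInputError):
            histogram_features(make_roi([2.0, 2.0, 2.0]))

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25)
    def test_distribution_sums_to_one_and_energy_bounds(self, seed):
        vol, mask = random_roi(np.random.default_rng(seed))
        roi = discretise(vol, mask)
        levels, p = histogram_distribution(roi)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        energy = float(np.sum(p**2))
        assert 1.0 / levels.size <= energy <= 1.0


class TestGLCM:
    def test_constant_roi_all_mass_on_diagonal(self):
        g = glcm_features(make_roi([1.0, 1.0, 1.0]))
        assert g["glcm_homogeneity"] == 1.0
        assert g["glcm_dissimilarity"] == 0.0

    def test_two_voxel_pair(self):
        g = glcm_features(make_roi([0.2, 0.7]))
        assert g == {
            "glcm_homogeneity": pytest.approx(0.5),
            "glcm_entropy": pytest.approx(1.0),
            "glcm_dissimilarity": pytest.approx(1.0),
        }

    def test_isolated_voxels_degenerate(self):
        vol = PETVolume(np.ones((3, 3, 3)), (1, 1, 1))
        mask = np.zeros((3, 3, 3), np.uint8)
        mask[0, 0, 0] = 1  # single voxel: no neighbour pair
        with pytest.raises(DegenerateInputError):
            glcm_features(discretise(vol, BinaryMask(mask, (1, 1, 1))))

    def test_matrix_is_symmetric_probability(self):
        from petprog.features import glcm_matrix

        vol, mask = random_roi(np.random.default_rng(42))
        _, p = glcm_matrix(discretise(vol, mask))
        assert p.sum() == pytest.approx(1.0)
        assert np.allclose(p, p.T)


class TestOracleEquivalence:
    """The vectorised texture matrices must agree with naive enumerators."""

    def _assert_matches(self, vol, mask):
        roi = discretise(vol, mask)
        g = glcm_features(roi)
        z = glszm_features(roi)
        bg, bm = roi.bin_grid, roi.mask
        for k, v in brute_glcm_features(bg, bm).items():
            assert g[k] == pytest.approx(v, abs=1e-12), k
        for k, v in brute_glszm_features(bg, bm).items():
            assert z[k] == pytest.approx(v, abs=1e-12), k
        expected = brute_coarseness(bg, bm)
        assert ngtdm_coarseness(roi) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize(
        "shape", [(2, 1, 1), (2, 2, 1), (3, 2, 1), (2, 2, 2), (3, 2, 2)]
    )
    def test_exhaustive_two_bin_patterns(self, shape):
        n = int(np.prod(shape))
        for pattern in itertools.product([0.2, 0.7], repeat=n):
            arr = np.array(pattern).reshape(shape)
            vol = PETVolume(arr, (1, 1, 1))
            mask = BinaryMask(np.ones(shape, np.uint8), (1, 1, 1))
            roi = discretise(vol, mask)
            if len(set(pattern)) > 1:
                self._assert_matches(vol, mask)
            else:
                assert glszm_features(roi)["glszm_zone_percentage"] == 1 / n

    def test_random_rois_up_to_5cubed(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 40:
            vol, mask = random_roi(rng)
            if mask.n_foreground < 2:
                continue
            try:
                self._assert_matches(vol, mask)
            except DegenerateInputError:
                continue
            checked += 1


class TestExtractAll:
    def test_tlg_identity_on_noiseless_phantom(self, noiseless_phantom):
        fv = extract_all(*noiseless_phantom)
        assert fv["tlg"] == pytest.approx(fv["suv_mean"] * fv["mtv_ml"], rel=1e-15)
        assert fv["suv_max"] == fv["suv_mean"] == 8.0  # constant tumour

    def test_invariant_ranges(self, noisy_phantom):
        fv = extract_all(*noisy_phantom)
        assert fv["tlg"] == pytest.approx(fv["suv_mean"] * fv["mtv_ml"], rel=1e-15)
        assert 0 < fv["hist_energy"] <= 1
        assert fv["hist_entropy"] >= 0
        assert fv["hist_kurtosis"] >= 1
        assert 0 < fv["glszm_zone_percentage"] <= 1
        assert 0 < fv["glcm_homogeneity"] <= 1

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        block = rng.uniform(0.5, 4.0, size=(3, 3, 3))
        grid_a, grid_b = np.zeros((8, 8, 8)), np.zeros((8, 8, 8))
        mask_a, mask_b = np.zeros((8, 8, 8), np.uint8), np.zeros((8, 8, 8), np.uint8)
        grid_a[0:3, 0:3, 0:3] = block
        mask_a[0:3, 0:3, 0:3] = 1
        grid_b[4:7, 3:6, 2:5] = block
        mask_b[4:7, 3:6, 2:5] = 1
        fa = extract_all(PETVolume(grid_a, (2, 2, 2)), BinaryMask(mask_a, (2, 2, 2)))
        fb = extract_all(PETVolume(grid_b, (2, 2, 2)), BinaryMask(mask_b, (2, 2, 2)))
        for k in fa.values:
            assert fa[k] == pytest.approx(fb[k], rel=1e-12), k

    def test_axis_permutation_invariance_isotropic(self):
        rng = np.random.default_rng(8)
        arr = rng.uniform(0.5, 4.0, size=(4, 4, 4))
        mask = (rng.random((4, 4, 4)) < 0.8).astype(np.uint8)
        mask[1, 1, 1] = 1
        fa = extract_all(PETVolume(arr, (2, 2, 2)), BinaryMask(mask, (2, 2, 2)))
        fb = extract_all(
            PETVolume(arr.transpose(2, 0, 1), (2, 2, 2)),
            BinaryMask(mask.transpose(2, 0, 1), (2, 2, 2)),
        )
        for k in fa.values:
            assert fa[k] == pytest.approx(fb[k], rel=1e-12), k

    def test_determinism_of_seeded_phantom_features(self):
        spec = PhantomSpec(noise_sd=0.3, heterogeneity_sd=0.6, seed=11)
        fa = extract_all(*generate_phantom(spec))
        fb = extract_all(*generate_phantom(spec))
        for k in fa.values:
            assert abs(fa[k] - fb[k]) < 1e-10

    def test_degenerate_metrics_flagged_not_silent(self):
        vol = PETVolume(np.full((2, 2, 2), 3.0), (1, 1, 1))
        mask = BinaryMask(np.ones((2, 2, 2), np.uint8), (1, 1, 1))
        fv = extract_all(vol, mask)
        assert np.isnan(fv["hist_kurtosis"]) and "hist_kurtosis" in fv.missing
        assert fv["hist_energy"] == 1.0  # still defined for a constant ROI
        assert fv["ngtdm_coarseness"] == pytest.approx(1e6)
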