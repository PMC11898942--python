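"""Radiomic features against brute-force oracles and invariances."""

import numpy as np
import pytest

from mmdiscover import (
    CohortSpec,
    DiscretizationConfig,
    RoiMask,
    VolumetricImage,
    discretize,
    extract_feature_vector,
    feature_registry,
    gen_lesion_volume,
)
from mmdiscover.radiomics import (
    DIRECTIONS_13,
    LAWS_NAMES,
    glcm_features,
    glcm_matrices,
    glrlm_lglre,
    glrlm_runs,
    glszm_counts,
    glszm_features,
    intensity_stats,
    laws_energy,
    morphology,
    mvee,
    ellipsoid_volume,
    wavelet_energies,
)

import oracles


def full_mask(shape):
    return RoiMask(np.ones(shape, dtype=bool))


def img(arr, spacing=(1.0, 1.0, 1.0)):
    return VolumetricImage(np.asarray(arr, dtype=float), spacing)


# ---------------------------------------------------------------------- disc

class TestDiscretize:
    def test_constant_image_maps_to_level_one(self):
        d = discretize(img(np.full((4, 4, 4), 7.0)), full_mask((4, 4, 4)),
                       DiscretizationConfig(8))
        assert set(d.ravel()) == {1}

    def test_integer_ramp_identity(self):
        arr = np.arange(32, dtype=float).reshape(2, 4, 4)
        d = discretize(img(arr), full_mask((2, 4, 4)), DiscretizationConfig(32))
        assert np.array_equal(d.ravel(), np.arange(1, 33))

    def test_uniform_occupancy_quarters(self, rng):
        arr = rng.random((12, 12, 12))
        d = discretize(img(arr), full_mask((12, 12, 12)), DiscretizationConfig(4))
        occ = np.bincount(d.ravel(), minlength=5)[1:] / arr.size
        assert np.allclose(occ, 0.25, atol=0.03)

    def test_bounds_and_extremes(self, rng):
        arr = rng.normal(size=(6, 6, 6))
        mask = full_mask((6, 6, 6))
        d = discretize(img(arr), mask, DiscretizationConfig(16))
        assert d.min() == 1 and d.max() == 16
        assert d[np.unravel_index(arr.argmin(), arr.shape)] == 1
        assert d[np.unravel_index(arr.argmax(), arr.shape)] == 16


# ---------------------------------------------------------------------- GLCM

class TestGLCM:
    def test_constant_roi(self):
        d = np.ones((3, 3, 3), dtype=np.int32)
        f = glcm_features(d, np.ones((3, 3, 3), bool), 4)
        assert f["joint_max"] == 1.0
        assert f["difference_entropy"] == 0.0

    def test_single_voxel_mask_errors(self):
        d = np.ones((3, 3, 3), dtype=np.int32)
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        with pytest.raises(ValueError):
            glcm_features(d, m, 4)

    def test_matches_pair_enumeration_oracle(self, rng):
        disc = rng.integers(1, 5, size=(5, 6, 4)).astype(np.int32)
        mask = rng.random((5, 6, 4)) > 0.25
        mask[2, 2, 2] = True
        mats = glcm_matrices(disc, mask, 4)
        oracle_mats = [
            oracles.glcm_matrix_oracle(disc, mask, d, 4) for d in DIRECTIONS_13
        ]
        oracle_mats = [m for m in oracle_mats if m is not None]
        assert len(mats) == len(oracle_mats)
        for a, b in zip(mats, oracle_mats):
            np.testing.assert_allclose(a, b, atol=1e-12)
        fo = [oracles.glcm_features_oracle(m) for m in oracle_mats]
        f = glcm_features(disc, mask, 4)
        for key in f:
            np.testing.assert_allclose(f[key], np.mean([x[key] for x in fo]),
                                       rtol=1e-12)

    def test_checkerboard_autocorrelation_axis_aligned(self):
        z, y, x = np.indices((4, 4, 4))
        disc = (1 + (z + y + x) % 2).astype(np.int32)
        mask = np.ones((4, 4, 4), bool)
        mats = glcm_matrices(disc, mask, 2)
        for d, m in zip(DIRECTIONS_13, mats):
            if sum(abs(c) for c in d) == 1:  # axis-aligned distance 1
                idx = np.arange(1, 3)
                autocorr = (m * np.outer(idx, idx)).sum()
                assert autocorr == pytest.approx(2.0)


# --------------------------------------------------------------------- GLSZM

class TestGLSZM:
    def test_uniform_roi_single_zone(self):
        d = np.ones((3, 3, 3), dtype=np.int32)
        f = glszm_features(d, np.ones((3, 3, 3), bool))
        assert f["high_grey_level_zone_emphasis"] == 1.0
        assert f["small_zone_high_grey_level_emphasis"] == pytest.approx(1 / 27**2)

    def test_two_single_voxel_zones(self):
        d = np.zeros((3, 3, 3), dtype=np.int32)
        m = np.zeros((3, 3, 3), bool)
        d[0, 0, 0], m[0, 0, 0] = 1, True
        d[2, 2, 2], m[2, 2, 2] = 4, True
        f = glszm_features(d, m)
        # two zones of size 1 at levels 1 and 4
        assert f["small_zone_high_grey_level_emphasis"] == pytest.approx((1 + 16) / 2)
        assert f["high_grey_level_zone_emphasis"] == pytest.approx((1 + 16) / 2)

    def test_matches_bfs_oracle(self, rng):
        disc = rng.integers(1, 4, size=(6, 5, 5)).astype(np.int32)
        mask = rng.random((6, 5, 5)) > 0.3
        mask[0, 0, 0] = True
        assert glszm_counts(disc, mask) == oracles.glszm_counts_oracle(disc, mask)

    def test_level_relabeling_preserves_zone_count(self, rng):
        disc = rng.integers(1, 5, size=(5, 5, 5)).astype(np.int32)
        mask = np.ones((5, 5, 5), bool)
        flipped = (5 - disc).astype(np.int32)
        a = glszm_counts(disc, mask)
        b = glszm_counts(flipped, mask)
        assert sum(a.values()) == sum(b.values())


# --------------------------------------------------------------------- GLRLM

class TestGLRLM:
    def test_all_level_one(self):
        d = np.ones((3, 3, 3), dtype=np.int32)
        assert glrlm_lglre(d, np.ones((3, 3, 3), bool)) == 1.0

    def test_all_level_four(self):
        d = np.full((3, 3, 3), 4, dtype=np.int32)
        assert glrlm_lglre(d, np.ones((3, 3, 3), bool)) == pytest.approx(1 / 16)

    def test_line_pattern_matches_oracle(self):
        d = np.ones((1, 1, 4), dtype=np.int32)
        d[0, 0, 2:] = 2
        m = np.ones((1, 1, 4), bool)
        for direction in DIRECTIONS_13:
            assert glrlm_runs(d, m, direction) == oracles.glrlm_runs_oracle(
                d, m, direction
            )

    def test_random_volume_matches_oracle(self, rng):
        d = rng.integers(1, 4, size=(4, 5, 4)).astype(np.int32)
        m = rng.random((4, 5, 4)) > 0.3
        m[1, 1, 1] = True
        impl = [glrlm_runs(d, m, dd) for dd in DIRECTIONS_13]
        orc = [
            {k: v for k, v in oracles.glrlm_runs_oracle(d, m, dd).items()}
            for dd in DIRECTIONS_13
        ]
        assert impl == orc
        lglre = glrlm_lglre(d, m)
        assert lglre == pytest.approx(np.mean([oracles.lglre_oracle(r) for r in orc]))


# ---------------------------------------------------------------------- Laws

class TestLaws:
    def test_zero_sum_kernels_kill_constant_image(self):
        image = img(np.full((7, 7, 7), 3.0))
        mask = full_mask((7, 7, 7))
        for trip in (("E5", "S5", "W5"), ("L5", "E5", "S5"), ("R5", "L5", "L5")):
            assert laws_energy(image, mask, trip) == pytest.approx(0.0, abs=1e-9)

    def test_l5_cubed_on_constant(self):
        image = img(np.full((7, 7, 7), 2.0))
        assert laws_energy(image, full_mask((7, 7, 7)), ("L5", "L5", "L5")) == (
            pytest.approx(2.0 * 16**3)
        )

    def test_separable_equals_direct_convolution(self, rng):
        arr = rng.normal(size=(7, 7, 7))
        image = img(arr)
        mask = full_mask((7, 7, 7))
        from mmdiscover.radiomics import LAWS_KERNELS

        for trip in (("L5", "E5", "S5"), ("W5", "R5", "E5")):
            direct = oracles.conv3d_oracle(arr, [LAWS_KERNELS[k] for k in trip])
            assert laws_energy(image, mask, trip) == pytest.approx(
                np.abs(direct).mean(), rel=1e-10
            )


# ------------------------------------------------------------------- wavelet

class TestWavelets:
    def test_constant_image_zero_detail_energy(self):
        image = img(np.full((8, 8, 8), 5.0))
        e = wavelet_energies(image, full_mask((8, 8, 8)), levels=2)
        for name, v in e.items():
            if not name.endswith("_C8"):  # C8 = deepest approximation
                assert v == pytest.approx(0.0, abs=1e-18)

    def test_parseval_on_impulse(self):
        arr = np.zeros((8, 8, 8))
        arr[3, 4, 2] = 2.0
        import pywt

        coeffs = pywt.wavedecn(arr, "haar", mode="periodization", level=2)
        total = (coeffs[0] ** 2).sum() + sum(
            (band**2).sum() for d in coeffs[1:] for band in d.values()
        )
        assert total == pytest.approx((arr**2).sum())

    def test_level1_bands_match_filter_bank_oracle(self, rng):
        arr = rng.normal(size=(8, 8, 8))
        import pywt

        coeffs = pywt.wavedecn(arr, "haar", mode="periodization", level=1)
        bands = oracles.haar_level1_oracle(arr)
        np.testing.assert_allclose(coeffs[0], bands["aaa"], atol=1e-10)
        for key, arr_band in coeffs[1].items():
            np.testing.assert_allclose(arr_band, bands[key], atol=1e-10)

    def test_too_small_roi_errors(self):
        image = img(np.zeros((8, 8, 8)))
        m = np.zeros((8, 8, 8), bool)
        m[:2, :8, :8] = True
        with pytest.raises(ValueError):
            wavelet_energies(image, RoiMask(m), levels=2)


# ------------------------------------------------------------ intensity stats

class TestIntensityStats:
    CFG = DiscretizationConfig(8)

    def test_constant_image(self):
        f = intensity_stats(img(np.full((4, 4, 4), 3.0)), full_mask((4, 4, 4)), self.CFG)
        assert f["cov"] == 0.0
        assert f["volume_at_intensity_fraction_10"] == 1.0

    def test_cov_hand_value(self):
        arr = np.zeros((1, 1, 3))
        arr[0, 0] = [1.0, 2.0, 3.0]
        f = intensity_stats(img(arr), full_mask((1, 1, 3)), self.CFG)
        assert f["cov"] == pytest.approx(0.5)

    def test_volume_fraction_uniform(self, rng):
        arr = rng.random((12, 12, 12))
        f = intensity_stats(img(arr), full_mask((12, 12, 12)), self.CFG)
        assert f["volume_at_intensity_fraction_10"] == pytest.approx(0.9, abs=0.02)

    def test_zero_mean_errors(self):
        arr = np.zeros((2, 2, 2))
        arr[0, 0, 0], arr[0, 0, 1] = -1.0, 1.0
        with pytest.raises(ValueError):
            intensity_stats(img(arr), full_mask((2, 2, 2)), self.CFG)


# ---------------------------------------------------------------- morphology

class TestMorphology:
    def test_cube_density_is_cube_to_ball_ratio(self):
        m = np.zeros((10, 10, 10), bool)
        m[1:9, 1:9, 1:9] = True
        f = morphology(RoiMask(m), img(np.ones((10, 10, 10))), (1.0, 1.0, 1.0))
        # MVEE of a cube is its circumscribed ball: density = 2/(pi*sqrt(3))
        assert f["mvee_volume_density"] == pytest.approx(2 / (np.pi * np.sqrt(3)),
                                                         rel=2e-3)

    def test_khachiyan_oracle_on_cube_corners(self):
        pts = np.array(list(np.ndindex(2, 2, 2)), dtype=float)
        _, a = mvee(pts, tol=1e-9)
        ball = 4 / 3 * np.pi * (np.sqrt(3) / 2) ** 3
        assert ellipsoid_volume(a) == pytest.approx(ball, rel=1e-3)

    def test_ellipsoidal_mask_density_approaches_one_with_resolution(self):
        # voxelization biases the density downward (mask undercounts the
        # ellipsoid, corner points inflate the MVEE); the bias shrinks as
        # the same shape is sampled at higher resolution
        densities = []
        for n, radii in ((12, (5, 4, 3)), (24, (10, 8, 6))):
            z, y, x = np.indices((n, n, n))
            c = (n - 1) / 2
            m = (
                ((z - c) / radii[0]) ** 2
                + ((y - c) / radii[1]) ** 2
                + ((x - c) / radii[2]) ** 2
                <= 1.0
            )
            f = morphology(RoiMask(m), img(np.ones((n, n, n))), (1.0, 1.0, 1.0))
            densities.append(f["mvee_volume_density"])
        assert densities[0] < densities[1] <= 1.001
        assert densities[1] > 0.7

    def test_symmetric_uniform_com_is_center(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        f = morphology(RoiMask(m), img(np.ones((9, 9, 9))), (2.0, 1.0, 0.5))
        assert f["weighted_com_x_mm"] == pytest.approx(4 * 2.0)
        assert f["weighted_com_y_mm"] == pytest.approx(4 * 1.0)
        assert f["weighted_com_z_mm"] == pytest.approx(4 * 0.5)


# ------------------------------------------------------------------ full panel

class TestFeatureVector:
    def test_deterministic_and_registry_complete(self):
        spec = CohortSpec(seed=3)
        image, mask = gen_lesion_volume(spec, "significant", 0)
        a = extract_feature_vector(image, mask)
        b = extract_feature_vector(image, mask)
        assert a == b
        assert list(a) == feature_registry()
        assert all(np.isfinite(v) for v in a.values())
        assert a["avgCoocurrence_Difference_entropy"] >= 0
        assert 0 < a["Avg_Coocurrence_Joint_MAX"] <= 1
        assert 0 < a["Volume_density_minimum_volume_enclosing_ellipsoid"] <= 1.001
        assert 0 < a["avg_3D_LGRE_(Low_grey_level_run_emphasis)"] <= 1

    def test_intensity_rescaling_leaves_discretized_texture_unchanged(self):
        spec = CohortSpec(seed=4)
        image, mask = gen_lesion_volume(spec, "indolent", 1)
        scaled = VolumetricImage(3.5 * image.voxels + 40.0, image.spacing_mm)
        a = extract_feature_vector(image, mask)
        b = extract_feature_vector(scaled, mask)
        texture = [
            "Avg_Coocurrence_Joint_MAX",
            "Avg_Coocurrence_Autocorrelation",
            "avgCoocurrence_Difference_entropy",
            "GLSZM_Small_zone_high_grey_level_emphasis",
            "GLSZM_High_grey_level_zone_emphasis",
            "avg_3D_LGRE_(Low_grey_level_run_emphasis)",
            "Maximum_histogram_gradient_grey_level",
        ]
        for name in texture:
            assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_translation_shifts_only_weighted_com(self):
        spec = CohortSpec(seed=5, image_shape=(20, 20, 20))
        image, mask = gen_lesion_volume(spec, "significant", 2)
        shift = (2, 1, 3)
        vox = np.roll(image.voxels, shift, axis=(0, 1, 2))
        mvox = np.roll(mask.voxels, shift, axis=(0, 1, 2))
        a = extract_feature_vector(image, mask)
        b = extract_feature_vector(
            VolumetricImage(vox, image.spacing_mm), RoiMask(mvox)
        )
        for name in feature_registry():
            if name.startswith("Weighted_CoM"):
                continue
            assert a[name] == pytest.approx(b[name], rel=1e-8), name
        assert b["Weighted_CoM_x_(mm)"] - a["Weighted_CoM_x_(mm)"] == pytest.approx(2.0)
        assert b["Weighted_CoM_y_(mm)"] - a["Weighted_CoM_y_(mm)"] == pytest.approx(1.0)
        assert b["Weighted_CoM_z_(mm)"] - a["Weighted_CoM_z_(mm)"] == pytest.approx(3.0)
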