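import numpy as np
import pytest

from voxelfs.features import (
    DIRECTIONS,
    MASK_SIZES,
    ORIENTATIONS,
    PLANES,
    diagonal_gradients,
    extract_roi_matrix,
    extract_voxel_vector,
    feature_groups,
    feature_names,
    feature_specs,
    glcm,
    haar_features,
    haralick_stats,
    position_feature,
    principal_moments,
    quantize,
)

# ---------------------------------------------------------------------------
# descriptor structure
# ---------------------------------------------------------------------------


class TestDescriptorStructure:
    def test_total_and_group_counts(self):
        specs = feature_specs()
        assert len(specs) == 315
        groups = feature_groups()
        assert len(groups["position"]) == 1
        assert len(groups["grey"]) == 1
        assert len(groups["haralick"]) == 4 * 66
        assert len(groups["haar"]) == 49

    def test_haralick_group_decomposition(self):
        specs = feature_specs()
        for m in MASK_SIZES:
            block = [s for s in specs if s.group == "haralick" and s.params.get("mask_size") == m]
            assert len(block) == 66
            assert sum(s.subgroup == "gradient" for s in block) == 13
            assert sum(s.subgroup == "moment" for s in block) == 5
            tex = [s for s in block if s.subgroup == "texstat"]
            assert len(tex) == 3 * 16
            for plane in PLANES:
                assert sum(s.params["plane"] == plane for s in tex) == 16

    def test_indices_are_a_bijection(self):
        specs = feature_specs()
        assert [s.index for s in specs] == list(range(315))
        assert len(set(feature_names())) == 315

    def test_thirteen_directions_cover_26_neighbourhood(self):
        dirs = {d for _, d in DIRECTIONS}
        with_opposites = dirs | {tuple(-c for c in d) for d in dirs}
        assert len(dirs) == 13
        assert len(with_opposites) == 26


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


class TestQuantize:
    def test_binary_split(self):
        np.testing.assert_array_equal(quantize([0, 0.49, 0.51, 1.0], 2), [0, 0, 1, 1])

    def test_constant_patch(self):
        assert set(np.unique(quantize(np.full((4, 4), 0.3), 8))) == {2}

    def test_uniform_ramp_near_equal_occupancy(self):
        lv = quantize(np.linspace(0, 1, 800), 8)
        counts = np.bincount(lv, minlength=8)
        assert counts.min() >= 99 and counts.max() <= 101

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            quantize([0.5, 1.2], 8)


# ---------------------------------------------------------------------------
# GLCM and Haralick statistics
# ---------------------------------------------------------------------------


def _brute_force_glcm(patch, orientation, levels):
    """Oracle: enumerate every ordered pair position explicitly."""
    offs = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = offs[orientation]
    h, w = patch.shape
    counts = np.zeros((levels, levels))
    for i in range(h):
        for j in range(w):
            ii, jj = i + dr, j + dc
            if 0 <= ii < h and 0 <= jj < w:
                counts[patch[i, j], patch[ii, jj]] += 1
    sym = counts + counts.T
    return sym / sym.sum()


class TestGLCM:
    def test_worked_binary_example(self):
        patch = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]])
        g = glcm(patch, 0, levels=2)
        np.testing.assert_allclose(g.matrix, np.array([[2, 2], [2, 6]]) / 12.0)

    def test_constant_patch_single_cell(self):
        g = glcm(np.full((4, 4), 3), 45, levels=8)
        assert g.matrix[3, 3] == 1.0
        assert g.matrix.sum() == 1.0

    @pytest.mark.parametrize("orientation", ORIENTATIONS)
    def test_matches_brute_force_on_random_patches(self, orientation):
        rng = np.random.default_rng(42)
        for _ in range(50):  # 50 patches x 4 orientations = 200 oracle checks
            m = int(rng.choice([3, 5, 7, 9]))
            levels = int(rng.choice([2, 4, 8]))
            patch = rng.integers(0, levels, size=(m, m))
            got = glcm(patch, orientation, levels).matrix
            np.testing.assert_array_equal(got, _brute_force_glcm(patch, orientation, levels))
            np.testing.assert_array_equal(got, got.T)  # symmetrization

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            glcm(np.array([[0], [1]]), 0, levels=2)


class TestHaralickStats:
    def test_single_cell_degenerate(self):
        p = np.zeros((8, 8))
        p[2, 2] = 1.0
        energy, contrast, corr, idm = haralick_stats(p)
        assert (energy, contrast, corr, idm) == (1.0, 0.0, 0.0, 1.0)

    def test_worked_example_energy_and_contrast(self):
        p = np.array([[2, 2], [2, 6]]) / 12.0
        energy, contrast, _, _ = haralick_stats(p)
        assert energy == pytest.approx(1 / 3)
        assert contrast == pytest.approx(1 / 3)

    def test_uniform_matrix_zero_correlation(self):
        p = np.full((6, 6), 1 / 36)
        assert haralick_stats(p)[2] == pytest.approx(0.0, abs=1e-12)

    def test_ranges_on_random_glcms(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            patch = rng.integers(0, 8, size=(7, 7))
            energy, contrast, corr, idm = haralick_stats(glcm(patch, 90, 8))
            assert 0 < energy <= 1
            assert 0 < idm <= 1
            assert contrast >= 0
            assert -1 - 1e-12 <= corr <= 1 + 1e-12


# ---------------------------------------------------------------------------
# gradients, moments, Haar, position
# ---------------------------------------------------------------------------


class TestDiagonalGradients:
    def test_constant_volume_all_zero(self):
        np.testing.assert_array_equal(
            diagonal_gradients(np.full((9, 9, 9), 0.4), (4, 4, 4), 5), np.zeros(13)
        )

    def test_x_ramp(self):
        vol = np.tile(np.arange(11.0)[:, None, None], (1, 11, 11))
        grads = diagonal_gradients(vol, (5, 5, 5), 5)  # r = 2
        by_label = dict(zip([lab for lab, _ in DIRECTIONS], grads))
        for (lab, d), g in zip(DIRECTIONS, grads):
            assert g == pytest.approx(4.0 * d[0]), lab
        assert by_label["OP"] == 0.0  # pure-y direction

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(1)
        vol = rng.random((9, 9, 9))
        v = (4, 4, 4)
        np.testing.assert_allclose(
            diagonal_gradients(-vol, v, 7), -diagonal_gradients(vol, v, 7)
        )


class TestPrincipalMoments:
    def test_constant_cube(self):
        out = principal_moments(np.full((7, 7, 7), 0.6), (3, 3, 3), 3)
        np.testing.assert_allclose(out, [0.6, 0, 0, 0, 0])

    def test_symmetric_values_zero_skew(self):
        vol = np.tile(np.arange(9.0)[:, None, None], (1, 9, 9))  # cube values symmetric
        out = principal_moments(vol, (4, 4, 4), 3)
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_moment_formulas(self):
        rng = np.random.default_rng(2)
        vol = rng.random((9, 9, 9))
        got = principal_moments(vol, (4, 4, 4), 3)
        cube = vol[3:6, 3:6, 3:6].ravel()
        mu = cube.mean()
        sd = cube.std()
        expect = [
            mu,
            sd**2,
            ((cube - mu) ** 3).mean() / sd**3,
            ((cube - mu) ** 4).mean() / sd**4 - 3,
            ((cube - mu) ** 5).mean() / sd**5,
        ]
        np.testing.assert_allclose(got, expect)


class TestHaar:
    def test_uniform_volume_all_zero(self):
        out = haar_features(np.full((13, 13, 13), 0.7), (6, 6, 6))
        np.testing.assert_allclose(out, np.zeros(49), atol=1e-12)

    def test_step_volume_sign_pattern(self):
        vol = np.tile((np.arange(13) >= 6).astype(float)[:, None, None], (1, 13, 13))
        out = haar_features(vol, (6, 6, 6))
        from voxelfs.features import haar_feature_names

        by_name = dict(zip(haar_feature_names(), out))
        for m in (5, 7, 9):
            assert by_name[f"haar_t1_MN_m{m}"] > 0.5  # x-normal split sees the step
            assert by_name[f"haar_t1_OP_m{m}"] == pytest.approx(0.0, abs=1e-12)
            assert by_name[f"haar_t1_QR_m{m}"] == pytest.approx(0.0, abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        vol = rng.random((13, 13, 13))
        v = (6, 6, 6)
        np.testing.assert_allclose(haar_features(2.5 * vol, v), 2.5 * haar_features(vol, v))


class TestPosition:
    def test_center_is_zero(self):
        assert position_feature((5, 5, 5), (11, 11, 11)) == 0.0

    def test_corner_is_one(self):
        assert position_feature((0, 0, 0), (11, 11, 11)) == pytest.approx(1.0)
        assert position_feature((10, 10, 10), (11, 11, 11)) == pytest.approx(1.0)

    def test_face_midpoint_closed_form(self):
        # midpoint of the x=0 face of a cube: distance 5 along x, half-diag 5*sqrt(3)
        got = position_feature((0, 5, 5), (11, 11, 11))
        assert got == pytest.approx(5 / (5 * np.sqrt(3)))


# ---------------------------------------------------------------------------
# full vectors and the ROI matrix
# ---------------------------------------------------------------------------


class TestVoxelVector:
    def test_length_and_group_slices(self):
        rng = np.random.default_rng(4)
        vec = extract_voxel_vector(rng.random((12, 12, 12)), (6, 6, 6))
        assert vec.shape == (315,)
        assert np.isfinite(vec).all()

    def test_constant_volume_degenerate_values(self):
        vec = extract_voxel_vector(np.full((12, 12, 12), 0.5), (6, 6, 6))
        specs = feature_specs()
        for s in specs:
            if s.subgroup == "gradient" or s.group == "haar":
                assert vec[s.index] == pytest.approx(0.0, abs=1e-12), s.name
            elif s.subgroup == "texstat" and s.params["statistic"] in ("energy", "idm"):
                assert vec[s.index] == 1.0, s.name
            elif s.subgroup == "texstat" and s.params["statistic"] in ("contrast", "corr"):
                assert vec[s.index] == 0.0, s.name


class TestRoiMatrix:
    def test_rows_labels_and_determinism(self, small_roi):
        X, y = extract_roi_matrix(small_roi)
        assert X.shape == (small_roi.intensities.size, 315)
        assert y.sum() == small_roi.mask.sum()
        X2, _ = extract_roi_matrix(small_roi)
        assert X.tobytes() == X2.tobytes()

    def test_matches_per_voxel_reference(self, small_roi):
        from voxelfs.features import quantize as q

        X, _ = extract_roi_matrix(small_roi)
        lv = q(small_roi.intensities, 8)
        rng = np.random.default_rng(5)
        shape = small_roi.intensities.shape
        for flat in rng.integers(0, X.shape[0], size=8):
            voxel = np.unravel_index(flat, shape)
            ref = extract_voxel_vector(small_roi.intensities, voxel, level_map=lv)
            np.testing.assert_allclose(X[flat], ref, atol=1e-8)

    def test_translation_covariance_of_non_position_features(self):
        rng = np.random.default_rng(6)
        base = rng.random((17, 16, 16))
        shifted = np.roll(base, 1, axis=0)
        # voxel far enough from every border that no window is clamped
        v = (8, 8, 8)
        v_shift = (9, 8, 8)
        a = extract_voxel_vector(base, v)
        b = extract_voxel_vector(shifted, v_shift)
        np.testing.assert_allclose(a[1:], b[1:], atol=1e-8)

    def test_unnormalized_volume_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            extract_roi_matrix(np.random.default_rng(0).random((6, 6, 6)) * 10)
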