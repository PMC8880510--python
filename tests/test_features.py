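"""Radiomic feature extraction vs brute-force enumeration oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from oracles import brute_glcm, brute_glrlm, brute_glszm, brute_ring, brute_sre
from radenrich.features import (
    ExtractionConfig,
    MANDATORY_FEATURES,
    all_feature_names,
    discretize,
    extract_all,
    first_order,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    glszm,
    glszm_features,
    peritumoral_features,
    peritumoral_ring,
    shape,
)
from radenrich.features.discretize import DiscretizedVolume
from radenrich.simulate import generate_lesion_image
from radenrich.volumes import LabeledVolume


def _dvol(levels, mask=None):
    levels = np.asarray(levels, dtype=np.int32)
    mask = np.ones(levels.shape, bool) if mask is None else mask
    return DiscretizedVolume(
        levels=np.where(mask, levels, 0),
        mask=mask,
        n_levels=int(levels[mask].max()),
        bin_edges=np.array([0.0, 1.0]),
        spacing=(1.0, 1.0, 1.0),
    )


class TestDiscretize:
    def test_constant_region_single_level(self):
        vol = LabeledVolume(np.full((4, 4, 4), 7.0), np.ones((4, 4, 4), bool), (1, 1, 1))
        d = discretize(vol, 32)
        assert d.n_levels == 1
        assert np.all(d.masked_levels() == 1)

    def test_two_values_partition_at_midpoint(self):
        img = np.zeros((2, 2, 2))
        img[1] = 10.0
        vol = LabeledVolume(img, np.ones((2, 2, 2), bool), (1, 1, 1))
        d = discretize(vol, 2)
        assert set(d.masked_levels()) == {1, 2}
        assert np.all(d.levels[1] == 2)

    def test_uniform_noise_fills_levels_uniformly(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (22, 22, 22))  # ~10^4 voxels
        vol = LabeledVolume(img, np.ones(img.shape, bool), (1, 1, 1))
        d = discretize(vol, 32)
        counts = np.bincount(d.masked_levels(), minlength=33)[1:]
        assert sps.chisquare(counts).pvalue > 0.01

    def test_requires_two_bins(self, random_volume):
        with pytest.raises(ValueError):
            discretize(random_volume(), n_bins=1)


class TestTextureMatricesAgainstOracles:
    @pytest.mark.parametrize("seed", range(25))
    def test_matrix_counts_equal_brute_force(self, seed, random_volume):
        vol = random_volume(seed=seed)
        d = discretize(vol, 4)
        R, Z, C = glrlm(d), glszm(d), glcm(d)
        Rb = brute_glrlm(d.levels, d.mask, d.n_levels)
        Zb = brute_glszm(d.levels, d.mask, d.n_levels)
        Cb = brute_glcm(d.levels, d.mask, d.n_levels)
        assert np.array_equal(R[:, : Rb.shape[1]], Rb)
        assert R[:, Rb.shape[1]:].sum() == 0
        assert np.array_equal(Z[:, : Zb.shape[1]], Zb)
        assert np.array_equal(C, Cb)

    def test_run_matrix_accounts_for_every_voxel_13_times(self, random_volume):
        vol = random_volume(seed=99, shape=(6, 5, 7))
        d = discretize(vol, 5)
        R = glrlm(d)
        j = np.arange(1, R.shape[1] + 1)
        assert (R * j).sum() == 13 * d.mask.sum()

    def test_alternating_line_runs_all_length_one(self):
        # 1x1xN line with alternating levels: the only in-grid direction
        # is the line axis and every run breaks immediately
        lev = (np.indices((1, 1, 8))[2] % 2 + 1).astype(np.int32)
        d = _dvol(lev)
        R = glrlm(d)
        assert R[:, 1:].sum() == 0
        assert R[:, 0].sum() == 13 * 8

    def test_constant_line_single_long_run(self):
        # constant 1x1xN line: direction along the line contributes one
        # run of length N; the other 12 directions give N runs of length 1
        lev = np.ones((1, 1, 6), dtype=np.int32)
        d = _dvol(lev)
        R = glrlm(d)
        assert R[0, 5] == 1
        assert R[0, 0] == 12 * 6

    def test_rotation_consistency_under_axis_permutation(self, random_volume):
        vol = random_volume(seed=5, shape=(5, 6, 4))
        d = discretize(vol, 4)
        ref_r = glrlm_features(glrlm(d), vol.n_voxels)
        ref_c = glcm_features(glcm(d))
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            pv = LabeledVolume(
                np.transpose(vol.intensities, perm),
                np.transpose(vol.mask, perm),
                (1.0, 1.0, 1.0),
            )
            dp = discretize(pv, 4)
            fr = glrlm_features(glrlm(dp), pv.n_voxels)
            fc = glcm_features(glcm(dp))
            for k in ref_r:
                assert fr[k] == pytest.approx(ref_r[k], rel=1e-12)
            for k in ref_c:
                assert fc[k] == pytest.approx(ref_c[k], rel=1e-12)


class TestRunLengthStatistics:
    def test_sre_is_one_iff_all_runs_length_one(self):
        R = np.zeros((3, 5))
        R[:, 0] = [4, 7, 2]
        f = glrlm_features(R, n_voxels=13)
        assert f["short_run_emphasis"] == pytest.approx(1.0)

    @pytest.mark.parametrize("L", [2, 3, 7])
    def test_single_run_closed_form(self, L):
        R = np.zeros((2, L))
        R[0, L - 1] = 1
        f = glrlm_features(R, n_voxels=L)
        assert f["short_run_emphasis"] == pytest.approx(1.0 / L**2)

    def test_sre_bounds(self, random_volume):
        for seed in range(5):
            vol = random_volume(seed=seed, shape=(5, 5, 5))
            d = discretize(vol, 4)
            R = glrlm(d)
            sre = glrlm_features(R, vol.n_voxels)["short_run_emphasis"]
            l_max = max(vol.mask.shape)
            assert 1 / l_max**2 <= sre <= 1.0

    def test_statistics_match_brute_force_definition(self, random_volume):
        vol = random_volume(seed=31, shape=(5, 5, 5))
        d = discretize(vol, 4)
        R = glrlm(d)
        assert glrlm_features(R, vol.n_voxels)["short_run_emphasis"] == pytest.approx(
            brute_sre(R)
        )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            glrlm_features(np.zeros((2, 2)), 4)
        with pytest.raises(ValueError):
            glszm_features(np.zeros((2, 2)), 4)


class TestFirstOrderAndShape:
    def test_volume_of_unit_cube_block(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[1:11, 1:11, 1:11] = True
        vol = LabeledVolume(np.zeros((12, 12, 12)), mask, (1, 1, 1))
        assert shape(vol)["volume_ml"] == pytest.approx(1.0)

    def test_anisotropic_spacing_uses_true_voxel_volume(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        vol = LabeledVolume(np.zeros((6, 6, 6)), mask, (1.0, 2.0, 2.5))
        assert shape(vol)["volume_ml"] == pytest.approx(64 * 5.0 / 1000)

    def test_constant_image_degenerate_statistics(self):
        vol = LabeledVolume(np.full((4, 4, 4), 3.0), np.ones((4, 4, 4), bool), (1, 1, 1))
        f = first_order(vol)
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["skewness"] == 0.0

    def test_sphere_more_spherical_than_slab(self):
        grid = np.indices((20, 20, 20)).astype(float)
        r2 = sum((grid[k] - 9.5) ** 2 for k in range(3))
        sphere = LabeledVolume(np.zeros((20, 20, 20)), r2 <= 49, (1, 1, 1))
        slab_mask = np.zeros((20, 20, 20), bool)
        slab_mask[9:11, 1:19, 1:19] = True
        slab = LabeledVolume(np.zeros((20, 20, 20)), slab_mask, (1, 1, 1))
        assert shape(sphere)["sphericity"] > shape(slab)["sphericity"]


class TestPeritumoral:
    def test_ring_disjoint_from_mask_and_matches_distance_oracle(self):
        grid = np.indices((14, 14, 14)).astype(float)
        r2 = sum((grid[k] - 6.5) ** 2 for k in range(3))
        mask = r2 <= 9
        spacing = (1.0, 1.0, 1.0)
        ring = peritumoral_ring(mask, spacing, 2.0)
        assert not (ring & mask).any()
        assert np.array_equal(ring, brute_ring(mask, spacing, 2.0))

    def test_constant_background_gives_zero_variance(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[3:5, 3:5, 3:5] = True
        img = np.where(mask, 50.0, 10.0)
        vol = LabeledVolume(img, mask, (1, 1, 1))
        ring = peritumoral_ring(mask, vol.spacing, 1.5)
        f = peritumoral_features(vol, ring)
        assert f["peri_variance"] == 0.0

    def test_mask_filling_grid_has_no_ring(self):
        with pytest.raises(ValueError):
            peritumoral_ring(np.ones((4, 4, 4), bool), (1, 1, 1), 2.0)


class TestExtractAll:
    def test_registry_covers_mandatory_names_and_sixty_features(self, random_volume):
        vol = random_volume(seed=2, shape=(10, 10, 10), mask_p=0.95)
        fv = extract_all(vol)
        assert len(fv.values) >= 60
        for name in MANDATORY_FEATURES:
            assert name in fv.values
        assert list(fv.values) == all_feature_names()

    def test_deterministic(self, random_volume):
        vol = random_volume(seed=3, shape=(8, 8, 8))
        a = extract_all(vol).values
        b = extract_all(vol).values
        assert a == b

    def test_single_voxel_mask_texture_errors_shape_defined(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        vol = LabeledVolume(np.random.default_rng(0).normal(size=(5, 5, 5)), mask, (1, 1, 1))
        with pytest.raises(ValueError):
            extract_all(vol)
        fv = extract_all(vol, ExtractionConfig(classes=["shape", "statistical"]))
        assert fv["volume_ml"] == pytest.approx(1e-3)


class TestLesionGenerator:
    def test_same_seed_reproduces_volume(self):
        a = generate_lesion_image(2.0, size=12, seed=5)
        b = generate_lesion_image(2.0, size=12, seed=5)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.mask, b.mask)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_lesion_image(0.0, size=12)
        with pytest.raises(ValueError):
            generate_lesion_image(1.0, size=4)

    def test_finer_texture_scale_raises_short_run_emphasis(self):
        def sre(scale, seed):
            vol = generate_lesion_image(scale, size=20, seed=seed)
            d = discretize(vol, 16)
            return glrlm_features(glrlm(d), vol.n_voxels)["short_run_emphasis"]

        fine = np.mean([sre(1.0, s) for s in range(6)])
        coarse = np.mean([sre(8.0, s) for s in range(6)])
        assert fine > coarse

    def test_texture_scale_sre_monotone_spearman(self):
        rng = np.random.default_rng(4)
        scales = rng.uniform(0.8, 8.0, 50)
        sres = []
        for i, sc in enumerate(scales):
            vol = generate_lesion_image(float(sc), size=24, seed=100 + i)
            d = discretize(vol, 32)
            sres.append(glrlm_features(glrlm(d), vol.n_voxels)["short_run_emphasis"])
        rho, p = sps.spearmanr(scales, sres)
        assert rho < 0
        assert p < 0.01
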