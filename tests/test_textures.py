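"""Texture stack: PC1, quantization, GLCM, run lengths, aggregation."""

import numpy as np
import pytest

from canopylai.containers import ReflectanceCube
from canopylai.textures import (ADVANCED_NAMES, RUNLENGTH_NAMES,
                                SIMPLE_NAMES, TEXTURE_NAMES, GLCMatrix,
                                PrincipalComponentImage, glcm_window,
                                glrlm_window, haralick_advanced,
                                haralick_simple, pca_first_component,
                                quantize, runlength_features,
                                texture_feature_maps,
                                texture_feature_table, window_features)
from oracles import (glcm_features_oracle, glrlm_oracle,
                     runlength_features_oracle)


def _random_glcm(rng, G=4):
    c = rng.random((G, G))
    c = c + c.T
    return GLCMatrix(c / c.sum(), G)


class TestPCA:
    def test_rank_one_cube_fully_explained(self, rng):
        base = rng.random(6)
        scale = rng.random((4, 5))
        cube = ReflectanceCube(scale[:, :, None] * base[None, None, :],
                               450 + 4.0 * np.arange(6))
        pc1 = pca_first_component(cube)
        assert pc1.explained_variance_ratio == pytest.approx(1.0, abs=1e-9)

    def test_two_band_toy_matches_closed_form(self):
        """3 pixels, 2 bands: eigendecomposition of the 2x2 covariance
        by hand."""
        vals = np.array([[[0.1, 0.2], [0.3, 0.6], [0.5, 1.0]]])
        cube = ReflectanceCube(vals, np.array([450.0, 454.0]))
        pc1 = pca_first_component(cube)
        X = vals.reshape(3, 2)
        cov = np.cov(X.T)
        evals, evecs = np.linalg.eigh(cov)
        assert pc1.explained_variance_ratio == \
            pytest.approx(evals[-1] / evals.sum(), abs=1e-12)
        v = evecs[:, -1]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        assert np.allclose(np.abs(pc1.loading), np.abs(v), atol=1e-12)
        scores = (X - X.mean(0)) @ v
        assert np.allclose(pc1.values.ravel(), scores, atol=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA
        vals = rng.random((6, 7, 10))
        cube = ReflectanceCube(vals, 450 + 4.0 * np.arange(10))
        pc1 = pca_first_component(cube)
        ref = PCA(n_components=3).fit(vals.reshape(-1, 10))
        assert pc1.explained_variance_ratio == \
            pytest.approx(ref.explained_variance_ratio_[0], abs=1e-9)
        assert np.allclose(np.abs(pc1.values.ravel()),
                           np.abs(ref.transform(vals.reshape(-1, 10))[:, 0]),
                           atol=1e-9)

    def test_degenerate_cube_rejected(self):
        cube = ReflectanceCube(np.full((3, 3, 4), 0.5),
                               450 + 4.0 * np.arange(4))
        with pytest.raises(ValueError):
            pca_first_component(cube)


class TestQuantize:
    def test_constant_maps_to_zero(self):
        assert (quantize(np.full((6, 6), 3.3), 32) == 0).all()

    def test_ramp_equal_bands(self):
        img = np.linspace(0, 1, 400).reshape(20, 20)
        q = quantize(img, 4, stretch=(0.0, 100.0))
        counts = np.bincount(q.ravel(), minlength=4)
        assert counts.min() >= 95  # four near-equal-width bands

    def test_range_clipped(self, rng):
        q = quantize(rng.normal(size=(30, 30)), 8)
        assert q.min() >= 0 and q.max() <= 7

    def test_masked_pixels_flagged(self):
        img = np.ones((3, 3))
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False
        q = quantize(img, 8, mask=mask)
        assert q[0, 0] == -1


class TestGLCM:
    def test_constant_window_single_cell(self):
        m = glcm_window(np.zeros((5, 5), int), 4)
        assert m.p[0, 0] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_checkerboard_diagonal_concentration(self):
        """Along 45 degrees a 2-level checkerboard pairs equal levels,
        so all mass sits on the diagonal."""
        q = np.indices((5, 5)).sum(axis=0) % 2
        m = glcm_window(q, 2)
        assert m.p[0, 0] + m.p[1, 1] == pytest.approx(1.0)
        assert m.p[0, 1] == pytest.approx(0.0)

    def test_probabilities_sum_to_one_and_symmetric(self, rng):
        for _ in range(25):
            m = glcm_window(rng.integers(0, 6, (5, 5)), 6)
            assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(m.p, m.p.T, atol=1e-12)

    def test_matches_skimage(self, rng):
        """skimage's graycomatrix is the independent reference for the
        pair counting. skimage measures angles with the row axis
        pointing down, so its 3*pi/4 equals the up-right (-1, +1)
        offset used here."""
        from skimage.feature import graycomatrix
        for _ in range(20):
            q = rng.integers(0, 5, (5, 5))
            ours = glcm_window(q, 5)
            ref = graycomatrix(q.astype(np.uint8), [1], [3 * np.pi / 4],
                               levels=5, symmetric=True, normed=True)
            assert np.allclose(ours.p, ref[:, :, 0, 0], atol=1e-12)

    def test_masked_window_rejected(self):
        q = np.zeros((5, 5), int)
        q[2, 2] = -1
        with pytest.raises(ValueError):
            glcm_window(q, 4)


class TestHaralickFeatures:
    def test_single_cell_concentration(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        m = GLCMatrix(p, 4)
        s = haralick_simple(m)
        assert s["energy"] == pytest.approx(1.0)
        assert s["entropy"] == pytest.approx(0.0)
        assert s["inertia"] == pytest.approx(0.0)
        assert s["inverse_difference_moment"] == pytest.approx(1.0)
        a = haralick_advanced(m)
        assert a["mean"] == pytest.approx(2.0)
        assert a["variance"] == pytest.approx(0.0)
        assert a["dissimilarity"] == pytest.approx(0.0)

    def test_uniform_two_level_closed_form(self):
        m = GLCMatrix(np.full((2, 2), 0.25), 2)
        s = haralick_simple(m)
        assert s["energy"] == pytest.approx(0.25)
        assert s["entropy"] == pytest.approx(np.log(4))

    def test_symmetric_mean_equals_marginal_means(self, rng):
        m = _random_glcm(rng)
        a = haralick_advanced(m)
        lev = np.arange(m.levels)
        assert a["mean"] == pytest.approx(float(lev @ m.p.sum(1)), abs=1e-12)
        assert a["mean"] == pytest.approx(float(lev @ m.p.sum(0)), abs=1e-12)

    def test_all_18_match_brute_force(self, rng):
        """Simple + advanced statistics against the double-loop oracle
        on random GLCMs."""
        for _ in range(120):
            m = _random_glcm(rng, G=4)
            expected = glcm_features_oracle(m.p)
            got = {**haralick_simple(m), **haralick_advanced(m)}
            for name in SIMPLE_NAMES + ADVANCED_NAMES:
                assert got[name] == pytest.approx(expected[name],
                                                  abs=1e-9), name

    def test_invariant_ranges(self, rng):
        for _ in range(50):
            m = _random_glcm(rng, G=5)
            s = haralick_simple(m)
            a = haralick_advanced(m)
            assert 0 < s["energy"] <= 1
            assert s["entropy"] >= 0
            assert 0 < s["inverse_difference_moment"] <= 1
            assert s["inertia"] >= 0
            assert 0 <= a["ic2"] <= 1


class TestRunLength:
    def test_constant_window_diagonal_runs(self):
        rlm = glrlm_window(np.zeros((5, 5), int), 4)
        assert rlm.n_runs == 9          # diagonal lengths 1,2,3,4,5,4,3,2,1
        feats = runlength_features(rlm)
        assert feats["run_percentage"] == pytest.approx(9 / 25)
        assert feats["grey_level_nonuniformity"] == pytest.approx(9.0)

    def test_alternating_window_all_unit_runs(self):
        q = np.indices((5, 5))[1] % 2   # alternates along every diagonal
        rlm = glrlm_window(q, 2)
        assert rlm.n_runs == 25
        feats = runlength_features(rlm)
        assert feats["short_run_emphasis"] == pytest.approx(1.0)
        assert feats["long_run_emphasis"] == pytest.approx(1.0)

    def test_pixel_conservation(self, rng):
        for _ in range(100):
            q = rng.integers(0, 4, (5, 5))
            rlm = glrlm_window(q, 4)
            lengths = np.arange(1, rlm.r.shape[1] + 1)
            assert (rlm.r * lengths).sum() == 25

    def test_matrix_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            q = rng.integers(0, 3, (5, 5))
            ours = glrlm_window(q, 3)
            ref = glrlm_oracle(q)
            assert np.array_equal(ours.r[:ref.shape[0]], ref)

    def test_all_10_match_brute_force(self, rng):
        for _ in range(120):
            q = rng.integers(0, 5, (5, 5))
            rlm = glrlm_window(q, 5)
            expected = runlength_features_oracle(rlm.r, 25)
            got = runlength_features(rlm)
            for name in RUNLENGTH_NAMES:
                assert got[name] == pytest.approx(expected[name],
                                                  abs=1e-9), name

    def test_empty_matrix_rejected(self):
        from canopylai.textures import RunLengthMatrix
        with pytest.raises(ValueError):
            runlength_features(RunLengthMatrix(np.zeros((3, 5), int), 3, 25))


class TestSlidingWindowPath:
    def test_fast_path_matches_reference(self, rng):
        """The vectorized whole-scene extractor reproduces the
        per-window reference functions everywhere."""
        img = rng.random((11, 13))
        pc1 = PrincipalComponentImage(img, 1.0, np.ones(img.shape, bool))
        maps = texture_feature_maps(pc1, G=6)
        q = quantize(img, 6)
        for r, c in [(2, 2), (4, 9), (8, 10), (5, 5), (7, 3)]:
            ref = window_features(q[r - 2:r + 3, c - 2:c + 3], 6)
            for name in TEXTURE_NAMES:
                assert maps[name][r, c] == pytest.approx(ref[name],
                                                         abs=1e-9), name

    def test_masked_windows_skipped(self, rng):
        img = rng.random((9, 12))
        mask = np.ones((9, 12), bool)
        mask[4, 4] = False
        pc1 = PrincipalComponentImage(img, 1.0, mask)
        maps = texture_feature_maps(pc1, G=4)
        # every window covering (4,4) is NaN; windows clear of it are not
        assert np.isnan(maps["energy"][2:7, 2:7]).all()
        assert np.isfinite(maps["energy"][2, 9])


class TestTextureTable:
    def test_default_shape(self, default_layout, default_cubes):
        pc1 = pca_first_component(default_cubes["BBCH41"])
        tab = texture_feature_table(pc1, default_layout, "BBCH41")
        assert tab.data.shape == (48, 28)
        assert set(tab.families.values()) == {"TEX"}

    def test_constant_image_degenerate_features(self, default_layout):
        from canopylai.synth import PIXEL_SIZE, SCENE_H_PX, SCENE_W_PX
        pc1 = PrincipalComponentImage(
            np.zeros((SCENE_H_PX, SCENE_W_PX)), 1.0,
            np.ones((SCENE_H_PX, SCENE_W_PX), bool), pixel_size=PIXEL_SIZE)
        tab = texture_feature_table(pc1, default_layout[:4], "BBCH41")
        assert np.allclose(tab.data["energy"], 1.0)
        assert np.allclose(tab.data["entropy"], 0.0)

    def test_plot_average_equals_window_mean(self, rng):
        """On a toy scene the plot aggregate equals the mean over its
        explicitly enumerated windows."""
        from shapely.geometry import box

        from canopylai.synth import PlotLayout
        img = rng.random((12, 12))
        pc1 = PrincipalComponentImage(img, 1.0, np.ones((12, 12), bool))
        maps = texture_feature_maps(pc1, G=4)
        plot = PlotLayout(1, "Z3", 72000, 225.0, 495.0, 1,
                          box(2, 2, 10, 10))
        tab = texture_feature_table(pc1, [plot], "BBCH41", G=4, maps=maps)
        q = quantize(img, 4)
        vals = [window_features(q[r - 2:r + 3, c - 2:c + 3], 4)["inertia"]
                for r in range(2, 10) for c in range(2, 10)]
        assert tab.data["inertia"].iloc[0] == pytest.approx(np.mean(vals),
                                                            abs=1e-9)

    def test_roughness_drives_texture(self, default_layout):
        """At fixed canopy LAI, plot-mean inertia and entropy track the
        generator's per-plot roughness parameter monotonically
        (|Spearman| >= 0.8 over 20 plots)."""
        from scipy.stats import spearmanr

        from canopylai.synth import (DISC_AREA_TOTAL, GroundTruthLAI,
                                     simulate_cube)
        lai = 1.5
        truth = []
        for p in default_layout:
            sm = DISC_AREA_TOTAL * p.plants_per_m2
            truth.append(GroundTruthLAI(
                p.plot_id, "BBCH41", 1.5, 1.5 * (3 * lai / sm - 1),
                DISC_AREA_TOTAL, p.plants_per_m2, lai,
                replicate=p.replicate))
        cube = simulate_cube(default_layout, truth, "BBCH41", 0,
                             k_ext_sd=0.0, noise_sigma=0.0,
                             roughness_noise=0.4, soil_brightness_sd=0.0,
                             chlorophyll_sd=0.0, nir_sd=0.0,
                             illumination_sd=0.0)
        pc1 = pca_first_component(cube)
        tab = texture_feature_table(pc1, default_layout[:20], "BBCH41")
        rough = [cube.meta["roughness"][p.plot_id]
                 for p in default_layout[:20]]
        for name in ("inertia", "entropy"):
            rho = spearmanr(rough, tab.data[name]).statistic
            assert abs(rho) >= 0.8, name
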