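"""PCA, quantization, co-occurrence matrices and Haralick statistics.

The per-pixel fast path is checked against a naive pairwise-counting oracle
implemented independently here.
"""

import numpy as np
import pytest

from chlorotex.errors import DataError, RankError
from chlorotex.hsi_io import HyperspectralCube
from chlorotex.texture_features import (DEFAULT_OFFSETS, FEATURE_NAMES,
                                        GLCMMatrix, glcm_window,
                                        haralick_features, pca_transform,
                                        quantize, texture_feature_images,
                                        texture_images)


def naive_window_features(gray, r0, c0, levels, half=1,
                          offsets=DEFAULT_OFFSETS):
    """Independent oracle: explicit pair counting + direct formula sums."""
    P = np.zeros((levels, levels))
    rows, cols = gray.shape
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            r, c = r0 + dr, c0 + dc
            if not (0 <= r < rows and 0 <= c < cols) or gray[r, c] < 0:
                continue
            for orr, occ in offsets:
                r2, c2 = r + orr, c + occ
                if not (r0 - half <= r2 <= r0 + half
                        and c0 - half <= c2 <= c0 + half):
                    continue
                if not (0 <= r2 < rows and 0 <= c2 < cols) or gray[r2, c2] < 0:
                    continue
                P[gray[r, c], gray[r2, c2]] += 1
                P[gray[r2, c2], gray[r, c]] += 1
    if P.sum() == 0:
        return None
    return haralick_features(GLCMMatrix(P / P.sum(), levels))


class TestPCA:
    def test_rank_one_cube_first_ratio_one(self):
        shape = np.linspace(0.2, 0.8, 6)
        bright = np.random.default_rng(0).uniform(0.5, 1.5, size=(10, 10))
        cube = HyperspectralCube(
            (bright[:, :, None] * shape).astype(np.float32),
            np.linspace(400, 900, 6))
        pca = pca_transform(cube, np.ones((10, 10), bool))
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self, scene_features):
        L = scene_features["pca"].loadings
        np.testing.assert_allclose(L.T @ L, np.eye(3), atol=1e-8)

    def test_ratios_normalized_and_sorted(self, scene_features):
        r = scene_features["pca"].explained_variance_ratio
        assert r.sum() == pytest.approx(1.0)
        assert np.all(np.diff(r) <= 1e-12)
        assert np.all((r >= 0) & (r <= 1))

    def test_sign_convention_peak_loading_positive(self, scene_features):
        L = scene_features["pca"].loadings
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_default_scene_top3_at_least_96_percent(self, scene_features):
        assert scene_features["pca"].cumulative_top3 >= 0.96

    def test_constant_cube_rejected(self):
        cube = HyperspectralCube(np.full((5, 5, 4), 0.5, np.float32),
                                 np.linspace(400, 900, 4))
        with pytest.raises(RankError):
            pca_transform(cube, np.ones((5, 5), bool))


class TestQuantize:
    def test_binary_binning_rule(self):
        out = quantize(np.array([[0.0, 0.5, 1.0]]), levels=2)
        assert out.tolist() == [[0, 1, 1]]

    def test_constant_image_all_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = quantize(np.full((3, 3), 2.0), levels=8)
        assert (out == 0).all()

    def test_output_range_within_levels(self):
        rng = np.random.default_rng(4)
        out = quantize(rng.normal(size=(20, 20)), levels=32)
        assert out.min() >= 0 and out.max() <= 31

    def test_masked_pixels_get_sentinel(self):
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = mask[1, 1] = True
        out = quantize(np.arange(4.0).reshape(2, 2), levels=4, mask=mask)
        assert out[0, 1] == -1 and out[1, 0] == -1


class TestGLCMWindow:
    def test_constant_window_single_cell(self):
        gray = np.full((3, 3), 5, dtype=np.int32)
        glcm = glcm_window(gray, (1, 1), levels=8)
        assert glcm.P[5, 5] == pytest.approx(1.0)
        assert glcm.P.sum() == pytest.approx(1.0)

    def test_vertical_stripes_horizontal_offset(self):
        # columns 0,1,0; the 6 horizontal pairs alternate -> p(0,1)=p(1,0)=1/2
        gray = np.array([[0, 1, 0]] * 3, dtype=np.int32)
        glcm = glcm_window(gray, (1, 1), levels=2, offsets=((0, 1),))
        assert glcm.P[0, 1] == pytest.approx(0.5)
        assert glcm.P[1, 0] == pytest.approx(0.5)

    def test_normalization_on_random_windows(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            gray = rng.integers(0, 8, size=(5, 5)).astype(np.int32)
            glcm = glcm_window(gray, (2, 2), levels=8)
            assert glcm.P.sum() == pytest.approx(1.0)
            assert np.all(glcm.P >= 0)

    def test_all_masked_window_flagged(self):
        gray = np.full((3, 3), -1, dtype=np.int32)
        with pytest.raises(DataError):
            glcm_window(gray, (1, 1), levels=4)


class TestHaralickFeatures:
    def test_constant_window_feature_values(self):
        g = 5
        gray = np.full((3, 3), g, dtype=np.int32)
        feats = haralick_features(glcm_window(gray, (1, 1), levels=8))
        assert feats["MEA"] == pytest.approx(g)
        assert feats["VAR"] == pytest.approx(0.0)
        assert feats["HOM"] == pytest.approx(1.0)
        assert feats["CON"] == pytest.approx(0.0)
        assert feats["DIS"] == pytest.approx(0.0)
        assert feats["ENT"] == pytest.approx(0.0)
        assert feats["SEC"] == pytest.approx(1.0)
        assert feats["COR"] == pytest.approx(1.0)  # zero-variance convention

    def test_two_cell_distribution_hand_computed(self):
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        feats = haralick_features(GLCMMatrix(P, 2))
        assert feats["CON"] == pytest.approx(1.0)
        assert feats["DIS"] == pytest.approx(1.0)
        assert feats["HOM"] == pytest.approx(0.5)
        assert feats["ENT"] == pytest.approx(1.0)  # one bit
        assert feats["SEC"] == pytest.approx(0.5)
        assert feats["MEA"] == pytest.approx(0.5)
        assert feats["VAR"] == pytest.approx(0.25)
        assert feats["COR"] == pytest.approx(-1.0)

    def test_uniform_distribution_second_moment(self):
        G = 4
        feats = haralick_features(GLCMMatrix(np.full((G, G), 1 / G**2), G))
        assert feats["SEC"] == pytest.approx(1 / G**2)
        assert feats["ENT"] == pytest.approx(2 * np.log2(G))

    def test_inequalities_on_random_windows(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            gray = rng.integers(0, 6, size=(3, 3)).astype(np.int32)
            f = haralick_features(glcm_window(gray, (1, 1), levels=6))
            assert f["CON"] >= f["DIS"] >= 0
            assert 0 < f["HOM"] <= 1


class TestTextureImages:
    def test_fast_path_equals_naive_oracle(self):
        rng = np.random.default_rng(3)
        gray = rng.integers(0, 8, size=(12, 15)).astype(np.int32)
        gray[rng.random(gray.shape) < 0.15] = -1  # masked patches
        images = texture_images(gray, levels=8)
        for r in range(gray.shape[0]):
            for c in range(gray.shape[1]):
                if gray[r, c] < 0:
                    assert all(np.isnan(images[n][r, c]) for n in FEATURE_NAMES)
                    continue
                oracle = naive_window_features(gray, r, c, 8)
                for name in FEATURE_NAMES:
                    assert images[name][r, c] == pytest.approx(
                        oracle[name], abs=1e-10)

    def test_constant_image_constant_mea(self):
        gray = np.zeros((6, 6), dtype=np.int32)
        images = texture_images(gray, levels=4)
        assert np.allclose(images["MEA"], 0.0)
        assert np.allclose(images["HOM"], 1.0)

    def test_24_images_across_three_pcs(self, scene_features):
        assert len(scene_features["tf_images"]) == 24
        for pc in ("PC1", "PC2", "PC3"):
            assert sum(1 for n in scene_features["tf_images"]
                       if n.startswith(pc)) == 8


def test_entropy_nondecreasing_with_gray_levels():
    """On continuous random fields, finer quantization cannot lower the mean
    window entropy (checked statistically over seeds)."""
    diffs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        img = rng.normal(size=(20, 20))
        ents = []
        for G in (4, 16):
            gray = quantize(img, levels=G)
            ents.append(np.nanmean(texture_images(gray, levels=G)["ENT"]))
        diffs.append(ents[1] - ents[0])
    assert np.mean(diffs) > 0
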