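"""Red-edge sweep, SPAD calibration chemistry, and LCC mapping."""

import numpy as np
import pandas as pd
import pytest

from chlorotex.analysis import (MultivariatePredictor, TwoPairPredictor,
                                chlorophyll_from_absorbance, fit_exponential,
                                predict_map, rededge_sweep)
from chlorotex.errors import BandLookupError, DataError
from chlorotex.spectral_features import compute_vi, roi_feature_means
from chlorotex.twopair import TwoPairResult, build_combination, fit_linear


class TestRededgeSweep:
    @pytest.fixture(scope="class")
    def sweep(self, default_scene):
        cube, truth = default_scene
        return cube, truth, rededge_sweep(cube, truth.vegetation_mask_true,
                                          truth.points_frame())

    def test_grid_covers_cube_bands_in_window(self, sweep):
        cube, _, result = sweep
        wl = cube.wavelengths
        expected = wl[(wl >= 702) & (wl <= 742)]
        np.testing.assert_allclose(result.wavelengths, expected)
        assert result.r2.shape == (9, expected.size)

    def test_identity_substitution_reproduces_unswept_r2(self, sweep):
        cube, truth, result = sweep
        mask = truth.vegetation_mask_true
        pts = truth.points_frame()
        for name in ("SR_re", "MSR_re"):
            from chlorotex.spectral_features import REGISTRY, nearest_band

            nominal = REGISTRY[name].bands["rededge"]
            idx, _ = nearest_band(cube.wavelengths, nominal)
            img = compute_vi(cube, name, mask=mask)
            table = roi_feature_means({name: img}, pts, mask, size=50)
            _, _, r2_ref, _, _ = fit_linear(table.data[name].to_numpy(),
                                            table.spad.to_numpy())
            swept = result.r2.loc[name, float(cube.wavelengths[idx])]
            assert swept == pytest.approx(r2_ref, abs=1e-12)

    def test_argmax_recovers_730nm_information_center(self, sweep):
        cube, _, result = sweep
        wl = cube.wavelengths
        nearest_730 = wl[np.argmin(np.abs(wl - 730.0))]
        band_step = wl[1] - wl[0]
        within = np.abs(result.best_band - nearest_730) <= band_step + 1e-9
        assert within.sum() > len(result.best_band) / 2  # majority of VI_re

    def test_r2_invariant_to_affine_lcc_rescaling(self, default_scene):
        cube, truth = default_scene
        pts = truth.points_frame()
        pts2 = pts.copy()
        pts2["spad"] = 2.0 * pts2["spad"] + 5.0
        mask = truth.vegetation_mask_true
        a = rededge_sweep(cube, mask, pts, vi_names=["MSR_re"])
        b = rededge_sweep(cube, mask, pts2, vi_names=["MSR_re"])
        pd.testing.assert_frame_equal(a.r2, b.r2, atol=1e-10)

    def test_empty_band_window_rejected(self, default_scene):
        cube, truth = default_scene
        with pytest.raises(BandLookupError):
            rededge_sweep(cube, truth.vegetation_mask_true,
                          truth.points_frame(), band_range=(702.2, 703.0))


class TestChlorophyllChemistry:
    def test_zero_absorbance_zero_chlorophyll(self):
        out = chlorophyll_from_absorbance(0.0, 0.0)
        assert out["total"] == 0.0

    def test_linearity_in_absorbance(self):
        a = chlorophyll_from_absorbance(0.3, 0.5)
        b = chlorophyll_from_absorbance(0.6, 1.0)
        assert b["total"] == pytest.approx(2 * a["total"])

    def test_hand_computed_coefficients(self):
        out = chlorophyll_from_absorbance(0.3, 0.5)
        assert out["chl_a"] == pytest.approx(4.911)
        assert out["chl_b"] == pytest.approx(3.828)
        assert out["total"] == pytest.approx(8.739)

    def test_inconsistent_measurements_flagged(self):
        out = chlorophyll_from_absorbance(1.0, 0.1)  # chl_a < 0
        assert bool(out["inconsistent"])

    def test_negative_absorbance_rejected(self):
        with pytest.raises(DataError):
            chlorophyll_from_absorbance(-0.1, 0.5)


class TestFitExponential:
    def test_noiseless_recovery_exact(self):
        spad = np.linspace(40, 70, 12)
        lab = 2.0 * np.exp(0.05 * spad)
        cal = fit_exponential(spad, lab)
        assert cal.a == pytest.approx(2.0, abs=1e-6)
        assert cal.b == pytest.approx(0.05, abs=1e-6)
        assert cal.r2 == pytest.approx(1.0)

    def test_noisy_recovery_within_three_se_at_n18(self):
        """18-sample lab-calibration fixture: the rate estimate stays within
        3 standard errors of truth across seeds."""
        a_true, b_true = 4.5, 0.035
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spad = rng.uniform(45, 70, 18)
            lab = a_true * np.exp(b_true * spad) * rng.lognormal(0, 0.06, 18)
            cal = fit_exponential(spad, lab)
            if abs(cal.b - b_true) <= 3 * cal.se_b:
                ok += 1
        assert ok >= 9

    def test_increasing_calibration_has_positive_rate(self):
        rng = np.random.default_rng(0)
        spad = rng.uniform(45, 70, 18)
        lab = 4.5 * np.exp(0.035 * spad) * rng.lognormal(0, 0.05, 18)
        assert fit_exponential(spad, lab).b > 0

    def test_constant_spad_rejected(self):
        with pytest.raises(DataError):
            fit_exponential(np.full(5, 50.0), np.full(5, 10.0))

    def test_nonpositive_chlorophyll_rejected(self):
        with pytest.raises(DataError):
            fit_exponential(np.arange(5.0) + 1, np.array([1, 2, 0, 4, 5.0]))


class TestPredictMap:
    def test_twopair_map_is_closed_form(self):
        rng = np.random.default_rng(1)
        vi = rng.uniform(0.2, 0.8, size=(10, 12))
        tf = rng.uniform(1.0, 3.0, size=(10, 12))
        mask = rng.random((10, 12)) > 0.3
        res = TwoPairResult("SR", "VIa", "TFa", "PC1",
                            slope=4.4, intercept=52.4, r2=0.8, rmse=2.0,
                            n_used=74)
        lcc, sd = predict_map(TwoPairPredictor(res),
                              {"VIa": vi, "TFa": tf}, mask)
        expected = 4.4 * build_combination(vi, tf, "SR") + 52.4
        np.testing.assert_allclose(lcc[mask], expected[mask], atol=1e-12)
        assert np.isnan(lcc[~mask]).all()
        assert sd is None

    def test_constant_features_give_constant_map(self):
        mask = np.ones((5, 5), bool)
        res = TwoPairResult("DVI", "v", "t", "PC1", slope=2.0, intercept=50.0,
                            r2=1.0, rmse=0.0, n_used=10)
        lcc, _ = predict_map(TwoPairPredictor(res),
                             {"v": np.full((5, 5), 0.6),
                              "t": np.full((5, 5), 0.1)}, mask)
        np.testing.assert_allclose(lcc, 2.0 * 0.5 + 50.0)

    def test_missing_feature_image_named_in_error(self):
        res = TwoPairResult("SR", "VIa", "TFa", "PC1", 1, 0, 0.5, 2.0, 10)
        with pytest.raises(Exception, match="TFa"):
            predict_map(TwoPairPredictor(res), {"VIa": np.ones((3, 3))},
                        np.ones((3, 3), bool))

    def test_mapped_roi_means_consistent_with_cv_skill(self, scene_features,
                                                       vi_tf_groups):
        """ROI-averaged mapped LCC must track point SPAD about as well as
        the model's cross-validated skill (internal consistency)."""
        from chlorotex.mlra import evaluate

        table = scene_features["table"]
        _, g_both = vi_tf_groups
        cv = evaluate("GPR", g_both, table, k=10, seed=1, n_restarts=2)
        predictor = MultivariatePredictor("GPR", table, g_both.members,
                                          seed=1, n_restarts=2)
        images = {**scene_features["vi_images"], **scene_features["tf_images"]}
        mask = scene_features["mask"]
        lcc_map, sd_map = predict_map(predictor, images, mask, with_sd=True)
        assert np.isnan(lcc_map[~mask]).all()
        assert np.nanmin(sd_map) >= 0
        truth = scene_features["truth"]
        roi = roi_feature_means({"lcc": lcc_map}, truth.points_frame(),
                                mask, size=50)
        r2_map = np.corrcoef(roi.data["lcc"], roi.spad)[0, 1] ** 2
        assert r2_map >= cv.r2 - 0.05
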