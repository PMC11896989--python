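"""Two-pair VI x TF combination search and its linear fits."""

import numpy as np
import pandas as pd
import pytest

from chlorotex.errors import DataError
from chlorotex.twopair import (best_combination, build_combination,
                               exhaustive_search, fit_linear, r2_grid,
                               results_frame)


class TestBuildCombination:
    def test_ratio_form(self):
        assert build_combination(2.0, 4.0, "SR") == pytest.approx(2.0)

    def test_normalized_difference_symmetry(self):
        assert build_combination(0.7, 0.7, "NDVI") == pytest.approx(0.0)

    def test_plain_difference(self):
        assert build_combination(0.9, 0.2, "DVI") == pytest.approx(0.7)

    def test_zero_denominators_flagged(self):
        assert np.isnan(build_combination(0.0, 1.0, "SR"))
        assert np.isnan(build_combination(0.5, -0.5, "NDVI"))

    def test_unknown_type_rejected(self):
        with pytest.raises(DataError):
            build_combination(1.0, 1.0, "LOG")


class TestFitLinear:
    def test_exact_linear_relationship(self):
        combo = np.array([1.0, 2.0, 3.0])
        slope, intercept, r2, rmse, n = fit_linear(combo, 2 * combo)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert n == 3

    def test_matches_normal_equation_oracle(self):
        x = np.array([0.2, 1.1, 1.9, 3.2, 4.0])
        y = np.array([50.0, 53.0, 52.5, 58.0, 61.0])
        slope, intercept, r2, rmse, _ = fit_linear(x, y)
        # closed-form normal equations, computed independently
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.inv(A.T @ A) @ A.T @ y
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)
        resid = y - A @ beta
        assert r2 == pytest.approx(1 - resid @ resid / ((y - y.mean()) ** 2).sum(),
                                   abs=1e-10)
        assert rmse == pytest.approx(np.sqrt(resid @ resid / x.size), abs=1e-10)

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, np.nan, 3.0, 4.0])
        y = np.array([2.0, 5.0, 6.0, 8.0])
        *_, n = fit_linear(x, y)
        assert n == 3

    def test_constant_combo_rejected(self):
        with pytest.raises(DataError):
            fit_linear(np.ones(5), np.arange(5.0))


@pytest.fixture()
def small_tables():
    rng = np.random.default_rng(8)
    n = 30
    lcc = rng.uniform(45, 70, n)
    vis = pd.DataFrame({
        "VIa": 0.02 * lcc + rng.normal(0, 0.05, n),
        "VIb": rng.normal(1.0, 0.2, n),
    })
    tfs = pd.DataFrame({
        "TFa": 0.1 * lcc + rng.normal(0, 0.3, n),
        "TFb": rng.normal(5.0, 1.0, n),
    })
    return vis, tfs, lcc


class TestExhaustiveSearch:
    def test_full_grid_size(self, small_tables):
        vis, tfs, lcc = small_tables
        results = exhaustive_search(vis, tfs, lcc)
        assert len(results) == 2 * 2 * 3  # every (vi, tf, type)

    def test_single_pair_gives_three_results(self, small_tables):
        vis, tfs, lcc = small_tables
        results = exhaustive_search(vis[["VIa"]], tfs[["TFa"]], lcc)
        assert sorted(r.type for r in results) == ["DVI", "NDVI", "SR"]

    def test_160_combinations_per_type_with_full_registries(self, scene_features):
        table = scene_features["table"]
        prov = table.provenance
        vis = table.data[[n for n, p in prov.items() if p == "VI"]]
        tfs = table.data[[n for n, p in prov.items() if p == "TF-PC1"]]
        results = exhaustive_search(vis, tfs, table.spad.to_numpy())
        frame = results_frame(results)
        counts = frame.groupby("type").size()
        assert (counts == 160).all()  # 20 VIs x 8 TFs
        grid = r2_grid(results, "SR", "PC1")
        assert grid.shape == (20, 8)
        assert not grid.isna().any().any()

    def test_r2_recomputed_independently_agrees(self, small_tables):
        vis, tfs, lcc = small_tables
        results = exhaustive_search(vis, tfs, lcc)
        for res in results:
            combo = build_combination(vis[res.vi_name].to_numpy(),
                                      tfs[res.tf_name].to_numpy(), res.type)
            keep = np.isfinite(combo)
            r = np.corrcoef(combo[keep], lcc[keep])[0, 1]
            assert res.r2 == pytest.approx(r**2, abs=1e-10)

    def test_column_order_invariance(self, small_tables):
        vis, tfs, lcc = small_tables
        a = results_frame(exhaustive_search(vis, tfs, lcc))
        b = results_frame(exhaustive_search(vis[["VIb", "VIa"]],
                                            tfs[["TFb", "TFa"]], lcc))
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_sr_type_r2_invariant_to_tf_rescaling(self, small_tables):
        vis, tfs, lcc = small_tables
        base = {(r.vi_name, r.tf_name): r.r2
                for r in exhaustive_search(vis, tfs, lcc, types=("SR",))}
        scaled = {(r.vi_name, r.tf_name): r.r2
                  for r in exhaustive_search(vis, tfs * 3.7, lcc, types=("SR",))}
        for key in base:
            assert scaled[key] == pytest.approx(base[key], abs=1e-10)


class TestBestCombination:
    def test_single_result_is_itself(self, small_tables):
        vis, tfs, lcc = small_tables
        results = exhaustive_search(vis[["VIa"]], tfs[["TFa"]], lcc,
                                    types=("SR",))
        report = best_combination(results)
        assert report.loc[0, "combination"] == "TFa/VIa"
        assert "y = " in report.loc[0, "model"]

    def test_argmax_per_type(self, small_tables):
        vis, tfs, lcc = small_tables
        results = exhaustive_search(vis, tfs, lcc)
        report = best_combination(results).set_index("type")
        for ctype in ("SR", "NDVI", "DVI"):
            sub = [r for r in results if r.type == ctype]
            assert report.loc[f"{ctype}-type", "r2"] == pytest.approx(
                max(r.r2 for r in sub))

    def test_tie_broken_lexicographically(self):
        from chlorotex.twopair import TwoPairResult

        tie = [
            TwoPairResult("SR", "VIb", "TFa", "PC1", 1, 0, 0.9, 1.0, 10),
            TwoPairResult("SR", "VIa", "TFz", "PC1", 1, 0, 0.9, 1.0, 10),
        ]
        report = best_combination(tie)
        assert report.loc[0, "combination"] == "TFz/VIa"

    def test_informative_feature_wins_sr_type(self, small_tables):
        vis, tfs, lcc = small_tables
        results = exhaustive_search(vis, tfs, lcc, types=("SR",))
        best = best_combination(results)
        label = best.loc[0, "combination"]
        # the winning ratio must involve a constructed-informative feature
        assert ("TFa" in label) or ("VIa" in label)
        assert best.loc[0, "r2"] > 0.3
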