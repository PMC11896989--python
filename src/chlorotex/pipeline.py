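"""Stage orchestration: simulate -> segment -> features -> screen ->
twopair -> train -> sweep -> map.

Each stage writes its artifacts plus a ``<stage>.manifest.json`` recording
the resolved config hash and the SHA-256 of every output file, so a rerun
with identical config and inputs reproduces identical manifests and stages
can verify their upstream dependencies.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, feature_screening, mlra, segmentation, twopair
from .config import PipelineConfig
from .errors import DataError
from .hsi_io import (HyperspectralCube, read_cube, read_ground_points,
                     write_cube, write_ground_points)
from .spectral_features import FeatureTable, roi_feature_means, vi_images
from .synthetic_scene import generate_scene
from .texture_features import pca_transform, texture_feature_images

log = logging.getLogger("chlorotex")

STAGES = ("simulate", "segment", "features", "screen", "twopair",
          "train", "sweep", "map")

_UPSTREAM = {
    "simulate": (),
    "segment": ("simulate",),
    "features": ("segment",),
    "screen": ("features",),
    "twopair": ("features",),
    "train": ("screen",),
    "sweep": ("segment",),
    "map": ("train", "twopair"),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, cfg: PipelineConfig,
                    files: list[Path], extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "config_sha256": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    if extra:
        manifest["info"] = extra
    (out / f"{stage}.manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _require_upstream(out: Path, stage: str) -> None:
    for dep in _UPSTREAM[stage]:
        if not (out / f"{dep}.manifest.json").exists():
            raise DataError(
                f"stage '{stage}' needs the '{dep}' stage to have run "
                f"(missing {dep}.manifest.json in {out})"
            )


def _load_mask(out: Path) -> np.ndarray:
    return np.load(out / "vegetation_mask.npy")


def _load_feature_table(out: Path) -> FeatureTable:
    data = pd.read_csv(out / "features.csv", index_col="id")
    sidecar = json.loads((out / "features.sidecar.json").read_text())
    spad = data.pop("spad")
    return FeatureTable(data=data, spad=spad,
                        provenance=sidecar["provenance"])


def run_stage(name: str, cfg: PipelineConfig, out_dir: str | Path | None = None):
    """Run one pipeline stage (or ``all``) and write its manifest."""
    if name == "all":
        for stage in STAGES:
            run_stage(stage, cfg, out_dir)
        return
    if name not in STAGES:
        raise DataError(f"unknown stage '{name}'; valid: {STAGES + ('all',)}")
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _require_upstream(out, name)
    t0 = time.time()
    files = _STAGE_FUNCS[name](cfg, out)
    log.info("stage %s finished in %.1f s", name, time.time() - t0)
    cfg.to_json(out / "config.resolved.json")
    files.append(out / "config.resolved.json")
    _write_manifest(out, name, cfg, files[:-1], extra=None)


# ---------------------------------------------------------------------------
# stage bodies


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    cube, truth = generate_scene(cfg.scene)
    files = [
        write_cube(cube, out / "scene.tif"),
        write_ground_points(truth.points_frame(), out / "ground_points.csv"),
    ]
    lcc = HyperspectralCube(
        truth.lcc_map[:, :, None].astype(np.float32),
        np.array([0.0]) + 1.0,  # single pseudo-band
        np.isfinite(truth.lcc_map),
    )
    files.append(write_cube(lcc, out / "lcc_true.tif"))
    return files


def _stage_segment(cfg: PipelineConfig, out: Path) -> list[Path]:
    cube = read_cube(out / "scene.tif")
    ndvi = segmentation.compute_ndvi(cube)
    report: dict = {}
    if cfg.segmentation_threshold == "derived":
        # label samples from the NDVI extremes (pure-pixel surrogates)
        finite = ndvi[np.isfinite(ndvi)]
        lo_q, hi_q = np.quantile(finite, [0.2, 0.8])
        thr, err = segmentation.derive_threshold(
            ndvi, finite[finite >= hi_q], finite[finite <= lo_q])
        report["misclassified_labeled"] = err
    else:
        thr = float(cfg.segmentation_threshold)
    vm = segmentation.apply_mask(cube, thr)
    np.save(out / "vegetation_mask.npy", vm.mask)
    report.update({"threshold": vm.threshold_used,
                   "n_vegetation": vm.n_vegetation, "n_soil": vm.n_soil})
    (out / "threshold.json").write_text(json.dumps(report, indent=2) + "\n")
    return [out / "vegetation_mask.npy", out / "threshold.json"]


def _stage_features(cfg: PipelineConfig, out: Path) -> list[Path]:
    cube = read_cube(out / "scene.tif")
    mask = _load_mask(out)
    points = read_ground_points(out / "ground_points.csv",
                                image_shape=cube.shape[:2])
    vi_imgs, vi_sidecar = vi_images(cube, mask)
    pca = pca_transform(cube, mask)
    tf_imgs, tf_prov = texture_feature_images(
        pca, mask, levels=cfg.glcm_levels, window=cfg.glcm_window)
    images = {**vi_imgs, **tf_imgs}
    provenance = {**{n: "VI" for n in vi_imgs}, **tf_prov}
    table = roi_feature_means(images, points, mask, size=cfg.roi_size,
                              provenance=provenance)
    frame = table.data.copy()
    frame["spad"] = table.spad
    frame.to_csv(out / "features.csv")
    sidecar = {
        "provenance": provenance,
        "vi_bands": vi_sidecar,
        "n_features": len(table.feature_names),
        "n_vi": len(vi_imgs),
        "n_tf": len(tf_imgs),
        "pca_explained_variance_ratio": pca.explained_variance_ratio[:10].tolist(),
        "pca_cumulative_top3": pca.cumulative_top3,
        "dropped_points": table.dropped_points,
    }
    (out / "features.sidecar.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    log.info("features: %d VIs + %d TFs = %d columns", len(vi_imgs),
             len(tf_imgs), len(table.feature_names))
    return [out / "features.csv", out / "features.sidecar.json"]


def _stage_screen(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = _load_feature_table(out)
    result = feature_screening.select_features(
        table, r_threshold=cfg.r_threshold, mic_threshold=cfg.mic_threshold,
        mic_alpha=cfg.mic_alpha, mic_c=cfg.mic_c)
    result.table.to_csv(out / "screening.csv", index=False)
    summary = {
        "selected_by_r": result.selected_by_provenance("r"),
        "selected_by_mic": result.selected_by_provenance("mic"),
        "r_threshold": cfg.r_threshold,
        "mic_threshold": cfg.mic_threshold,
    }
    (out / "screening.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return [out / "screening.csv", out / "screening.json"]


def _stage_twopair(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = _load_feature_table(out)
    vi_cols = [n for n, p in table.provenance.items() if p == "VI"]
    all_results = []
    files = []
    for pc in ("PC1", "PC2", "PC3"):
        tf_cols = [n for n, p in table.provenance.items() if p == f"TF-{pc}"]
        if not tf_cols:
            continue
        res = twopair.exhaustive_search(
            table.data[vi_cols], table.data[tf_cols], table.spad.to_numpy(),
            pc_image=pc)
        all_results.extend(res)
        for ctype in twopair.COMBINATION_TYPES:
            grid = twopair.r2_grid(res, ctype, pc)
            if len(grid):
                png = out / f"twopair_r2_{ctype}_{pc}.png"
                twopair.plot_r2_grid(grid, png, title=f"{ctype}-type, {pc}")
                files.append(png)
    twopair.results_frame(all_results).to_csv(out / "twopair_results.csv",
                                              index=False)
    twopair.best_combination(all_results).to_csv(out / "twopair_best.csv",
                                                 index=False)
    files = [out / "twopair_results.csv", out / "twopair_best.csv"] + files
    return files


def _stage_train(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = _load_feature_table(out)
    summary = json.loads((out / "screening.json").read_text())
    groups = mlra.standard_feature_groups(
        table, selected_r=summary["selected_by_r"],
        selected_mic=summary["selected_by_mic"])
    results, preds = [], []
    for group in groups:
        if not group.members:
            continue
        for model in cfg.models:
            kwargs = {"n_restarts": cfg.gpr_restarts} if model == "GPR" else {}
            res = mlra.evaluate(model, group, table, k=cfg.cv_folds,
                                seed=cfg.cv_seed, **kwargs)
            results.append(res)
            frame = pd.DataFrame({
                "id": table.data.index, "model": model, "group": group.name,
                "measured": res.y_true, "predicted": res.y_pred,
                "sd": res.y_sd if res.y_sd is not None else np.nan,
            })
            preds.append(frame)
    mlra.results_matrix(results).to_csv(out / "cv_results.csv")
    pd.concat(preds, ignore_index=True).to_csv(out / "cv_predictions.csv",
                                               index=False)
    groups_info = [{"name": g.name, "n_features": g.n_features,
                    "members": g.members} for g in groups]
    (out / "feature_groups.json").write_text(
        json.dumps(groups_info, indent=2) + "\n")
    return [out / "cv_results.csv", out / "cv_predictions.csv",
            out / "feature_groups.json"]


def _stage_sweep(cfg: PipelineConfig, out: Path) -> list[Path]:
    cube = read_cube(out / "scene.tif")
    mask = _load_mask(out)
    points = read_ground_points(out / "ground_points.csv",
                                image_shape=cube.shape[:2])
    try:
        result = analysis.rededge_sweep(cube, mask, points,
                                        band_range=cfg.sweep_range,
                                        roi_size=cfg.roi_size)
    except DataError as exc:
        (out / "sweep.csv").write_text(f"# sweep skipped: {exc}\n")
        return [out / "sweep.csv"]
    long = result.r2.reset_index(names="vi").melt(
        id_vars="vi", var_name="wavelength_nm", value_name="r2")
    long.to_csv(out / "sweep.csv", index=False)
    result.best_band.rename("best_band_nm").to_csv(out / "sweep_best.csv")
    return [out / "sweep.csv", out / "sweep_best.csv"]


def _stage_map(cfg: PipelineConfig, out: Path) -> list[Path]:
    cube = read_cube(out / "scene.tif")
    mask = _load_mask(out)
    table = _load_feature_table(out)
    summary = json.loads((out / "screening.json").read_text())
    best = pd.read_csv(out / "twopair_results.csv").sort_values(
        ["r2", "type", "vi", "tf"], ascending=[False, True, True, True]).iloc[0]

    vi_imgs, _ = vi_images(cube, mask)
    pca = pca_transform(cube, mask)
    tf_imgs, _ = texture_feature_images(pca, mask, levels=cfg.glcm_levels,
                                        window=cfg.glcm_window)
    images = {**vi_imgs, **tf_imgs}

    # best two-pair linear map
    tp = twopair.TwoPairResult(
        type=best["type"], vi_name=best["vi"], tf_name=best["tf"],
        pc_image=best["pc"], slope=best["slope"], intercept=best["intercept"],
        r2=best["r2"], rmse=best["rmse"], n_used=int(best["n_used"]))
    lcc_tp, _ = analysis.predict_map(analysis.TwoPairPredictor(tp), images, mask)

    # GPR map from the MIC-selected (or fallback all-VI+TF) group
    sel = summary["selected_by_mic"]
    members = sel.get("VI", []) + sel.get("TF-PC1", [])
    if not members:
        members = table.feature_names
    predictor = analysis.MultivariatePredictor(
        "GPR", table, members, seed=cfg.cv_seed, n_restarts=cfg.gpr_restarts)
    lcc_gpr, sd = analysis.predict_map(predictor, images, mask, with_sd=True)

    files = []
    for name, img in (("lcc_map_twopair", lcc_tp), ("lcc_map_gpr", lcc_gpr),
                      ("lcc_map_gpr_sd", sd)):
        c = HyperspectralCube(img[:, :, None].astype(np.float32),
                              np.array([1.0]), np.isfinite(img))
        files.append(write_cube(c, out / f"{name}.tif"))
    hist = {
        "twopair": np.histogram(lcc_tp[np.isfinite(lcc_tp)], bins=20)[0].tolist(),
        "gpr": np.histogram(lcc_gpr[np.isfinite(lcc_gpr)], bins=20)[0].tolist(),
    }
    (out / "map_histograms.json").write_text(json.dumps(hist) + "\n")
    files.append(out / "map_histograms.json")
    return files


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "features": _stage_features,
    "screen": _stage_screen,
    "twopair": _stage_twopair,
    "train": _stage_train,
    "sweep": _stage_sweep,
    "map": _stage_map,
}
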