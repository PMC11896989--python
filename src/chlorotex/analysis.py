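"""Auxiliary analyses: red-edge band sweep, SPAD verification, LCC mapping.

The band sweep replaces the red-edge slot of each red-edge vegetation index
with every cube band in a 702-742 nm window, refits the linear LCC
regression and reports the R2 profile and per-index argmax band -- the tool
used to ask which red-edge wavelength is most informative for chlorophyll.

SPAD verification converts 95%-ethanol extract absorbances at 649/665 nm to
chlorophyll a+b concentrations (Wellburn-style coefficients) and fits the
increasing exponential calibration lab_chl = a*exp(b*SPAD).

LCC mapping applies either the best two-pair linear model or a trained
multivariable model per vegetation pixel; soil is nodata, and models with a
predictive variance (GPR) also yield a per-pixel uncertainty layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import BandLookupError, DataError, RegistryError
from .hsi_io import HyperspectralCube
from .spectral_features import REGISTRY, compute_vi, roi_feature_means
from .twopair import build_combination

__all__ = [
    "SweepResult",
    "SpadCalibration",
    "rededge_sweep",
    "chlorophyll_from_absorbance",
    "fit_exponential",
    "TwoPairPredictor",
    "MultivariatePredictor",
    "predict_map",
]


# ---------------------------------------------------------------------------
# Red-edge band sweep


@dataclass
class SweepResult:
    """R2 of the linear LCC fit per (red-edge VI, substituted band)."""

    r2: pd.DataFrame          # index = vi name, columns = band wavelength (nm)
    best_band: pd.Series      # per-VI argmax wavelength

    @property
    def wavelengths(self) -> np.ndarray:
        return self.r2.columns.to_numpy(dtype=float)


def rededge_sweep(
    cube: HyperspectralCube,
    mask: np.ndarray,
    points: pd.DataFrame,
    band_range: tuple[float, float] = (702.0, 742.0),
    roi_size: int = 50,
    vi_names: list[str] | None = None,
) -> SweepResult:
    """Sweep the substitutable red-edge band of every VI_re across a window.

    For each cube band center inside ``band_range`` and each red-edge index,
    the index is recomputed with that band in its red-edge slot (fixed slots
    untouched), averaged over each point's ROI, and regressed linearly
    against the point SPAD values. Returns the R2 surface and per-index
    argmax band.
    """
    from .twopair import fit_linear

    wl = cube.wavelengths
    in_range = np.where((wl >= band_range[0]) & (wl <= band_range[1]))[0]
    if in_range.size == 0:
        raise BandLookupError(
            f"no cube bands inside {band_range[0]}-{band_range[1]} nm"
        )
    if vi_names is None:
        vi_names = [n for n, d in REGISTRY.items() if d.rededge_role is not None]
    for name in vi_names:
        if REGISTRY[name].rededge_role is None:
            raise RegistryError(f"'{name}' has no substitutable red-edge band")
    y = points["spad"].to_numpy(dtype=float)
    r2 = pd.DataFrame(index=vi_names,
                      columns=[float(wl[b]) for b in in_range], dtype=float)
    for b in in_range:
        override = {"rededge": float(wl[b])}
        images = {
            name: compute_vi(cube, name, band_override=override, mask=mask)
            for name in vi_names
        }
        table = roi_feature_means(images, points, mask, size=roi_size)
        for name in vi_names:
            _, _, fit_r2, _, _ = fit_linear(table.data[name].to_numpy(),
                                            table.spad.to_numpy())
            r2.loc[name, float(wl[b])] = fit_r2
    best = r2.astype(float).idxmax(axis=1)
    return SweepResult(r2=r2.astype(float), best_band=best.astype(float))


# ---------------------------------------------------------------------------
# SPAD verification


def chlorophyll_from_absorbance(a649, a665) -> dict[str, np.ndarray]:
    """Chlorophyll a, b and total (ug/mL of 95% ethanol extract).

    Uses the 95%-ethanol coefficients:
    Ca = 13.95*A665 - 6.88*A649;  Cb = 24.96*A649 - 7.32*A665.
    Negative component concentrations are flagged as measurement
    inconsistencies but still returned.
    """
    a649 = np.asarray(a649, dtype=float)
    a665 = np.asarray(a665, dtype=float)
    if np.any(a649 < 0) or np.any(a665 < 0):
        raise DataError("absorbances must be >= 0")
    ca = 13.95 * a665 - 6.88 * a649
    cb = 24.96 * a649 - 7.32 * a665
    return {
        "chl_a": ca,
        "chl_b": cb,
        "total": ca + cb,
        "inconsistent": (ca < 0) | (cb < 0),
    }


@dataclass
class SpadCalibration:
    """Fitted exponential link lab_chl = a * exp(b * SPAD)."""

    a: float
    b: float
    r2: float
    n: int
    se_a: float
    se_b: float


def fit_exponential(spad, lcc_lab) -> SpadCalibration:
    """Nonlinear least squares of y = a*exp(b*x), log-linear initialized."""
    x = np.asarray(spad, dtype=float)
    y = np.asarray(lcc_lab, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("need two equal-length samples with n >= 3")
    if np.any(y <= 0):
        raise DataError("lab chlorophyll must be > 0 for the exponential fit")
    if np.ptp(x) == 0:
        raise DataError("constant SPAD: exponential rate unidentifiable")
    slope, intercept = np.polyfit(x, np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, pcov = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y,
                           p0=p0, maxfev=20000)
    resid = y - popt[0] * np.exp(popt[1] * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return SpadCalibration(
        a=float(popt[0]), b=float(popt[1]),
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        n=int(x.size), se_a=float(se[0]), se_b=float(se[1]),
    )


# ---------------------------------------------------------------------------
# LCC mapping


class TwoPairPredictor:
    """Closed-form per-pixel predictor from a fitted two-pair combination."""

    def __init__(self, result) -> None:
        self.result = result
        self.feature_names = [result.vi_name, result.tf_name]

    def predict(self, X: np.ndarray) -> np.ndarray:
        combo = build_combination(X[:, 0], X[:, 1], self.result.type)
        return self.result.slope * combo + self.result.intercept


class MultivariatePredictor:
    """A model family trained on the full feature table for map time."""

    def __init__(self, model_spec: str, table, members: list[str],
                 seed: int = 0, **kwargs) -> None:
        from .mlra import fit_predict

        self.feature_names = list(members)
        self._fit_predict = fit_predict
        self.model_spec = model_spec
        self._X = table.select(members).to_numpy(dtype=float)
        self._y = table.spad.to_numpy(dtype=float)
        self._seed = seed
        self._kwargs = kwargs

    def predict(self, X: np.ndarray, return_std: bool = False):
        pred, sd = self._fit_predict(self.model_spec, self._X, self._y, X,
                                     seed=self._seed, **self._kwargs)
        if return_std:
            return pred, sd
        return pred


def predict_map(
    predictor,
    feature_images: dict[str, np.ndarray],
    mask: np.ndarray,
    with_sd: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-pixel LCC map over the vegetation mask; soil is NaN (nodata).

    ``predictor`` exposes ``feature_names`` and ``predict`` (optionally with
    ``return_std``). Feature images must cover every name the model was
    trained on; pixels with non-finite features are left nodata.
    """
    missing = [n for n in predictor.feature_names if n not in feature_images]
    if missing:
        raise RegistryError(
            f"map-time features missing from training registry: {missing}"
        )
    mask = np.asarray(mask, dtype=bool)
    stack = np.stack([feature_images[n] for n in predictor.feature_names], axis=-1)
    ok = mask & np.isfinite(stack).all(axis=-1)
    X = stack[ok]
    lcc = np.full(mask.shape, np.nan)
    sd_map = None
    if with_sd:
        pred, sd = predictor.predict(X, return_std=True)
        sd_map = np.full(mask.shape, np.nan)
        sd_map[ok] = sd
    else:
        pred = predictor.predict(X)
    lcc[ok] = pred
    return lcc, sd_map
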