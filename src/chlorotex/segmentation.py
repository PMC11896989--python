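"""Vegetation/soil separation by NDVI thresholding.

The field protocol derives a per-plot NDVI cut from hand-labeled pure
vegetation and pure soil pixel samples by minimizing the misclassification
count, then classifies strictly-greater NDVI pixels as vegetation. A generic
fallback rule (NDVI in 0.3-1.0 is vegetation) is supported through a fixed
threshold of 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .hsi_io import HyperspectralCube
from .spectral_features import nearest_band

__all__ = ["VegetationMask", "compute_ndvi", "derive_threshold", "apply_mask"]

NIR_NM = 802.0
RED_NM = 682.0


@dataclass
class VegetationMask:
    """Boolean vegetation mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float
    n_vegetation: int
    n_soil: int


def compute_ndvi(cube: HyperspectralCube) -> np.ndarray:
    """NDVI image from the 802/682 nm bands: (Rnir-Rred)/(Rnir+Rred).

    Values lie in [-1, 1]; pixels where the denominator vanishes (or that
    are invalid in the cube) are NaN.
    """
    i_nir, _ = nearest_band(cube.wavelengths, NIR_NM)
    i_red, _ = nearest_band(cube.wavelengths, RED_NM)
    nir = cube.reflectance[:, :, i_nir].astype(float)
    red = cube.reflectance[:, :, i_red].astype(float)
    den = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(den != 0, (nir - red) / den, np.nan)
    ndvi = np.where(cube.valid_mask, ndvi, np.nan)
    return ndvi


def derive_threshold(
    ndvi: np.ndarray,
    veg_sample: np.ndarray,
    soil_sample: np.ndarray,
) -> tuple[float, int]:
    """Optimal NDVI cut between labeled vegetation and soil pixel samples.

    Candidate thresholds are the midpoints of consecutive distinct values of
    the pooled sorted sample (plus cuts below/above everything). The cut
    minimizing the misclassification count is returned; ties are broken
    toward the larger threshold. Classification is strict: NDVI > threshold
    is vegetation.

    Parameters are index pairs ``(rows, cols)`` or value arrays; returns
    ``(threshold, misclassification_count)``.
    """
    veg = _sample_values(ndvi, veg_sample)
    soil = _sample_values(ndvi, soil_sample)
    if veg.size == 0 or soil.size == 0:
        raise DataError("vegetation and soil samples must be non-empty")
    pooled = np.sort(np.unique(np.concatenate([veg, soil])))
    candidates = [pooled[0] - 1.0]
    candidates.extend(0.5 * (pooled[:-1] + pooled[1:]))
    candidates.append(pooled[-1] + 1.0)
    best_thr, best_err = None, None
    for thr in candidates:
        err = int(np.sum(soil > thr)) + int(np.sum(veg <= thr))
        if best_err is None or err < best_err or (err == best_err and thr > best_thr):
            best_thr, best_err = float(thr), err
    total = veg.size + soil.size
    if best_err * 2 >= total:
        warnings.warn(
            "NDVI distributions of the labeled samples are not separable; "
            "threshold returned but unreliable",
            stacklevel=2,
        )
    return best_thr, best_err


def _sample_values(ndvi: np.ndarray, sample) -> np.ndarray:
    sample = np.asarray(sample) if not isinstance(sample, tuple) else sample
    if isinstance(sample, tuple):
        vals = ndvi[sample[0], sample[1]]
    elif isinstance(sample, np.ndarray) and sample.dtype == bool:
        vals = ndvi[sample]
    else:
        vals = np.asarray(sample, dtype=float)
    return vals[np.isfinite(vals)]


def apply_mask(cube: HyperspectralCube, threshold: float) -> VegetationMask:
    """Classify pixels with NDVI strictly above ``threshold`` as vegetation.

    Pixels exactly at the threshold count as soil, following the protocol's
    "larger than" wording.
    """
    if not -1.0 <= threshold <= 1.0:
        raise DataError("NDVI threshold must lie in [-1, 1]")
    ndvi = compute_ndvi(cube)
    with np.errstate(invalid="ignore"):
        mask = (ndvi > threshold) & cube.valid_mask
    n_veg = int(mask.sum())
    n_soil = int(cube.valid_mask.sum()) - n_veg
    return VegetationMask(mask=mask, threshold_used=float(threshold),
                          n_vegetation=n_veg, n_soil=n_soil)
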