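"""Synthetic hyperspectral canopy scenes with known per-pixel chlorophyll.

The generator emulates a two-plot banana field observed by a UAV
hyperspectral camera (164 bands, 350-1000 nm): circular plant crowns on a
planting grid over bare laterite soil, and a leaf reflectance model whose
red absorption deepens and whose red-edge inflection shifts toward longer
wavelengths as leaf chlorophyll content (LCC, SPAD units) increases.

Three nuisance/information fields shape what downstream features can see:

* an *optical-expression mismatch* -- the chlorophyll the spectra express
  differs from the SPAD-measured content by a smooth field (leaf
  water/thickness/surface effects), which caps how well purely spectral
  indices can track SPAD;
* a multiplicative *brightness-level* field and a fine-scale *roughness*
  (jitter-amplitude) field, both coupled to the LCC map with correlation
  ``texture_corr`` -- crown vigor raises brightness and surface roughness,
  so image texture statistics carry chlorophyll information that ROI-mean
  spectral indices do not;
* a long-range additive ambient-light field plus per-band sensor noise.

Ground measurement points aggregate plant-crown mean LCC plus SPAD meter
noise, split 30/44 across the two plots at default size.

Every random draw comes from a single seeded ``numpy`` generator, so a
given :class:`SceneConfig` reproduces its scene bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import ConfigError, DataError, SceneConfigError
from .hsi_io import HyperspectralCube

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "leaf_reflectance",
    "red_edge_inflection",
    "generate_scene",
    "default_wavelengths",
    "spad_from_lab_chlorophyll",
    "lab_chlorophyll_from_spad",
]

#: Reference SPAD split of ground points between the two plots.
PLOT_SPLIT = (30, 44)


def default_wavelengths(n_bands: int = 164, lo: float = 350.0, hi: float = 1000.0) -> np.ndarray:
    """Uniform band-center grid, 350-1000 nm in 164 steps (~3.99 nm)."""
    return np.linspace(lo, hi, n_bands)


@dataclass
class SceneConfig:
    """Generator parameters; defaults encode the emulated study conditions.

    ``texture_corr`` sets the correlation between the multiplicative
    brightness field and the LCC field: at 0 image texture carries no
    chlorophyll information, at 1 it mirrors the LCC map.
    """

    seed: int = 42
    n_rows: int = 300
    n_cols: int = 700
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    n_points: int = 74
    lcc_range: tuple[float, float] = (45.0, 70.0)
    soil_fraction: float = 0.4
    texture_corr: float = 0.6
    noise_sd: float = 0.004
    spad_noise_sd: float = 1.2
    #: plant grid pitch; also the ROI edge length used downstream
    spacing: int = 50
    #: amplitude (relative sd) of the multiplicative brightness-level field
    brightness_amp: float = 0.08
    #: base amplitude of the fine-scale (3x3) brightness jitter and the
    #: relative gain by which crown vigor modulates it; this roughness
    #: channel is what local texture statistics read
    texture_rough_base: float = 0.05
    texture_rough_gain: float = 0.5
    #: sd (SPAD units) of the smooth optical-expression mismatch: the
    #: chlorophyll the spectra express differs from the SPAD-measured
    #: content by this leaf-surface/water/structure term
    spectral_mismatch_sd: float = 6.0
    #: amplitude of the long-range additive ambient-light field (reflectance units)
    ambient_amp: float = 0.012
    #: within-crown LCC variability (SPAD units)
    within_plant_sd: float = 0.8
    #: SPAD <-> lab chlorophyll exponential link: lab = a * exp(b * SPAD)
    spad_link_a: float = 4.5
    spad_link_b: float = 0.035

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigError("wavelengths must be strictly increasing")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        lo, hi = self.lcc_range
        if not lo < hi:
            raise ConfigError("lcc_range min must be < max")
        for name in ("noise_sd", "spad_noise_sd", "brightness_amp",
                     "texture_rough_base", "texture_rough_gain",
                     "spectral_mismatch_sd", "ambient_amp",
                     "within_plant_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.soil_fraction < 1.0:
            raise ConfigError("soil_fraction must be in [0, 1)")
        if not -1.0 <= self.texture_corr <= 1.0:
            raise ConfigError("texture_corr must be in [-1, 1]")
        if self.spacing < 2:
            raise ConfigError("spacing must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wavelengths"] = [float(w) for w in self.wavelengths]
        d["lcc_range"] = list(self.lcc_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "wavelengths" in d:
            d["wavelengths"] = np.asarray(d["wavelengths"], dtype=float)
        if "lcc_range" in d:
            d["lcc_range"] = tuple(d["lcc_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-pixel truth for a generated scene.

    ``lcc_map`` is NaN on soil; ``points`` holds one record per ground
    measurement point as ``(id, row, col, spad, plot_id)`` where ``spad``
    is the crown-mean LCC plus SPAD-meter noise.
    """

    lcc_map: np.ndarray
    vegetation_mask_true: np.ndarray
    points: list[tuple[int, int, int, float, int]]

    def points_frame(self):
        import pandas as pd

        return pd.DataFrame(self.points, columns=["id", "row", "col", "spad", "plot"])


# ---------------------------------------------------------------------------
# Leaf reflectance model

_WELLS = (  # center nm, width nm, depth at full chlorophyll saturation
    (446.0, 30.0, 0.26),
    (550.0, 45.0, 0.13),
    (682.0, 45.0, 0.33),
)
_VIS_BASE = 0.34
_NIR_LEVEL = 0.55
_RE_WIDTH = 7.0
_RE_CENTER = 730.0       # red-edge midpoint at the reference SPAD
_RE_SHIFT = 0.25         # nm of midpoint shift per SPAD unit
_LCC_REF = 57.5          # reference SPAD (midpoint of the default range)
_SAT_SCALE = 18.0        # SPAD scale of the saturating absorption response


def _chl_saturation(lcc: np.ndarray) -> np.ndarray:
    """Saturating absorption response 1 - exp(-LCC/18), in (0, 1)."""
    return 1.0 - np.exp(-np.asarray(lcc, dtype=float) / _SAT_SCALE)


def leaf_reflectance(lcc, wavelengths) -> np.ndarray:
    """Canopy-leaf reflectance spectrum as a function of chlorophyll.

    The model is a visible baseline with Gaussian absorption wells at 446,
    550 and 682 nm whose depths scale with a saturating function of LCC,
    blended into a near-infrared plateau through a logistic red-edge ramp
    whose midpoint sits at 730 nm for the reference SPAD of 57.5 and moves
    +0.25 nm per SPAD unit. Consequences: reflectance at 682 nm is strictly
    decreasing in LCC, the red-edge inflection wavelength is strictly
    increasing in LCC, and the NIR plateau stays at 0.55.

    Parameters
    ----------
    lcc : float or array
        Leaf chlorophyll content in SPAD units, > 0. Broadcast against
        ``wavelengths``: scalar -> (bands,), array of shape S -> S+(bands,).
    wavelengths : array
        Wavelengths in nm, within [350, 1000].

    Returns
    -------
    ndarray of reflectance in [0, 1].
    """
    lcc_arr = np.asarray(lcc, dtype=float)
    if np.any(lcc_arr <= 0):
        raise DataError("lcc must be > 0")
    wl = np.asarray(wavelengths, dtype=float)
    if np.any((wl < 350.0) | (wl > 1000.0)):
        raise DataError("wavelengths must lie within 350-1000 nm")

    sat = _chl_saturation(lcc_arr)[..., None]          # (..., 1)
    well_profile = np.zeros_like(wl)
    for center, width, depth in _WELLS:
        well_profile = well_profile + depth * np.exp(-(((wl - center) / width) ** 2))
    vis = _VIS_BASE - sat * well_profile               # (..., bands)

    mid = _RE_CENTER + _RE_SHIFT * (lcc_arr[..., None] - _LCC_REF)
    ramp = expit((wl - mid) / _RE_WIDTH)
    refl = vis + (_NIR_LEVEL - vis) * ramp
    out = np.clip(refl, 0.0, 1.0)
    if np.isscalar(lcc) or lcc_arr.ndim == 0:
        return out.reshape(wl.shape)
    return out


def red_edge_inflection(
    spectrum: np.ndarray, wavelengths: np.ndarray, window: tuple[float, float] = (690.0, 750.0)
) -> float:
    """Wavelength of maximum first derivative within the red-edge window.

    Finite differences on the band grid with quadratic (three-point)
    interpolation around the peak for sub-band resolution.
    """
    wl = np.asarray(wavelengths, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    mids = 0.5 * (wl[1:] + wl[:-1])
    deriv = np.diff(spec) / np.diff(wl)
    sel = (mids >= window[0]) & (mids <= window[1])
    if sel.sum() < 3:
        raise DataError("too few bands inside the red-edge window")
    d, m = deriv[sel], mids[sel]
    k = int(np.argmax(d))
    if 0 < k < d.size - 1:
        denom = d[k - 1] - 2 * d[k] + d[k + 1]
        if denom != 0:
            shift = 0.5 * (d[k - 1] - d[k + 1]) / denom
            return float(m[k] + shift * (m[1] - m[0]))
    return float(m[k])


def soil_reflectance(wavelengths) -> np.ndarray:
    """Bare laterite soil: a dim, gently rising featureless spectrum."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.16 + 2.2e-4 * (wl - 350.0)


# ---------------------------------------------------------------------------
# SPAD <-> lab chlorophyll link


def lab_chlorophyll_from_spad(spad, a: float = 4.5, b: float = 0.035) -> np.ndarray:
    """Lab-extract chlorophyll (ug/mL scale) from SPAD: ``a * exp(b*SPAD)``."""
    return a * np.exp(b * np.asarray(spad, dtype=float))


def spad_from_lab_chlorophyll(lab, a: float = 4.5, b: float = 0.035) -> np.ndarray:
    """Inverse link ``SPAD = (1/b) * ln(lab / a)``."""
    lab = np.asarray(lab, dtype=float)
    if np.any(lab <= 0):
        raise DataError("lab chlorophyll must be > 0")
    return np.log(lab / a) / b


# ---------------------------------------------------------------------------
# Scene assembly


def _standardize(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    if sd == 0:
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def _plan_layout(cfg: SceneConfig):
    """Grid-cell layout of the two plots and the point split between them."""
    s = cfg.spacing
    grid_rows = cfg.n_rows // s
    grid_cols = cfg.n_cols // s
    n1 = max(1, round(cfg.n_points * PLOT_SPLIT[0] / sum(PLOT_SPLIT)))
    n2 = cfg.n_points - n1
    if grid_rows < 1 or grid_cols < 2:
        raise SceneConfigError(
            f"scene {cfg.n_rows}x{cfg.n_cols} too small for {s}x{s} ROIs"
        )
    cols1 = math.ceil(n1 / grid_rows)
    cols2 = grid_cols - cols1
    if cols1 > grid_cols or grid_rows * cols2 < n2:
        raise SceneConfigError(
            f"scene too small to place {cfg.n_points} non-overlapping "
            f"{s}x{s} ROIs split {n1}/{n2} across two plots"
        )
    cells_plot1 = [(i, j) for j in range(cols1) for i in range(grid_rows)]
    cells_plot2 = [(i, j) for j in range(cols1, grid_cols) for i in range(grid_rows)]
    return cells_plot1, cells_plot2, n1, n2


def generate_scene(config: SceneConfig) -> tuple[HyperspectralCube, GroundTruth]:
    """Generate a two-plot canopy scene and its ground truth.

    Plot 1 (left columns) holds plants in the lower part of ``lcc_range``
    (young, leaf-development stage), plot 2 (right columns) the upper part
    (fruit-development stage). Exactly ``n_points`` ground points are placed
    at plant-grid centers, split 30:44 proportionally between the plots.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.n_rows, cfg.n_cols
    s = cfg.spacing
    cells1, cells2, n1, n2 = _plan_layout(cfg)

    lo, hi = cfg.lcc_range
    span = hi - lo
    # overlapping sub-ranges emulating two growth stages
    range1 = (lo, lo + 0.56 * span)
    range2 = (lo + 0.44 * span, hi)

    radius = s * math.sqrt((1.0 - cfg.soil_fraction) / math.pi)
    yy, xx = np.mgrid[0:rows, 0:cols]
    lcc_map = np.full((rows, cols), np.nan)
    veg = np.zeros((rows, cols), dtype=bool)

    def _stamp(cells, lcc_lo, lcc_hi):
        values = {}
        for (i, j) in cells:
            cr, cc = s // 2 + i * s, s // 2 + j * s
            if cr >= rows or cc >= cols:
                continue
            val = rng.uniform(lcc_lo, lcc_hi)
            values[(i, j)] = (cr, cc, val)
            disc = (yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2
            veg[disc] = True
            lcc_map[disc] = val
        return values

    plants1 = _stamp(cells1, *range1)
    plants2 = _stamp(cells2, *range2)

    # smooth within-crown LCC variation
    if cfg.within_plant_sd > 0:
        wiggle = gaussian_filter(rng.standard_normal((rows, cols)), sigma=4.0)
        wiggle = _standardize(wiggle) * cfg.within_plant_sd
        lcc_map = np.where(veg, np.clip(lcc_map + wiggle, 1.0, None), np.nan)

    # multiplicative brightness: a level field plus fine-scale jitter whose
    # local amplitude ("crown roughness") both couple to the LCC map with
    # correlation texture_corr; their independent components are smooth at
    # ROI scale so neither channel becomes noise-free under ROI averaging
    lcc_filled = np.where(veg, lcc_map, np.nanmean(lcc_map))
    z_lcc = _standardize(gaussian_filter(lcc_filled, sigma=2.0))
    tc = cfg.texture_corr
    orth = math.sqrt(max(0.0, 1.0 - tc * tc))
    z_lvl = _standardize(gaussian_filter(rng.standard_normal((rows, cols)), sigma=25.0))
    z_rough = _standardize(gaussian_filter(rng.standard_normal((rows, cols)), sigma=25.0))
    f_level = tc * z_lcc + orth * z_lvl
    f_rough = tc * z_lcc + orth * z_rough
    jitter = _standardize(gaussian_filter(rng.standard_normal((rows, cols)), sigma=0.8))
    rough_amp = cfg.texture_rough_base * np.clip(
        1.0 + cfg.texture_rough_gain * f_rough, 0.2, None)
    brightness = np.clip(1.0 + cfg.brightness_amp * f_level + rough_amp * jitter,
                         0.5, None)

    # long-range additive ambient-light field (corrupts ratios, not texture)
    ambient = cfg.ambient_amp * _standardize(
        gaussian_filter(rng.standard_normal((rows, cols)), sigma=20.0)
    )

    # the chlorophyll the optics express: true LCC plus a smooth mismatch
    # field (leaf water/thickness/surface effects) that VIs cannot separate
    if cfg.spectral_mismatch_sd > 0:
        delta = cfg.spectral_mismatch_sd * _standardize(
            gaussian_filter(rng.standard_normal((rows, cols)), sigma=30.0)
        )
    else:
        delta = np.zeros((rows, cols))
    optical_lcc = np.clip(np.where(veg, lcc_map, _LCC_REF) + delta, 1.0, None)

    wl = cfg.wavelengths
    n_bands = wl.size
    sat = np.where(veg, _chl_saturation(optical_lcc), 0.0)
    mid = _RE_CENTER + _RE_SHIFT * (optical_lcc - _LCC_REF)
    well_profile = np.zeros(n_bands)
    for center, width, depth in _WELLS:
        well_profile += depth * np.exp(-(((wl - center) / width) ** 2))
    soil_spec = soil_reflectance(wl)

    cube = np.empty((rows, cols, n_bands), dtype=np.float32)
    noise = None
    for b in range(n_bands):
        vis = _VIS_BASE - sat * well_profile[b]
        ramp = expit((wl[b] - mid) / _RE_WIDTH)
        leaf = vis + (_NIR_LEVEL - vis) * ramp
        band = np.where(veg, leaf, soil_spec[b]) * brightness + ambient
        if cfg.noise_sd > 0:
            noise = rng.normal(0.0, cfg.noise_sd, size=(rows, cols))
            band = band + noise
        cube[:, :, b] = np.clip(band, 0.0, 1.2)

    # ground points at plant-grid centers
    point_cells1 = [cells1[i] for i in rng.choice(len(cells1), size=n1, replace=False)]
    point_cells2 = [cells2[i] for i in rng.choice(len(cells2), size=n2, replace=False)]
    points: list[tuple[int, int, int, float, int]] = []
    pid = 1
    for cell_list, plants, plot_id in ((point_cells1, plants1, 1), (point_cells2, plants2, 2)):
        for cell in sorted(cell_list):
            cr, cc, _ = plants[cell]
            disc = (yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2
            crown_mean = float(np.nanmean(lcc_map[disc]))
            spad = crown_mean + float(rng.normal(0.0, cfg.spad_noise_sd))
            points.append((pid, cr, cc, spad, plot_id))
            pid += 1

    hsi = HyperspectralCube(cube, wl, np.ones((rows, cols), dtype=bool))
    truth = GroundTruth(lcc_map=lcc_map, vegetation_mask_true=veg, points=points)
    return hsi, truth
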