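"""Vegetation index registry and evaluation.

Twenty indices are registered: eleven "original" indices (VI_org) built from
blue/green/red/NIR bands and nine red-edge variants (VI_re) that swap a
700-710 nm reflectance into an analogous algebraic form. Band requirements
follow the nominal centers of the source definitions (802, 770, 710, 706,
682, 550, 510, 446 nm); each is resolved to the nearest cube band at
evaluation time.

Formula notes
-------------
A few commonly garbled forms are implemented in their canonical published
shape: MSR = (N/R - 1)/sqrt(N/R + 1); MDVI and MDVI_re as the renormalized
difference (N - R)/sqrt(N + R); the OSAVI family as
(1 + 0.16)(N - R)/(N + R + 0.16). RDVI here is the plain difference
Rnir - Rred (the band table's reading), not the classical renormalized DVI.
CI_green deliberately uses 770/510 nm rather than the common 550 nm
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import BandLookupError, DataError, EmptyROIError, RegistryError
from .hsi_io import HyperspectralCube, extract_roi

__all__ = [
    "VIDefinition",
    "FeatureTable",
    "REGISTRY",
    "nearest_band",
    "compute_vi",
    "vi_images",
    "roi_feature_means",
]


def nearest_band(wavelengths: np.ndarray, target: float) -> tuple[int, float]:
    """Index of the band nearest to ``target`` nm and the achieved offset.

    Ties are broken toward the lower index. Targets outside the grid range
    raise :class:`BandLookupError`.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if target < wl[0] or target > wl[-1]:
        raise BandLookupError(
            f"wavelength {target} nm outside cube range [{wl[0]}, {wl[-1]}]"
        )
    idx = int(np.argmin(np.abs(wl - target)))
    return idx, float(wl[idx] - target)


@dataclass(frozen=True)
class VIDefinition:
    """One vegetation index: a formula over wavelength-resolved bands.

    ``bands`` maps symbolic roles (nir, red, green, blue, rededge) to
    nominal center wavelengths in nm. ``rededge_role`` names the band slot
    that red-edge sweeps may substitute (None for VI_org).
    """

    name: str
    vi_class: str  # "VI_org" | "VI_re"
    formula: str
    bands: dict = field(hash=False)
    func: Callable = field(hash=False, repr=False)
    rededge_role: str | None = None


def _sdiv(num, den):
    """Division with zero denominators mapped to NaN (flagged, not dropped)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / den, np.nan)
    return out


def _ssqrt(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(x >= 0, np.sqrt(np.abs(x)), np.nan)


def _build_registry() -> dict[str, VIDefinition]:
    defs = [
        # --- original vegetation indices -----------------------------------
        ("SR", "VI_org", "Rnir/Rred", {"nir": 802, "red": 682},
         lambda b: _sdiv(b["nir"], b["red"]), None),
        ("NDVI", "VI_org", "(Rnir-Rred)/(Rnir+Rred)", {"nir": 802, "red": 682},
         lambda b: _sdiv(b["nir"] - b["red"], b["nir"] + b["red"]), None),
        ("GDVI", "VI_org", "Rgreen-Rred", {"green": 550, "red": 682},
         lambda b: b["green"] - b["red"], None),
        ("RDVI", "VI_org", "Rnir-Rred", {"nir": 802, "red": 682},
         lambda b: b["nir"] - b["red"], None),
        ("MDVI", "VI_org", "(Rnir-Rred)/sqrt(Rnir+Rred)", {"nir": 802, "red": 682},
         lambda b: _sdiv(b["nir"] - b["red"], _ssqrt(b["nir"] + b["red"])), None),
        ("MSR", "VI_org", "(Rnir/Rred-1)/sqrt(Rnir/Rred+1)", {"nir": 802, "red": 682},
         lambda b: _sdiv(_sdiv(b["nir"], b["red"]) - 1,
                         _ssqrt(_sdiv(b["nir"], b["red"]) + 1)), None),
        ("mNDVI", "VI_org", "(Rnir-Rred)/(Rnir+Rred-2Rblue)",
         {"nir": 802, "red": 682, "blue": 446},
         lambda b: _sdiv(b["nir"] - b["red"], b["nir"] + b["red"] - 2 * b["blue"]), None),
        ("CI_green", "VI_org", "Rnir/Rgreen-1", {"nir": 770, "green": 510},
         lambda b: _sdiv(b["nir"], b["green"]) - 1, None),
        ("OSAVI", "VI_org", "(1+0.16)(Rnir-Rred)/(Rnir+Rred+0.16)",
         {"nir": 802, "red": 682},
         lambda b: 1.16 * _sdiv(b["nir"] - b["red"], b["nir"] + b["red"] + 0.16), None),
        ("OSAVI_green", "VI_org", "(1+0.16)(Rnir-Rgreen)/(Rnir+Rgreen+0.16)",
         {"nir": 802, "green": 550},
         lambda b: 1.16 * _sdiv(b["nir"] - b["green"], b["nir"] + b["green"] + 0.16), None),
        ("SIPI", "VI_org", "(Rnir-Rblue)/(Rnir-Rred)",
         {"nir": 802, "blue": 446, "red": 682},
         lambda b: _sdiv(b["nir"] - b["blue"], b["nir"] - b["red"]), None),
        # --- red-edge vegetation indices -----------------------------------
        ("SR_re", "VI_re", "Rnir/Rrededge", {"nir": 802, "rededge": 706},
         lambda b: _sdiv(b["nir"], b["rededge"]), "rededge"),
        ("NDVI_re", "VI_re", "(Rnir-Rrededge)/(Rnir+Rrededge)",
         {"nir": 802, "rededge": 706},
         lambda b: _sdiv(b["nir"] - b["rededge"], b["nir"] + b["rededge"]), "rededge"),
        ("REDVI", "VI_re", "Rrededge-Rred", {"rededge": 710, "red": 682},
         lambda b: b["rededge"] - b["red"], "rededge"),
        ("MDVI_re", "VI_re", "(Rnir-Rrededge)/sqrt(Rnir+Rrededge)",
         {"nir": 802, "rededge": 710},
         lambda b: _sdiv(b["nir"] - b["rededge"], _ssqrt(b["nir"] + b["rededge"])),
         "rededge"),
        ("MSR_re", "VI_re", "(Rnir/Rrededge-1)/sqrt(Rnir/Rrededge+1)",
         {"nir": 802, "rededge": 710},
         lambda b: _sdiv(_sdiv(b["nir"], b["rededge"]) - 1,
                         _ssqrt(_sdiv(b["nir"], b["rededge"]) + 1)), "rededge"),
        ("mNDVI_re", "VI_re", "(Rnir-Rrededge)/(Rnir+Rrededge-2Rblue)",
         {"nir": 802, "rededge": 710, "blue": 446},
         lambda b: _sdiv(b["nir"] - b["rededge"],
                         b["nir"] + b["rededge"] - 2 * b["blue"]), "rededge"),
        ("CI_re", "VI_re", "Rnir/Rrededge-1", {"nir": 770, "rededge": 710},
         lambda b: _sdiv(b["nir"], b["rededge"]) - 1, "rededge"),
        ("OSAVI_re", "VI_re", "(1+0.16)(Rnir-Rrededge)/(Rnir+Rrededge+0.16)",
         {"nir": 802, "rededge": 706},
         lambda b: 1.16 * _sdiv(b["nir"] - b["rededge"],
                                b["nir"] + b["rededge"] + 0.16), "rededge"),
        ("MTCI", "VI_re", "(Rnir-Rrededge)/(Rrededge-Rred)",
         {"nir": 802, "rededge": 710, "red": 682},
         lambda b: _sdiv(b["nir"] - b["rededge"], b["rededge"] - b["red"]), "rededge"),
    ]
    registry = {}
    for name, cls, formula, bands, func, re_role in defs:
        registry[name] = VIDefinition(
            name=name, vi_class=cls, formula=formula, bands=dict(bands),
            func=func, rededge_role=re_role,
        )
    return registry


REGISTRY: dict[str, VIDefinition] = _build_registry()

VI_ORG_NAMES = [n for n, d in REGISTRY.items() if d.vi_class == "VI_org"]
VI_RE_NAMES = [n for n, d in REGISTRY.items() if d.vi_class == "VI_re"]
assert len(REGISTRY) == 20 and len(VI_ORG_NAMES) == 11 and len(VI_RE_NAMES) == 9


def _resolve_bands(
    cube: HyperspectralCube,
    definition: VIDefinition,
    band_override: dict | None = None,
) -> tuple[dict, dict]:
    """Map each band role to a reflectance image; report resolved indices."""
    resolved, report = {}, {}
    targets = dict(definition.bands)
    if band_override:
        targets.update(band_override)
    for role, nm in targets.items():
        idx, offset = nearest_band(cube.wavelengths, nm)
        arr = cube.reflectance[:, :, idx].astype(float)
        resolved[role] = np.where(cube.valid_mask, arr, np.nan)
        report[role] = {"target_nm": float(nm),
                        "band_index": idx, "offset_nm": offset}
    return resolved, report


def compute_vi(
    source: HyperspectralCube | dict,
    name: str,
    band_override: dict | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate one registered index on a cube or a role->reflectance dict.

    ``band_override`` remaps band roles to other wavelengths (used by the
    red-edge sweep). With ``mask`` given, pixels outside it are NaN.
    Division by zero yields NaN, never a silent drop.
    """
    if name not in REGISTRY:
        raise RegistryError(
            f"unknown VI '{name}'; valid names: {sorted(REGISTRY)}"
        )
    definition = REGISTRY[name]
    if isinstance(source, HyperspectralCube):
        bands, _ = _resolve_bands(source, definition, band_override)
    else:
        bands = {k: np.asarray(v, dtype=float) for k, v in source.items()}
        missing = [r for r in definition.bands if r not in bands]
        if missing:
            raise DataError(f"VI '{name}' needs band roles {missing}")
    out = definition.func(bands)
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out


def vi_images(
    cube: HyperspectralCube,
    mask: np.ndarray,
    names: list[str] | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """All (or selected) VI images on vegetation pixels, plus a band report."""
    names = list(REGISTRY) if names is None else names
    images, sidecar = {}, {}
    for name in names:
        definition = REGISTRY[name]
        bands, report = _resolve_bands(cube, definition)
        img = definition.func(bands)
        images[name] = np.where(mask, img, np.nan)
        sidecar[name] = {"formula": definition.formula, "bands": report,
                         "class": definition.vi_class}
    return images, sidecar


@dataclass
class FeatureTable:
    """Ground points x named features, with provenance and the SPAD vector.

    ``data`` is indexed by point id; ``provenance`` maps each feature name
    to one of ``VI``, ``TF-PC1``, ``TF-PC2``, ``TF-PC3``.
    """

    data: pd.DataFrame
    spad: pd.Series
    provenance: dict[str, str]
    dropped_points: list[dict] = field(default_factory=list)
    roi_pixel_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise DataError("feature names must be unique")
        if self.data.isna().any().any():
            raise DataError("feature table holds missing cells after exclusions")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def select(self, names: list[str]) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise RegistryError(f"features not in table: {missing}")
        return self.data[names]


def roi_feature_means(
    feature_images: dict[str, np.ndarray],
    points: pd.DataFrame,
    mask: np.ndarray,
    size: int = 50,
    provenance: dict[str, str] | None = None,
) -> FeatureTable:
    """Average each feature image over the masked ROI of each ground point.

    NaN pixels inside a ROI are excluded from the mean (their count is kept
    in ``roi_pixel_counts``); points whose ROI retains no pixels at all are
    excluded and recorded in ``dropped_points``.
    """
    names = list(feature_images)
    shape = next(iter(feature_images.values())).shape
    records, counts, dropped, kept_ids, spad = [], [], [], [], []
    for _, pt in points.iterrows():
        try:
            rr, cc = extract_roi(shape, (int(pt["row"]), int(pt["col"])),
                                 size=size, mask=mask)
        except EmptyROIError:
            dropped.append({"id": pt["id"], "reason": "empty ROI after masking"})
            continue
        row_vals, row_counts = [], []
        for name in names:
            vals = feature_images[name][rr, cc]
            finite = np.isfinite(vals)
            if not finite.any():
                row_vals.append(np.nan)
                row_counts.append(0)
            else:
                row_vals.append(float(vals[finite].mean()))
                row_counts.append(int(finite.sum()))
        if not all(np.isfinite(row_vals)):
            dropped.append({"id": pt["id"], "reason": "all-NaN feature in ROI"})
            continue
        records.append(row_vals)
        counts.append(row_counts)
        kept_ids.append(pt["id"])
        spad.append(float(pt["spad"]))
    data = pd.DataFrame(records, index=pd.Index(kept_ids, name="id"), columns=names)
    counts_df = pd.DataFrame(counts, index=data.index, columns=names)
    prov = provenance or {n: "VI" for n in names}
    return FeatureTable(
        data=data,
        spad=pd.Series(spad, index=data.index, name="spad"),
        provenance=prov,
        dropped_points=dropped,
        roi_pixel_counts=counts_df,
    )
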