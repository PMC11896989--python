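"""PCA of the cube and Haralick textures from per-window co-occurrence.

The cube is reduced to its first three principal-component images (fit on
vegetation pixels only) and eight gray-level co-occurrence (GLCM) statistics
are computed per pixel from a sliding 3x3 window: MEA, VAR, HOM, CON, DIS,
ENT, SEC, COR. Defaults: 32 gray levels from a global min-max quantization
over vegetation pixels, the four distance-1 offsets (0, 45, 90, 135 deg)
accumulated into one symmetric matrix, entropy in bits.

With a symmetric matrix the two marginals coincide, so MEA doubles as the
marginal mean and VAR as the marginal variance used by COR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DataError, RankError
from .hsi_io import HyperspectralCube

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_OFFSETS",
    "PCAResult",
    "GLCMMatrix",
    "pca_transform",
    "quantize",
    "glcm_window",
    "haralick_features",
    "texture_images",
    "texture_feature_images",
]

FEATURE_NAMES = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEC", "COR")

#: distance-1 offsets at 0, 45, 90, 135 degrees (row, col)
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class PCAResult:
    """Principal-component images with loadings and variance shares."""

    pc_images: np.ndarray                 # rows x cols x n_components
    explained_variance_ratio: np.ndarray  # all components, sums to 1
    loadings: np.ndarray                  # bands x n_components
    fit_pixel_set: str

    @property
    def cumulative_top3(self) -> float:
        return float(self.explained_variance_ratio[:3].sum())


@dataclass
class GLCMMatrix:
    """Normalized co-occurrence distribution of one window."""

    P: np.ndarray
    G: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.G, self.G):
            raise DataError("GLCM must be G x G")
        if np.any(self.P < 0) or not np.isclose(self.P.sum(), 1.0):
            raise DataError("GLCM entries must be >= 0 and sum to 1")

    @property
    def marginal_mean(self) -> tuple[float, float]:
        i = np.arange(self.G)
        return float((self.P.sum(axis=1) * i).sum()), float((self.P.sum(axis=0) * i).sum())

    @property
    def marginal_var(self) -> tuple[float, float]:
        i = np.arange(self.G)
        ui, uj = self.marginal_mean
        return (
            float((self.P.sum(axis=1) * (i - ui) ** 2).sum()),
            float((self.P.sum(axis=0) * (i - uj) ** 2).sum()),
        )


def pca_transform(
    cube: HyperspectralCube, mask: np.ndarray, n_components: int = 3
) -> PCAResult:
    """PCA of mean-centered vegetation-pixel spectra, scored on valid pixels.

    Components come from the eigendecomposition of the covariance of spectra
    inside ``mask``. Sign convention: the largest-magnitude element of each
    loading vector is positive. Scores are rendered for every valid pixel of
    the cube (NaN elsewhere).
    """
    mask = np.asarray(mask, dtype=bool)
    X = cube.reflectance[mask].astype(np.float64)
    if X.shape[0] < 3 or X.shape[1] < 3:
        raise DataError("need >= 3 masked-in pixels and >= 3 bands for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (Xc.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise RankError("degenerate covariance: cube is constant over the mask")
    for k in range(evecs.shape[1]):
        peak = np.argmax(np.abs(evecs[:, k]))
        if evecs[peak, k] < 0:
            evecs[:, k] = -evecs[:, k]
    loadings = evecs[:, :n_components]
    rows, cols, _ = cube.shape
    scores = np.full((rows, cols, n_components), np.nan)
    valid = cube.valid_mask
    scores[valid] = (cube.reflectance[valid].astype(np.float64) - mean) @ loadings
    return PCAResult(
        pc_images=scores,
        explained_variance_ratio=evals / total,
        loadings=loadings,
        fit_pixel_set=f"{int(mask.sum())} masked-in pixels",
    )


def quantize(image: np.ndarray, levels: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Linear min-max binning of ``image`` into gray levels 0..levels-1.

    Bin edges are uniform over the masked value range; the maximum maps into
    the top bin (right-closed). A constant image quantizes to all zeros with
    a warning. Pixels outside the mask (or non-finite) carry the sentinel -1.
    """
    if levels < 2:
        raise DataError("need at least 2 gray levels")
    img = np.asarray(image, dtype=float)
    mask = np.isfinite(img) if mask is None else (np.asarray(mask, bool) & np.isfinite(img))
    if not mask.any():
        raise DataError("no finite pixels to quantize")
    vmin, vmax = img[mask].min(), img[mask].max()
    out = np.full(img.shape, -1, dtype=np.int32)
    if vmax == vmin:
        warnings.warn("constant image: quantized to all zeros", stacklevel=2)
        out[mask] = 0
        return out
    idx = np.floor((img[mask] - vmin) / (vmax - vmin) * levels).astype(np.int32)
    out[mask] = np.clip(idx, 0, levels - 1)
    return out


def glcm_window(
    gray: np.ndarray,
    center: tuple[int, int],
    levels: int,
    window: int = 3,
    offsets=DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCMMatrix:
    """Co-occurrence matrix of one window (reference implementation).

    Pairs whose second pixel falls off-image or on a masked-out (-1)
    pixel are skipped; ``symmetric`` adds the transposed pairs before
    normalizing to sum 1. Zero accumulable pairs raise ``DataError``
    (the per-pixel path flags such pixels NaN instead).
    """
    if window % 2 == 0 or window < 1:
        raise DataError("window must be odd and >= 1")
    gray = np.asarray(gray)
    half = window // 2
    r0, c0 = int(center[0]), int(center[1])
    P = np.zeros((levels, levels), dtype=float)
    n = 0
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            r, c = r0 + dr, c0 + dc
            if not (0 <= r < gray.shape[0] and 0 <= c < gray.shape[1]):
                continue
            a = gray[r, c]
            if a < 0:
                continue
            for (orr, occ) in offsets:
                r2, c2 = r + orr, c + occ
                if not (r0 - half <= r2 <= r0 + half and c0 - half <= c2 <= c0 + half):
                    continue
                if not (0 <= r2 < gray.shape[0] and 0 <= c2 < gray.shape[1]):
                    continue
                b = gray[r2, c2]
                if b < 0:
                    continue
                P[a, b] += 1
                n += 1
                if symmetric:
                    P[b, a] += 1
                    n += 1
    if n == 0:
        raise DataError(f"no accumulable pairs in window at {center}")
    return GLCMMatrix(P=P / n, G=levels)


def haralick_features(glcm: GLCMMatrix) -> dict[str, float]:
    """The eight texture statistics of a normalized co-occurrence matrix.

    ENT uses log base 2 with 0*log(0) := 0; COR is the Haralick correlation
    with COR := 1 when either marginal variance vanishes.
    """
    P = glcm.P
    G = glcm.G
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    mea = float((i * P).sum())
    var = float((((i - mea) ** 2) * P).sum())
    hom = float((P / (1.0 + (i - j) ** 2)).sum())
    con = float((((i - j) ** 2) * P).sum())
    dis = float((np.abs(i - j) * P).sum())
    nz = P[P > 0]
    ent = float(-(nz * np.log2(nz)).sum())
    sec = float((P**2).sum())
    ui, uj = glcm.marginal_mean
    vi, vj = glcm.marginal_var
    if vi <= 0 or vj <= 0:
        cor = 1.0
    else:
        cor = float((((i - ui) * (j - uj)) * P).sum() / np.sqrt(vi * vj))
    return {"MEA": mea, "VAR": var, "HOM": hom, "CON": con,
            "DIS": dis, "ENT": ent, "SEC": sec, "COR": cor}


@njit(cache=False)
def _texture_kernel(gray, levels, half, offsets, out):  # pragma: no cover
    rows, cols = gray.shape
    n_off = offsets.shape[0]
    max_pairs = (2 * half + 1) ** 2 * n_off * 2
    pi = np.empty(max_pairs, dtype=np.int32)
    pj = np.empty(max_pairs, dtype=np.int32)
    for r0 in range(rows):
        for c0 in range(cols):
            if gray[r0, c0] < 0:
                continue
            n = 0
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    r = r0 + dr
                    c = c0 + dc
                    if r < 0 or r >= rows or c < 0 or c >= cols:
                        continue
                    a = gray[r, c]
                    if a < 0:
                        continue
                    for k in range(n_off):
                        r2 = r + offsets[k, 0]
                        c2 = c + offsets[k, 1]
                        if r2 < r0 - half or r2 > r0 + half:
                            continue
                        if c2 < c0 - half or c2 > c0 + half:
                            continue
                        if r2 < 0 or r2 >= rows or c2 < 0 or c2 >= cols:
                            continue
                        b = gray[r2, c2]
                        if b < 0:
                            continue
                        pi[n] = a
                        pj[n] = b
                        pi[n + 1] = b
                        pj[n + 1] = a
                        n += 2
            if n == 0:
                continue
            inv = 1.0 / n
            mea = 0.0
            hom = 0.0
            con = 0.0
            dis = 0.0
            sij = 0.0
            for t in range(n):
                d = pi[t] - pj[t]
                mea += pi[t]
                hom += 1.0 / (1.0 + d * d)
                con += d * d
                dis += abs(d)
                sij += pi[t] * pj[t]
            mea *= inv
            hom *= inv
            con *= inv
            dis *= inv
            sij *= inv
            var = 0.0
            for t in range(n):
                var += (pi[t] - mea) * (pi[t] - mea)
            var *= inv
            # distribution-based stats need cell counts: dedup the pair list
            ent = 0.0
            sec = 0.0
            for t in range(n):
                if pi[t] == -1:
                    continue
                cnt = 1
                for u in range(t + 1, n):
                    if pi[u] == pi[t] and pj[u] == pj[t]:
                        cnt += 1
                        pi[u] = -1  # consumed
                p = cnt * inv
                ent -= p * np.log2(p)
                sec += p * p
            if var <= 0.0:
                cor = 1.0
            else:
                cor = (sij - mea * mea) / var
            out[r0, c0, 0] = mea
            out[r0, c0, 1] = var
            out[r0, c0, 2] = hom
            out[r0, c0, 3] = con
            out[r0, c0, 4] = dis
            out[r0, c0, 5] = ent
            out[r0, c0, 6] = sec
            out[r0, c0, 7] = cor


def texture_images(
    gray: np.ndarray,
    levels: int,
    window: int = 3,
    offsets=DEFAULT_OFFSETS,
) -> dict[str, np.ndarray]:
    """Eight per-pixel texture images from a quantized (sentinel -1) image.

    Each pixel's features come from the symmetric GLCM of its ``window`` x
    ``window`` neighborhood; pixels with no accumulable pairs are NaN.
    """
    if window % 2 == 0:
        raise DataError("window must be odd")
    gray = np.asarray(gray, dtype=np.int32)
    out = np.full(gray.shape + (8,), np.nan)
    off = np.asarray(offsets, dtype=np.int64)
    _texture_kernel(gray, np.int64(levels), np.int64(window // 2), off, out)
    return {name: out[:, :, k] for k, name in enumerate(FEATURE_NAMES)}


def texture_feature_images(
    pca: PCAResult,
    mask: np.ndarray,
    levels: int = 32,
    window: int = 3,
    offsets=DEFAULT_OFFSETS,
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """The 24 texture images: 8 features x PC1..PC3, named ``PCk_FEAT``.

    Each PC image is quantized globally over the vegetation mask so ROI
    means are comparable across points; soil pixels are excluded from both
    quantization and pair accumulation.
    """
    images: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    n_pc = pca.pc_images.shape[2]
    for k in range(n_pc):
        gray = quantize(pca.pc_images[:, :, k], levels, mask)
        feats = texture_images(gray, levels, window=window, offsets=offsets)
        for name, img in feats.items():
            col = f"PC{k + 1}_{name}"
            images[col] = img
            provenance[col] = f"TF-PC{k + 1}"
    return images, provenance
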