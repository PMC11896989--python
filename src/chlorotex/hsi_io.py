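"""Hyperspectral cube and ground-point I/O, plus ROI extraction.

Cubes are stored either as ENVI (raw BSQ/BIL binary next to a text ``.hdr``
carrying the wavelength list) or as single-file GeoTIFF with the wavelength
vector serialized into the image description tag. Reflectance is float32 on
disk; wavelengths are preserved exactly.

Coordinate conventions
----------------------
Pixel coordinates are 0-based ``(row, col)``. The even 50x50 ROI window has
no exact center pixel: the window spans rows ``[r-25, r+24]`` and cols
``[c-25, c+24]`` inclusive, i.e. ``size//2`` pixels before the point and
``size - size//2`` pixels at/after it. Ground tables recorded with 1-based
coordinates must be read with ``one_based=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError, EmptyROIError, FormatError

__all__ = [
    "HyperspectralCube",
    "read_cube",
    "write_cube",
    "read_ground_points",
    "write_ground_points",
    "extract_roi",
    "roi_slices",
]


@dataclass
class HyperspectralCube:
    """Reflectance cube with a wavelength axis and per-pixel validity mask.

    Attributes
    ----------
    reflectance : ndarray, shape (rows, cols, bands), float32
        Unitless reflectance, typically in [0, ~1.2]. Pixels outside
        ``valid_mask`` may hold NaN.
    wavelengths : ndarray, shape (bands,)
        Band-center wavelengths in nanometers, strictly increasing.
    valid_mask : ndarray of bool, shape (rows, cols)
        True where the pixel carries usable data.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.reflectance.ndim != 3:
            raise DataError("reflectance must be a rows x cols x bands array")
        if self.reflectance.shape[2] != self.wavelengths.shape[0]:
            raise DataError(
                f"band count {self.reflectance.shape[2]} does not match "
                f"{self.wavelengths.shape[0]} wavelengths"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DataError("wavelengths must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.reflectance).all(axis=2)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.reflectance.shape[:2]:
            raise DataError("valid_mask shape does not match image shape")
        if not np.isfinite(self.reflectance[self.valid_mask]).all():
            raise DataError("NaN/Inf reflectance inside valid_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]


# ---------------------------------------------------------------------------
# ENVI


def _write_envi(cube: HyperspectralCube, path: Path) -> None:
    img_path = path.with_suffix(".img")
    hdr_path = path.with_suffix(".hdr")
    rows, cols, bands = cube.shape
    data = np.where(cube.valid_mask[:, :, None], cube.reflectance, np.nan)
    # BSQ: band-sequential (bands, rows, cols)
    data.transpose(2, 0, 1).astype("<f4").tofile(img_path)
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        "description = {chlorotex reflectance cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {" + wl + "}\n"
    )
    hdr_path.write_text(hdr)


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    in_brace = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_brace:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf).strip("{} ")
                in_brace = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            in_brace = True
            buf = [value.lstrip("{")]
        else:
            fields[key] = value.strip("{} ")
    return fields


def _read_envi(path: Path) -> HyperspectralCube:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    for required in ("samples", "lines", "bands"):
        if required not in fields:
            raise FormatError(f"ENVI header missing field '{required}'")
    if "wavelength" not in fields:
        raise FormatError("ENVI header missing field 'wavelength'")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    dtype = {"4": "<f4", "5": "<f8"}.get(fields.get("data type", "4"))
    if dtype is None:
        raise FormatError(f"unsupported ENVI data type {fields.get('data type')}")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace(",", " ").split()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"ENVI header lists {wavelengths.size} wavelengths for {bands} bands"
        )
    img_path = path.with_suffix(".img")
    raw = np.fromfile(img_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise FormatError(
            f"ENVI data size {raw.size} does not match {rows}x{cols}x{bands}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        raise FormatError(f"unsupported ENVI interleave '{interleave}'")
    return HyperspectralCube(np.ascontiguousarray(data), wavelengths)


# ---------------------------------------------------------------------------
# GeoTIFF


def _write_gtiff(cube: HyperspectralCube, path: Path) -> None:
    data = np.where(cube.valid_mask[:, :, None], cube.reflectance, np.nan)
    meta = {"wavelengths_nm": [float(w) for w in cube.wavelengths]}
    tifffile.imwrite(
        path,
        data.transpose(2, 0, 1).astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def _read_gtiff(path: Path) -> HyperspectralCube:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(
            "GeoTIFF missing per-band wavelength metadata field 'wavelengths_nm'"
        ) from exc
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != wavelengths.size:
        raise FormatError(
            f"GeoTIFF has {data.shape[0]} bands but {wavelengths.size} wavelengths"
        )
    return HyperspectralCube(data.transpose(1, 2, 0), wavelengths)


def write_cube(cube: HyperspectralCube, path: str | Path) -> Path:
    """Write a cube as ENVI (``.img``/``.hdr``) or GeoTIFF (``.tif``).

    The format is selected from the file extension; ``.img``, ``.hdr`` or
    ``.bsq`` select ENVI, ``.tif``/``.tiff`` select GeoTIFF.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_gtiff(cube, path)
    elif path.suffix.lower() in {".img", ".hdr", ".bsq", ""}:
        _write_envi(cube, path)
    else:
        raise FormatError(f"unrecognized cube extension '{path.suffix}'")
    return path


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read an ENVI or GeoTIFF cube; see :func:`write_cube` for conventions."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_gtiff(path)
    return _read_envi(path)


# ---------------------------------------------------------------------------
# Ground points

GROUND_COLUMNS = ["id", "row", "col", "spad", "plot"]


def read_ground_points(
    path: str | Path,
    image_shape: tuple[int, int] | None = None,
    one_based: bool = False,
) -> pd.DataFrame:
    """Read a ground-point table CSV with header ``id,row,col,spad,plot``.

    Set ``one_based=True`` for tables whose pixel coordinates start at 1;
    they are converted to the package's 0-based convention on read.
    """
    df = pd.read_csv(path)
    missing = [c for c in GROUND_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ground table missing columns {missing}")
    df = df[GROUND_COLUMNS].copy()
    if one_based:
        df["row"] -= 1
        df["col"] -= 1
    if df["id"].duplicated().any():
        raise DataError("ground table ids are not unique")
    if image_shape is not None:
        rows, cols = image_shape
        inside = (
            (df["row"] >= 0) & (df["row"] < rows)
            & (df["col"] >= 0) & (df["col"] < cols)
        )
        if not inside.all():
            bad = df.loc[~inside, "id"].tolist()
            raise DataError(f"ground points outside image bounds: {bad}")
    return df


def write_ground_points(points: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    points[GROUND_COLUMNS].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# ROI extraction


def roi_slices(
    row: int, col: int, size: int, shape: tuple[int, int]
) -> tuple[slice, slice]:
    """Slices of the ``size x size`` window at (row, col), clipped to image."""
    half = size // 2
    r0, r1 = max(0, row - half), min(shape[0], row + size - half)
    c0, c1 = max(0, col - half), min(shape[1], col + size - half)
    return slice(r0, r1), slice(c0, c1)


def extract_roi(
    cube_or_shape: HyperspectralCube | tuple[int, int],
    point: tuple[int, int],
    size: int = 50,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Masked-in pixel indices of the window centered on ``point``.

    Parameters
    ----------
    cube_or_shape : HyperspectralCube or (rows, cols)
        The image the window is clipped against.
    point : (row, col)
        0-based pixel coordinates of the measurement point.
    size : int
        Window edge length in pixels (50 in the field protocol).
    mask : bool array, optional
        Vegetation/validity mask; only masked-in pixels are retained.

    Returns
    -------
    rows, cols : int arrays
        Indices of retained pixels (empty never returned; an empty window
        raises :class:`EmptyROIError` so the caller can exclude the point).
    """
    if size < 1:
        raise DataError("ROI size must be >= 1")
    shape = (
        cube_or_shape.reflectance.shape[:2]
        if isinstance(cube_or_shape, HyperspectralCube)
        else tuple(cube_or_shape)
    )
    rs, cs = roi_slices(int(point[0]), int(point[1]), size, shape)  # type: ignore[arg-type]
    rr, cc = np.mgrid[rs, cs]
    rr, cc = rr.ravel(), cc.ravel()
    if mask is not None:
        keep = mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
    if rr.size == 0:
        raise EmptyROIError(
            f"ROI at {tuple(point)} retains zero pixels after masking"
        )
    return rr, cc
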