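"""Image, mask, polygon and trait-table input/output.

Images are represented in memory as 2-D ``float64`` arrays with values in
[0, 1] (row-major, origin at the top-left, y increasing downward).
Integer rasters are normalized by the maximum representable value of
their bit depth (255 for 8-bit, 65535 for 16-bit) so that the
sensitivity threshold operates on the same scale for every input.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: ITU-R 601 luminance weights, the coefficients of the classic
#: rgb-to-gray conversion used by MATLAB's rgb2gray.
RGB_WEIGHTS = (0.2989, 0.5870, 0.1140)

SUPPORTED_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


def to_gray(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Combine three [0, 1] channels into luminance.

    Uses the fixed weighting 0.2989 R + 0.5870 G + 0.1140 B and clips the
    result to [0, 1] (the weights sum to 0.9999, so pure white maps to
    0.9999 before clipping).
    """
    r, g, b = (np.asarray(c, dtype=np.float64) for c in (r, g, b))
    if not (r.shape == g.shape == b.shape):
        raise ValueError(
            f"channel shapes differ: {r.shape}, {g.shape}, {b.shape}"
        )
    wr, wg, wb = RGB_WEIGHTS
    return np.clip(wr * r + wg * g + wb * b, 0.0, 1.0)


def _normalize(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scale = float(info.max) if info.max > 0 else 1.0
        return arr.astype(np.float64) / scale
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def load_image(path: str | Path) -> np.ndarray:
    """Load a raster image as a normalized [0, 1] grayscale array.

    Color inputs are converted through :func:`to_gray`; an alpha channel,
    if present, is discarded.
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_EXTENSIONS:
        raise ValueError(f"unsupported image format: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - present path in message
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
        else:
            norm = _normalize(arr[:, :, :3])
            return to_gray(norm[:, :, 0], norm[:, :, 1], norm[:, :, 2])
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape} in {path}")
    return _normalize(arr)


def save_image(img: np.ndarray, path: str | Path, bitdepth: int = 8) -> None:
    """Write a [0, 1] grayscale array as an 8- or 16-bit raster."""
    img = np.asarray(img, dtype=np.float64)
    if bitdepth == 8:
        data = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
    elif bitdepth == 16:
        data = np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    iio.imwrite(Path(path), data)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with root = 255."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask (any pixel above half intensity counts as root)."""
    return load_image(path) > 0.5


def save_rgb(rgb: np.ndarray, path: str | Path) -> None:
    """Write an RGB overlay (float [0, 1] or uint8) as a PNG."""
    rgb = np.asarray(rgb)
    if rgb.dtype != np.uint8:
        rgb = np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    iio.imwrite(Path(path), rgb)


def read_polygon(path: str | Path) -> list[tuple[float, float]]:
    """Read a polygon ROI file: one ``row,col`` vertex per line."""
    vertices = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'row,col', got {raw!r}")
        vertices.append((float(parts[0]), float(parts[1])))
    if len(vertices) < 3:
        raise ValueError(f"{path}: polygon needs >= 3 vertices, found {len(vertices)}")
    return vertices


def write_traits_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trait table (one row per image, 44 trait columns) as CSV.

    The index holds image identifiers and is written under the header
    ``image``.  Column order is the frozen trait schema order.
    """
    from .traits import N_TRAITS

    if table.shape[1] != N_TRAITS:
        raise ValueError(
            f"trait table must have exactly {N_TRAITS} columns, got {table.shape[1]}"
        )
    table.to_csv(Path(path), index_label="image")
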