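"""Binary root segmentation.

Two stages produce the clean root mask:

1. **Adaptive thresholding.**  Each pixel is compared against the
   Gaussian-weighted mean of its neighborhood; it is classified as root
   iff its intensity exceeds that local mean by more than the
   sensitivity offset ``T`` (on the normalized [0, 1] scale).  Because
   the decision is purely local-contrast based, it tolerates global
   illumination inhomogeneity such as the vertical intensity gradient
   typical of rhizobox photographs.

2. **Morphological shape filtering.**  Roots are elongated curvilinear
   structures, while sand grains, gravel and water-condensation
   artifacts are compact blobs.  Connected components (8-connected) are
   therefore screened by area, length (major axis of the ellipse with
   the same second central moments) and eccentricity (0 for a circle,
   1 for a line); only components passing all three thresholds survive.

An optional non-interactive correction step clears root pixels inside or
outside a user-supplied polygon, replacing interactive mask editing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage.measure import label as sk_label

from . import preprocess
from .config import SegmentationConfig


def default_window(shape: tuple[int, int]) -> int:
    """Default local-mean window: ``2 * floor(min(H, W) / 16) + 1``, >= 3."""
    return max(2 * (min(shape) // 16) + 1, 3)


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")


def gaussian_local_mean(
    img: np.ndarray, window: int, sigma: float | None = None
) -> np.ndarray:
    """Per-pixel Gaussian-weighted mean over a ``window``-sized neighborhood.

    Weights are a truncated 2-D Gaussian normalized to sum 1; borders are
    reflective.  ``sigma`` defaults to ``window / 6`` so the kernel decays
    to ~3 sigma at the window edge.
    """
    _check_window(window)
    if sigma is None:
        sigma = window / 6.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = window // 2
    return ndi.gaussian_filter(
        np.asarray(img, dtype=np.float64),
        sigma=sigma,
        truncate=half / sigma,
        mode="reflect",
    )


def adaptive_threshold(
    img: np.ndarray,
    T: float = 0.12,
    window: int | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Local-contrast binarization: root iff ``I - local_mean > T``.

    Bright-foreground convention: dark-root modalities must be inverted
    upstream.  ``T`` is an additive offset on the [0, 1] intensity scale.
    """
    if not 0.0 <= T <= 1.0:
        raise ValueError(f"sensitivity T must lie in [0, 1], got {T}")
    img = np.asarray(img, dtype=np.float64)
    if window is None:
        window = default_window(img.shape)
    mu = gaussian_local_mean(img, window, sigma)
    return (img - mu) > T


@dataclass(frozen=True)
class Component:
    """A connected foreground component and its ellipse shape descriptors.

    ``major_axis``/``minor_axis`` are the axis lengths of the ellipse with
    the same normalized second central moments as the pixel set;
    ``eccentricity = sqrt(1 - (minor/major)^2)`` is 0 for a 4-fold
    symmetric shape and exactly 1 for collinear pixels.  ``length`` is the
    major axis (the elongation measure used by the shape filter).
    """

    label: int
    area: int
    centroid: tuple[float, float]
    major_axis: float
    minor_axis: float
    eccentricity: float
    coords: np.ndarray

    @property
    def length(self) -> float:
        return self.major_axis


def _ellipse_descriptors(coords: np.ndarray) -> tuple[float, float, float]:
    """Exact eigen-ellipse axes/eccentricity from integer pixel coordinates.

    The second central moments are accumulated in exact integer
    arithmetic (n*S_rr - S_r^2 etc.) so that symmetric shapes yield
    eccentricity exactly 0 and collinear pixel sets exactly 1.
    """
    n = int(coords.shape[0])
    sr, sc = int(np.sum(coords[:, 0], dtype=np.int64)), int(np.sum(coords[:, 1], dtype=np.int64))
    srr = int(np.sum(coords[:, 0].astype(np.int64) ** 2))
    scc = int(np.sum(coords[:, 1].astype(np.int64) ** 2))
    src = int(np.sum(coords[:, 0].astype(np.int64) * coords[:, 1].astype(np.int64)))
    # n^2 * central moments, exact integers
    A = n * srr - sr * sr
    B = n * scc - sc * sc
    C = n * src - sr * sc
    common_sq = (A - B) ** 2 + 4 * C * C
    common = math.isqrt(common_sq)
    exact = common * common == common_sq
    if not exact:
        common = math.sqrt(float(common_sq))
    l1 = (A + B + common) / (2.0 * n * n)  # larger eigenvalue of the inertia tensor
    l2 = (A + B - common) / (2.0 * n * n)
    l2 = max(l2, 0.0)
    major = 4.0 * math.sqrt(l1 / 1.0) if l1 > 0 else 0.0
    minor = 4.0 * math.sqrt(l2 / 1.0) if l2 > 0 else 0.0
    if l1 <= 0:
        ecc = 0.0  # single pixel / degenerate: call it round
    else:
        ecc = math.sqrt(max(1.0 - l2 / l1, 0.0))
    return major, minor, ecc


def component_props(mask: np.ndarray) -> list[Component]:
    """Label the mask (8-connected) and describe every component."""
    mask = np.asarray(mask, bool)
    labels, n = sk_label(mask, connectivity=2, return_num=True)
    comps: list[Component] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        major, minor, ecc = _ellipse_descriptors(coords)
        comps.append(
            Component(
                label=lab,
                area=coords.shape[0],
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                major_axis=major,
                minor_axis=minor,
                eccentricity=ecc,
                coords=coords,
            )
        )
    return comps


def morphological_filter(
    mask: np.ndarray,
    min_area: float = 450,
    min_length: float = 46,
    min_eccentricity: float = 0.49,
) -> np.ndarray:
    """Keep only components with area, length and eccentricity above threshold.

    All three criteria must hold simultaneously; everything else is
    cleared.  The operation is idempotent and its output foreground is a
    subset of the input foreground.
    """
    if min_area < 0 or min_length < 0 or min_eccentricity < 0:
        raise ValueError("shape thresholds must be nonnegative")
    mask = np.asarray(mask, bool)
    out = np.zeros_like(mask)
    for comp in component_props(mask):
        if (
            comp.area >= min_area
            and comp.length >= min_length
            and comp.eccentricity >= min_eccentricity
        ):
            out[comp.coords[:, 0], comp.coords[:, 1]] = True
    return out


def clear_region(
    mask: np.ndarray,
    polygon: list[tuple[float, float]],
    mode: str = "inside",
) -> np.ndarray:
    """Clear root pixels inside (or outside) a polygon.

    ``polygon`` is a list of (row, col) vertices; pixels on the polygon
    boundary count as inside.  ``mode="inside"`` removes covered root
    pixels (artifact removal); ``mode="outside"`` keeps only covered
    pixels (region-of-interest restriction).
    """
    if len(polygon) < 3:
        raise ValueError(f"polygon needs >= 3 vertices, got {len(polygon)}")
    if mode not in ("inside", "outside"):
        raise ValueError("mode must be 'inside' or 'outside'")
    mask = np.asarray(mask, bool)
    rows = np.asarray([p[0] for p in polygon], dtype=np.float64)
    cols = np.asarray([p[1] for p in polygon], dtype=np.float64)
    region = np.zeros_like(mask)
    rr, cc = skdraw.polygon(rows, cols, shape=mask.shape)
    region[rr, cc] = True
    rr, cc = skdraw.polygon_perimeter(rows, cols, shape=mask.shape)
    region[rr, cc] = True
    if mode == "inside":
        return mask & ~region
    return mask & region


def segment_image(
    img: np.ndarray,
    config: SegmentationConfig | None = None,
    roi: tuple[int, int, int, int] | None = None,
    clear_inside: list[list[tuple[float, float]]] | None = None,
    clear_outside: list[list[tuple[float, float]]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full segmentation pipeline: preprocess, threshold, shape-filter, correct.

    Returns ``(mask, preprocessed_image)``; the preprocessed image is the
    one trait extraction should use for intensity statistics so that the
    mask and the intensities refer to the same signal.
    """
    config = config or SegmentationConfig()
    pre = preprocess.apply(img, config, roi=roi)
    mask = adaptive_threshold(
        pre, T=config.sensitivity_T, window=config.window_size, sigma=config.local_sigma
    )
    mask = morphological_filter(
        mask, config.min_area, config.min_length, config.min_eccentricity
    )
    for poly in clear_inside or []:
        mask = clear_region(mask, poly, mode="inside")
    for poly in clear_outside or []:
        mask = clear_region(mask, poly, mode="outside")
    return mask, pre
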