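"""Image conditioning ahead of thresholding.

The pipeline order is fixed: crop -> invert -> despeckle -> smooth.
Inversion must precede thresholding because segmentation assumes bright
roots on a darker background; agar-grown and washed-root scans show the
opposite polarity.  All filters use reflective border padding so the
local statistics near the frame are not biased by an artificial dark rim.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .config import SegmentationConfig


def crop_roi(img: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Crop a rectangular region of interest.

    ``rect`` is ``(r0, c0, height, width)`` in pixel coordinates; it must
    lie fully inside the image and have positive extent.
    """
    r0, c0, h, w = rect
    H, W = img.shape
    if h <= 0 or w <= 0:
        raise ValueError(f"ROI must have positive extent, got {rect}")
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise ValueError(f"ROI {rect} exceeds image bounds {(H, W)}")
    return img[r0:r0 + h, c0:c0 + w].copy()


def invert(img: np.ndarray) -> np.ndarray:
    """Intensity complement ``1 - I``, turning dark roots bright."""
    return 1.0 - np.asarray(img, dtype=np.float64)


def despeckle(img: np.ndarray, radius: int = 1) -> np.ndarray:
    """Median filter over a ``(2 radius + 1)`` square; radius 0 is a no-op."""
    if radius < 0:
        raise ValueError("despeckle radius must be >= 0")
    if radius == 0:
        return np.asarray(img, dtype=np.float64).copy()
    return ndi.median_filter(img, size=2 * radius + 1, mode="reflect")


def smooth(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian blur with reflective borders; sigma 0 is a no-op."""
    if sigma < 0:
        raise ValueError("smoothing sigma must be >= 0")
    if sigma == 0:
        return np.asarray(img, dtype=np.float64).copy()
    return ndi.gaussian_filter(img, sigma=sigma, mode="reflect")


def apply(
    img: np.ndarray,
    config: SegmentationConfig,
    roi: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Run the full preprocessing chain configured in ``config``."""
    out = np.asarray(img, dtype=np.float64)
    if roi is not None:
        out = crop_roi(out, roi)
    if config.invert:
        out = invert(out)
    out = despeckle(out, config.despeckle_radius)
    out = smooth(out, config.smooth_sigma)
    return out
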