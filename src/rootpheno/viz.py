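"""Overlay renderings of skeleton-level features.

Two overlays mirror the standard diagnostic views of a root analysis:
the skeleton colored by local width (gray-scale map) and by local
tangent angle (black-to-yellow map), both drawn on top of the dimmed
binary mask.
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .skeleton import OrientationMap, Skeleton

_BLACK_YELLOW = LinearSegmentedColormap.from_list(
    "black_yellow", [(0.0, 0.0, 0.0), (1.0, 1.0, 0.0)]
)

_MASK_GRAY = 0.45  # brightness of the mask backdrop in overlays


def _backdrop(mask: np.ndarray) -> np.ndarray:
    rgb = np.zeros((*mask.shape, 3))
    rgb[np.asarray(mask, bool)] = _MASK_GRAY
    return rgb


def width_overlay(mask: np.ndarray, skel: Skeleton, dmap: np.ndarray) -> np.ndarray:
    """Skeleton colored by local width on the dimmed mask (float RGB)."""
    rgb = _backdrop(mask)
    coords = skel.coords
    if coords.size:
        widths = 2.0 * dmap[coords[:, 0], coords[:, 1]]
        top = widths.max() if widths.max() > 0 else 1.0
        shade = 0.25 + 0.75 * widths / top
        rgb[coords[:, 0], coords[:, 1]] = shade[:, None]
    return rgb


def orientation_overlay(mask: np.ndarray, omap: OrientationMap) -> np.ndarray:
    """Skeleton colored black->yellow by tangent angle (0..90 deg).

    Pixels that fail the regression validity gate are drawn in gray.
    """
    rgb = _backdrop(mask)
    invalid = ~omap.valid & ~np.isnan(omap.p_value)
    rgb[invalid] = 0.6
    sel = omap.valid
    if sel.any():
        rgb[sel] = _BLACK_YELLOW(omap.angle[sel] / 90.0)[:, :3]
    return rgb
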