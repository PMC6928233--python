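"""Skeleton-based geometry: medial axis, width, branching, orientation.

The clean binary mask is reduced to a 1-pixel-wide skeleton by homotopic
thinning.  The Euclidean distance transform of the mask evaluated on the
skeleton gives the local root radius, hence width (diameter) as twice
the distance.  Skeleton topology (degree of each pixel under
8-connectivity) yields end points (degree 1) and branch points (degree
>= 3, with 8-connected clusters of branch pixels collapsed to a single
point, since thinning algorithms may emit junction pixels with
algorithm-dependent multiplicity).

Skeleton length is the total length of the 8-adjacency graph edges: 1
per orthogonal edge, sqrt(2) per diagonal edge, where a diagonal edge is
dropped whenever its endpoints share an orthogonal skeleton neighbor
(otherwise every staircase corner would be counted twice).

Local orientation is estimated per skeleton pixel by ordinary
least-squares regression over the skeleton pixels inside a sliding
square window (default 15 x 15 px).  To handle near-vertical runs the
coordinate with the smaller spread is regressed on the one with the
larger spread.  A pixel's tangent is accepted only when the fit is
statistically credible: at least 3 skeleton pixels in the window, slope
F-test p-value < 0.05 and R^2 > 0.5.  Junctions, where skeleton pixels
are not collinear, fail this gate and are excluded from orientation
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize as sk_skeletonize

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)

SQRT2 = math.sqrt(2.0)


@dataclass
class Skeleton:
    """1-pixel-wide medial representation of a binary mask."""

    mask: np.ndarray  # bool, same shape as the source mask

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)

    @property
    def coords(self) -> np.ndarray:
        """Skeleton pixel coordinates, (n, 2) int array in row-major order."""
        return np.argwhere(self.mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def degree_image(self) -> np.ndarray:
        """8-neighbor count for every pixel; 0 outside the skeleton."""
        counts = ndi.convolve(
            self.mask.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0
        )
        return np.where(self.mask, counts, 0)


def skeletonize(mask: np.ndarray, erode_iterations: int = 0) -> Skeleton:
    """Thin a binary mask to its skeleton, optionally eroding first.

    Erosion (3x3 structuring element, ``erode_iterations`` passes)
    suppresses high-frequency boundary noise that would otherwise spawn
    spurious skeleton branches; 0 disables it.  Thinning is homotopic, so
    connected mask components yield connected skeletons as long as the
    erosion does not destroy them.
    """
    if erode_iterations < 0:
        raise ValueError("erode_iterations must be >= 0")
    mask = np.asarray(mask, bool)
    if erode_iterations > 0:
        mask = ndi.binary_erosion(
            mask, structure=np.ones((3, 3), bool), iterations=erode_iterations
        )
    return Skeleton(sk_skeletonize(mask))


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of each root pixel to the nearest background pixel."""
    return ndi.distance_transform_edt(np.asarray(mask, bool))


def width_along_skeleton(skel: Skeleton, dmap: np.ndarray) -> np.ndarray:
    """Local root width (diameter, px) at each skeleton pixel: ``2 * distance``.

    Returned in the same order as ``skel.coords``.
    """
    coords = skel.coords
    d = dmap[coords[:, 0], coords[:, 1]]
    if np.any(d <= 0):
        raise ValueError("skeleton pixel with zero distance: skeleton not inside mask")
    return 2.0 * d


def detect_branch_end_points(skel: Skeleton) -> tuple[np.ndarray, np.ndarray]:
    """Locate branch points (degree >= 3) and end points (degree == 1).

    Adjacent degree->=3 pixels are merged: each 8-connected cluster of
    branch pixels is reported once, at the cluster pixel closest to the
    cluster centroid.  Returns ``(branch_coords, end_coords)`` as (n, 2)
    integer arrays.
    """
    deg = skel.degree_image()
    end_coords = np.argwhere(deg == 1)
    branch_mask = deg >= 3
    labels, n = sk_label(branch_mask, connectivity=2, return_num=True)
    reps = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        center = coords.mean(axis=0)
        reps.append(coords[np.argmin(((coords - center) ** 2).sum(axis=1))])
    branch_coords = np.asarray(reps, dtype=int).reshape(-1, 2)
    return branch_coords, end_coords


def _edge_half_lengths(mask: np.ndarray) -> np.ndarray:
    """Per-pixel half-sum of incident skeleton edge lengths.

    Edges follow the corner-cut rule described in the module docstring;
    summing the returned image over all pixels gives the total skeleton
    length (each edge contributes half its length to both endpoints).
    """
    S = np.asarray(mask, bool)
    acc = np.zeros(S.shape, dtype=np.float64)
    # orthogonal edges
    right = S[:, :-1] & S[:, 1:]
    acc[:, :-1][right] += 0.5
    acc[:, 1:][right] += 0.5
    down = S[:-1, :] & S[1:, :]
    acc[:-1, :][down] += 0.5
    acc[1:, :][down] += 0.5
    # diagonal edges, skipped when the corner pixel is present
    dr = S[:-1, :-1] & S[1:, 1:]  # down-right
    dr &= ~(S[1:, :-1] | S[:-1, 1:])
    acc[:-1, :-1][dr] += SQRT2 / 2.0
    acc[1:, 1:][dr] += SQRT2 / 2.0
    dl = S[:-1, 1:] & S[1:, :-1]  # down-left
    dl &= ~(S[1:, 1:] | S[:-1, :-1])
    acc[:-1, 1:][dl] += SQRT2 / 2.0
    acc[1:, :-1][dl] += SQRT2 / 2.0
    return acc


def skeleton_length(skel: Skeleton) -> float:
    """Total skeleton length in pixels (unit + sqrt(2) edge weights)."""
    return float(_edge_half_lengths(skel.mask).sum())


@dataclass
class OrientationMap:
    """Per-skeleton-pixel tangent orientation with regression diagnostics.

    All fields are full-image 2-D arrays; pixels off the skeleton hold
    NaN (or False for ``valid``).  ``angle`` is the absolute tangent
    angle in degrees within [0, 90], measured against the configured
    reference axis, and is defined only where ``valid`` is True.
    """

    angle: np.ndarray
    r_squared: np.ndarray
    p_value: np.ndarray
    valid: np.ndarray

    def valid_angles(self) -> np.ndarray:
        """Angles of accepted pixels, as a flat array."""
        return self.angle[self.valid]


def local_orientation(
    skel: Skeleton, window: int = 15, axis: str = "horizontal"
) -> OrientationMap:
    """Estimate the local tangent angle at every skeleton pixel.

    For each pixel, an OLS line is fitted through the skeleton pixels in
    the centered ``window x window`` neighborhood (coordinate with the
    smaller spread regressed on the larger-spread one).  The angle is
    reported in [0, 90] degrees relative to ``axis`` ("horizontal" or
    "vertical"); validity follows the p < 0.05 and R^2 > 0.5 gate with at
    least 3 supporting pixels.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    S = skel.mask
    H, W = S.shape
    half = window // 2
    angle = np.full(S.shape, np.nan)
    r2map = np.full(S.shape, np.nan)
    pmap = np.full(S.shape, np.nan)
    valid = np.zeros(S.shape, bool)
    for r, c in skel.coords:
        win = S[max(0, r - half):r + half + 1, max(0, c - half):c + half + 1]
        ys, xs = np.nonzero(win)
        n = ys.size
        if n < 3:
            continue
        ys = ys.astype(np.float64)
        xs = xs.astype(np.float64)
        # regress the tighter coordinate on the wider one; ties go to
        # x-as-regressor, which keeps 45-degree runs well-posed
        if xs.std() >= ys.std():
            theta, r2, p = _ols_angle(xs, ys, from_horizontal=True)
        else:
            theta, r2, p = _ols_angle(ys, xs, from_horizontal=False)
        r2map[r, c] = r2
        pmap[r, c] = p
        ok = (p < 0.05) and (r2 > 0.5)
        valid[r, c] = ok
        if ok:
            angle[r, c] = theta if axis == "horizontal" else 90.0 - theta
    return OrientationMap(angle=angle, r_squared=r2map, p_value=pmap, valid=valid)


def _ols_angle(x: np.ndarray, y: np.ndarray, from_horizontal: bool) -> tuple[float, float, float]:
    """Slope angle (deg from horizontal), R^2 and slope-test p-value of y ~ x."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx  # regressor has the larger spread, so sxx > 0
    ss_res = max(syy - slope * sxy, 0.0)
    if syy > 0:
        r2 = 1.0 - ss_res / syy
    else:
        r2 = 1.0  # dependent coordinate constant: a perfect flat line
    if r2 >= 1.0:
        p = 0.0
    else:
        f_stat = (n - 2) * r2 / (1.0 - r2)
        p = float(sps.f.sf(f_stat, 1, n - 2))
    theta = math.degrees(math.atan(abs(slope)))
    if not from_horizontal:
        theta = 90.0 - theta
    return theta, r2, p
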