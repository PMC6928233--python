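"""The 44-trait phenotypic descriptor table.

The table covers 11 feature categories: root area, number of
disconnected root objects, total skeleton length, surface area, volume,
branch-point count, end-point count, mean root intensity, and the
statistical distributions of root geometry in the horizontal and
vertical directions, of local width and of local orientation.  Each of
the four distributions is summarized by the same 9 statistics (mean,
median, standard deviation, skewness, kurtosis, min, max, 25th and 75th
percentile), giving 8 scalars + 4 x 9 = 44 traits.  The schema (names
and order) is frozen; the CSV header appends a unit suffix per trait.

Surface area and volume use a tube model over the skeleton: with local
radius ``r_i`` (the distance-transform value at skeleton pixel i) and
incident half-length ``l_i`` (half the summed lengths of the skeleton
edges touching pixel i), surface = sum(2 pi r_i l_i) and volume =
sum(pi r_i^2 l_i) — the discrete integral of a circular cross-section
swept along the medial axis.

With a conversion factor ``c`` (mm/px) every length-like trait scales by
c, areas by c^2 and volumes by c^3; counts, angles, intensities and the
dimensionless shape statistics (skewness, kurtosis) are unchanged.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.measure import label as sk_label

from .config import ConversionFactor, SegmentationConfig
from .skeleton import (
    Skeleton,
    _edge_half_lengths,
    detect_branch_end_points,
    distance_map,
    local_orientation,
    skeletonize,
)

#: scalar traits with their unit dimension exponent (px^k)
SCALAR_TRAITS: list[tuple[str, int]] = [
    ("root_area", 2),
    ("object_count", 0),
    ("total_length", 1),
    ("surface_area", 2),
    ("volume", 3),
    ("branch_count", 0),
    ("end_count", 0),
    ("mean_intensity", 0),
]

#: distribution traits; horizontal/vertical position of root pixels in the
#: image frame, local width along the skeleton, validated tangent angle
DISTRIBUTIONS: list[str] = ["pos_x", "pos_y", "width", "angle"]

STAT_NAMES: list[str] = [
    "mean", "median", "std", "skewness", "kurtosis", "min", "max", "p25", "p75",
]

#: stats that carry the distribution's length unit; skewness/kurtosis are
#: scale-invariant and therefore dimensionless
_SCALED_STATS = {"mean", "median", "std", "min", "max", "p25", "p75"}

N_TRAITS = len(SCALAR_TRAITS) + len(DISTRIBUTIONS) * len(STAT_NAMES)


def base_trait_names() -> list[str]:
    """The 44 trait names without unit suffixes, in frozen order."""
    names = [name for name, _ in SCALAR_TRAITS]
    for dist in DISTRIBUTIONS:
        names.extend(f"{dist}_{stat}" for stat in STAT_NAMES)
    return names


def unit_exponents() -> dict[str, int]:
    """Map base trait name -> power of the length unit (0, 1, 2 or 3)."""
    exp = {name: k for name, k in SCALAR_TRAITS}
    for dist in DISTRIBUTIONS:
        for stat in STAT_NAMES:
            if dist == "angle":
                exp[f"{dist}_{stat}"] = 0
            else:
                exp[f"{dist}_{stat}"] = 1 if stat in _SCALED_STATS else 0
    return exp


def trait_names(metric: bool = False) -> list[str]:
    """Trait names with unit suffixes (px/px2/px3 or mm/mm2/mm3, deg)."""
    unit = "mm" if metric else "px"
    suffix = {0: "", 1: f"_{unit}", 2: f"_{unit}2", 3: f"_{unit}3"}
    exp = unit_exponents()
    out = []
    for name in base_trait_names():
        if name.startswith("angle_") and name.split("_", 1)[1] in _SCALED_STATS:
            out.append(f"{name}_deg")
        else:
            out.append(name + suffix[exp[name]])
    return out


def _dist_stats(values: np.ndarray) -> list[float]:
    """The 9 summary statistics; NaN throughout for an empty sample."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return [math.nan] * len(STAT_NAMES)
    return [
        float(values.mean()),
        float(np.median(values)),
        float(values.std()),
        float(sps.skew(values)) if values.size > 1 else math.nan,
        float(sps.kurtosis(values)) if values.size > 1 else math.nan,
        float(values.min()),
        float(values.max()),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    ]


def compute_traits(
    mask: np.ndarray,
    img: np.ndarray,
    cf: ConversionFactor | None = None,
    config: SegmentationConfig | None = None,
) -> pd.Series:
    """Extract the 44-trait table from a clean binary mask.

    ``img`` supplies the intensity statistics (use the same preprocessed
    image the mask was derived from).  All traits are pixel-wise over the
    whole mask, irrespective of how many root systems it contains.  With
    ``cf`` given, length-like traits are reported in mm (area mm^2,
    volume mm^3); otherwise in pixel units.  An empty mask yields zero
    for every scalar trait and NaN for the distribution statistics.
    """
    mask = np.asarray(mask, bool)
    img = np.asarray(img, dtype=np.float64)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    config = config or SegmentationConfig()

    values: dict[str, float] = {}
    if mask.any():
        n_objects = int(sk_label(mask, connectivity=2, return_num=True)[1])
        skel = skeletonize(mask, erode_iterations=config.erode_iterations)
        dmap = distance_map(mask)
        half_len = _edge_half_lengths(skel.mask)
        total_length = float(half_len.sum())
        coords = skel.coords
        radii = dmap[coords[:, 0], coords[:, 1]]
        incident = half_len[coords[:, 0], coords[:, 1]]
        surface = float(np.sum(2.0 * math.pi * radii * incident))
        volume = float(np.sum(math.pi * radii**2 * incident))
        branch, end = detect_branch_end_points(skel)
        omap = local_orientation(
            skel, window=config.orientation_window, axis=config.orientation_axis
        )
        angles = omap.valid_angles()
        rows, cols = np.nonzero(mask)
        values.update(
            root_area=float(mask.sum()),
            object_count=float(n_objects),
            total_length=total_length,
            surface_area=surface,
            volume=volume,
            branch_count=float(branch.shape[0]),
            end_count=float(end.shape[0]),
            mean_intensity=float(img[mask].mean()),
        )
        dists = {
            "pos_x": cols.astype(np.float64),
            "pos_y": rows.astype(np.float64),
            "width": 2.0 * radii,
            "angle": angles,
        }
    else:
        values.update({name: 0.0 for name, _ in SCALAR_TRAITS})
        dists = {d: np.empty(0) for d in DISTRIBUTIONS}

    for dist in DISTRIBUTIONS:
        for stat, val in zip(STAT_NAMES, _dist_stats(dists[dist])):
            values[f"{dist}_{stat}"] = val

    exp = unit_exponents()
    scale = cf.mm_per_px if cf is not None else 1.0
    data = [values[name] * scale ** exp[name] for name in base_trait_names()]
    return pd.Series(data, index=trait_names(metric=cf is not None), dtype=np.float64)
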