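"""Segmentation quality and modality separability metrics.

The Dice similarity coefficient DSC = 2 TP / (2 TP + FP + FN) measures
spatial overlap between a predicted and a reference binary mask (0 = no
overlap, 1 = perfect overlap).  Histogram separability quantifies how
distinguishable root and background intensities are in a given imaging
modality: the Euclidean distance between the normalized 256-bin
intensity histograms of the two pixel classes.  Low separability (heavy
histogram overlap) characterizes soil-root photographs, the hardest
modality; agar-grown and washed-root scans separate progressively
better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DSCResult:
    """Pixel confusion counts and the Dice coefficient."""

    tp: int
    fp: int
    fn: int
    dsc: float


def dice(pred: np.ndarray, truth: np.ndarray) -> DSCResult:
    """Dice similarity between a predicted and a ground-truth mask.

    Symmetric in its arguments.  When both masks are empty the
    coefficient is undefined; it is reported as 0 with a warning.
    """
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("DSC of two empty masks is undefined; reporting 0", stacklevel=2)
        return DSCResult(tp=0, fp=0, fn=0, dsc=0.0)
    return DSCResult(tp=tp, fp=fp, fn=fn, dsc=2.0 * tp / denom)


@dataclass(frozen=True)
class SeparabilityResult:
    """Root/background histogram pair and their Euclidean distance."""

    pdist: float
    hist_root: np.ndarray
    hist_nonroot: np.ndarray


N_BINS = 256  # matches the 8-bit provenance of the intensity scale


def histogram_separability(img: np.ndarray, truth: np.ndarray) -> SeparabilityResult:
    """Distance between root and non-root intensity histograms.

    Both histograms use 256 uniform bins on [0, 1] and are normalized to
    sum 1; ``pdist`` is the Euclidean distance between the two vectors
    (a permutation-invariant, purely intensity-based statistic).
    """
    img = np.asarray(img, dtype=np.float64)
    truth = np.asarray(truth, bool)
    if img.shape != truth.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {truth.shape}")
    root_vals = img[truth]
    nonroot_vals = img[~truth]
    if root_vals.size == 0 or nonroot_vals.size == 0:
        raise ValueError("degenerate class: both root and non-root pixels required")
    h_root, _ = np.histogram(root_vals, bins=N_BINS, range=(0.0, 1.0))
    h_non, _ = np.histogram(nonroot_vals, bins=N_BINS, range=(0.0, 1.0))
    h_root = h_root / h_root.sum()
    h_non = h_non / h_non.sum()
    return SeparabilityResult(
        pdist=float(np.linalg.norm(h_root - h_non)),
        hist_root=h_root,
        hist_nonroot=h_non,
    )
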