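"""Pipeline configuration and physical-unit conversion.

All tunable parameters of the segmentation/trait pipeline live in
:class:`SegmentationConfig`.  Intensities are always on the normalized
[0, 1] scale, so the sensitivity offset ``sensitivity_T`` is portable
across 8- and 16-bit inputs.  Metric output is controlled by a
:class:`ConversionFactor` derived from a reference bar of known physical
length photographed alongside the roots.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass(frozen=True)
class ConversionFactor:
    """Pixel-to-millimetre scale, CF = bar length in mm / bar length in px.

    The reference bar's pixel length is measured externally (e.g. in any
    image viewer); automatic scale-bar detection is deliberately not
    attempted.
    """

    reference_len_mm: float
    reference_len_px: float

    def __post_init__(self) -> None:
        if self.reference_len_mm <= 0 or self.reference_len_px <= 0:
            raise ValueError("reference lengths must be strictly positive")

    @property
    def mm_per_px(self) -> float:
        return self.reference_len_mm / self.reference_len_px

    @classmethod
    def from_mm_per_px(cls, mm_per_px: float) -> "ConversionFactor":
        """Build a conversion factor directly from a mm/px scale."""
        if mm_per_px <= 0:
            raise ValueError("mm_per_px must be strictly positive")
        return cls(reference_len_mm=mm_per_px, reference_len_px=1.0)


@dataclass
class SegmentationConfig:
    """All knobs of the segmentation and trait-extraction pipeline.

    Parameters
    ----------
    sensitivity_T:
        Additive contrast offset on the [0, 1] intensity scale.  A pixel
        is classified as root iff its intensity exceeds the local
        Gaussian-weighted mean by more than ``sensitivity_T``.
    window_size:
        Odd side length (px) of the local-mean window.  ``None`` selects
        ``2 * floor(min(H, W) / 16) + 1`` per image: large relative to a
        root's width, small relative to the illumination gradient.
    local_sigma:
        Gaussian weight sigma of the local-mean window; ``None`` selects
        ``window_size / 6``.
    min_area, min_length, min_eccentricity:
        Shape thresholds of the connected-component filter.  A component
        is kept only if area >= min_area (px), ellipse major axis >=
        min_length (px) and eccentricity >= min_eccentricity (0 = circle,
        1 = line).  Defaults are the reference operating point for
        soil-root images: T = 0.12, area 450, length 46, eccentricity 0.49.
    despeckle_radius:
        Median-filter radius (px); 0 disables despeckling.
    smooth_sigma:
        Gaussian pre-smoothing sigma (px); 0 disables smoothing.
    invert:
        Flip intensities (``1 - I``) before thresholding.  Required for
        agar-grown and washed-root scans where roots are dark on bright.
    erode_iterations:
        Binary erosions applied before skeletonization to suppress
        high-frequency boundary noise.
    orientation_window:
        Odd side length (px) of the sliding window used for the local
        tangent regression along the skeleton.
    orientation_axis:
        Reference axis for the reported angle: ``"horizontal"`` (angle 0
        for a horizontal root) or ``"vertical"`` (the complement, 90 - a).
    """

    sensitivity_T: float = 0.12
    window_size: int | None = None
    local_sigma: float | None = None
    min_area: int = 450
    min_length: float = 46.0
    min_eccentricity: float = 0.49
    despeckle_radius: int = 1
    smooth_sigma: float = 1.0
    invert: bool = False
    erode_iterations: int = 0
    orientation_window: int = 15
    orientation_axis: str = "horizontal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity_T <= 1.0:
            raise ValueError("sensitivity_T must lie in [0, 1]")
        for name in ("window_size", "orientation_window"):
            v = getattr(self, name)
            if v is not None and (v < 3 or v % 2 == 0):
                raise ValueError(f"{name} must be odd and >= 3, got {v}")
        if self.min_area < 0 or self.min_length < 0:
            raise ValueError("shape thresholds must be nonnegative")
        if not 0.0 <= self.min_eccentricity <= 1.0:
            raise ValueError("min_eccentricity must lie in [0, 1]")
        if self.despeckle_radius < 0:
            raise ValueError("despeckle_radius must be >= 0")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.erode_iterations < 0:
            raise ValueError("erode_iterations must be >= 0")
        if self.orientation_axis not in ("horizontal", "vertical"):
            raise ValueError("orientation_axis must be 'horizontal' or 'vertical'")

    def replace(self, **kwargs) -> "SegmentationConfig":
        return dataclasses.replace(self, **kwargs)


_BOOL_TRUE = {"1", "true", "yes", "on"}
_BOOL_FALSE = {"0", "false", "no", "off"}


def write_config(config: SegmentationConfig, path: str | Path) -> None:
    """Write the configuration as a flat ``key = value`` text file."""
    lines = []
    for f in fields(config):
        v = getattr(config, f.name)
        lines.append(f"{f.name} = {'none' if v is None else v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SegmentationConfig:
    """Read a flat ``key = value`` configuration file.

    Unknown keys raise; missing keys keep their defaults.  Lines that are
    blank or start with ``#`` are ignored.
    """
    known = {f.name: f for f in fields(SegmentationConfig)}
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (s.strip() for s in line.partition("="))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        kwargs[key] = _parse_value(key, value)
    return SegmentationConfig(**kwargs)


def _parse_value(key: str, value: str):
    if value.lower() in ("none", ""):
        return None
    if key == "invert":
        low = value.lower()
        if low in _BOOL_TRUE:
            return True
        if low in _BOOL_FALSE:
            return False
        raise ValueError(f"cannot parse boolean {value!r} for key {key!r}")
    if key == "orientation_axis":
        return value
    if key in ("window_size", "min_area", "despeckle_radius", "erode_iterations",
               "orientation_window"):
        return int(value)
    return float(value)
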