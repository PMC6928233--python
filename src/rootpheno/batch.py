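"""Unsupervised batch processing of image directories.

The intended workflow: tune the configuration on a few representative
images, then apply it unchanged to the whole dataset.  Images are
processed independently in lexicographic filename order; a failure on
one image is logged and listed in the summary without aborting the
batch, and repeated runs with the same inputs produce byte-identical
trait CSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io, viz
from .config import ConversionFactor, SegmentationConfig
from .segmentation import segment_image
from .skeleton import distance_map, local_orientation, skeletonize
from .traits import compute_traits, trait_names

logger = logging.getLogger(__name__)


def process_image(
    path: str | Path,
    config: SegmentationConfig | None = None,
    cf: ConversionFactor | None = None,
    out_dir: str | Path | None = None,
) -> pd.Series:
    """Segment one image, extract traits, optionally write mask + overlays."""
    path = Path(path)
    config = config or SegmentationConfig()
    img = io.load_image(path)
    mask, pre = segment_image(img, config)
    traits = compute_traits(mask, pre, cf=cf, config=config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.save_mask(mask, out_dir / f"{path.stem}_mask.png")
        skel = skeletonize(mask, erode_iterations=config.erode_iterations)
        dmap = distance_map(mask)
        io.save_rgb(viz.width_overlay(mask, skel, dmap),
                    out_dir / f"{path.stem}_width.png")
        omap = local_orientation(skel, window=config.orientation_window,
                                 axis=config.orientation_axis)
        io.save_rgb(viz.orientation_overlay(mask, omap),
                    out_dir / f"{path.stem}_orientation.png")
    return traits


def run_batch(
    image_dir: str | Path,
    config: SegmentationConfig | None = None,
    cf: ConversionFactor | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Apply one configuration to every image in a directory.

    Returns ``(traits, failures)``: a trait table with one row per
    successfully processed image (rows in lexicographic filename order)
    and a list of ``(filename, error message)`` pairs for images that
    failed.  When ``out_dir`` is given, per-image masks and overlays,
    the aggregate ``traits.csv`` and a ``summary.txt`` are written there.
    """
    image_dir = Path(image_dir)
    config = config or SegmentationConfig()
    paths = sorted(
        p for p in image_dir.iterdir()
        if p.is_file() and p.suffix.lower() in io.SUPPORTED_EXTENSIONS
    )
    if not paths:
        raise FileNotFoundError(f"no images found in {image_dir}")

    rows: dict[str, pd.Series] = {}
    failures: list[tuple[str, str]] = []
    for path in paths:
        try:
            rows[path.name] = process_image(path, config=config, cf=cf, out_dir=out_dir)
        except Exception as exc:  # noqa: BLE001 - batch must continue
            logger.warning("failed to process %s: %s", path.name, exc)
            failures.append((path.name, str(exc)))

    columns = trait_names(metric=cf is not None)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "image"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_traits_csv(table, out_dir / "traits.csv")
        lines = [f"processed: {len(rows)}", f"failed: {len(failures)}"]
        lines += [f"FAILED {name}: {msg}" for name, msg in failures]
        (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return table, failures
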