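"""Top-level routing: classify an image, then run the matching segmenter."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .classify import ImageClass, ImageLabel, classify_image
from .config import FrameworkConfig
from .io import Manifest, RegionRecord, read_image, write_image
from .irregular import segment_irregular
from .regions import SegmentationResult
from .regular import segment_regular

logger = logging.getLogger(__name__)


def segment_any(
    image: np.ndarray, cls: ImageClass, config: FrameworkConfig
) -> SegmentationResult | None:
    """Dispatch to the branch matching the image class.

    Single-panel images get no segmentation (the whole image is already the
    retrievable unit) and ``None`` is returned.
    """
    if cls.label is ImageLabel.SINGLE_PANEL:
        return None
    if cls.label is ImageLabel.MULTI_PANEL_REGULAR:
        return segment_regular(image, cls, config)
    return segment_irregular(image, config, cls)


def run_pipeline(
    path: str | Path,
    config: FrameworkConfig | None = None,
    out_dir: str | Path | None = None,
) -> Manifest:
    """Classify a figure file and segment it along the matching branch.

    Crops are written as ``<stem>_panel_<k>.png`` plus ``manifest.json`` when
    ``out_dir`` is given; the manifest (with the effective configuration
    embedded) is returned either way.
    """
    config = config or FrameworkConfig()
    path = Path(path)
    image = read_image(path)
    cls = classify_image(image, config)
    logger.info(
        "%s: %s (separator indices: %d horizontal, %d vertical; "
        "lines: %d horizontal, %d vertical)",
        path.name,
        cls.label.value,
        cls.total_horizontal,
        cls.total_vertical,
        cls.lines_horizontal,
        cls.lines_vertical,
    )
    result = segment_any(image, cls, config)

    records: list[RegionRecord] = []
    if result is not None:
        logger.info("%s: %d panel(s) via %s branch", path.name,
                    len(result.regions), result.regions[0].branch)
        for k, region in enumerate(result.regions):
            records.append(
                RegionRecord(region=region, crop_file=f"{path.stem}_panel_{k}.png")
            )

    manifest = Manifest(
        source=path.name,
        image_class=cls.label.value,
        regions=records,
        config_snapshot=config.to_dict(),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if result is not None:
            for record, crop in zip(records, result.crops):
                write_image(out_dir / record.crop_file, crop)
        manifest.save(out_dir / "manifest.json")
    return manifest
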