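"""Irregular multi-panel segmentation.

Irregular montages (stitched mosaics, non-uniform gaps, no straight
full-width gutters) cannot be cut by projection profiles.  They are instead
segmented by global Otsu thresholding, a morphological closing that fills
small holes and pits inside panels, 8-connected component labeling with
per-component statistics, and an area filter that keeps only components
large enough to be genuine panels.  Each surviving component's bounding box
is emitted as a panel region and the crop is taken from the original image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .classify import ImageClass, ImageLabel
from .config import FrameworkConfig
from .core import to_grayscale
from .exceptions import WrongBranchError
from .regions import IRREGULAR_BRANCH, PanelRegion, SegmentationResult

MAX_VALUE = 255


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold: the intensity t maximizing between-class variance.

    The two classes of the split at ``t`` are pixels ``<= t`` and ``> t``.
    The between-class variance is ``w0 * w1 * (mu0 - mu1)**2`` where ``w``
    are class weights and ``mu`` class means; the lowest maximizing ``t`` is
    returned.  A constant image has no two-class split; 0 is returned with a
    warning.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("Otsu thresholding requires a grayscale image")
    hist = np.bincount(image.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        warnings.warn("constant image: degenerate histogram, returning threshold 0")
        return 0
    total = hist.sum()
    intensities = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    cum_mass = np.cumsum(hist * intensities)
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mass / w0
        mu1 = (cum_mass[-1] - cum_mass) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between, nan=0.0)
    return int(np.argmax(between))


def binarize(image: np.ndarray, t: int, max_value: int = MAX_VALUE) -> np.ndarray:
    """Two-way split: pixels ``<= t`` map to 0, pixels ``> t`` to ``max_value``."""
    if not 0 <= t <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    image = np.asarray(image)
    return np.where(image > t, max_value, 0).astype(np.uint8)


def morphological_close(
    binary: np.ndarray, kernel_rows: int, kernel_cols: int
) -> np.ndarray:
    """Closing = dilation (neighborhood maximum) then erosion (minimum).

    Neighborhoods are the ``kernel_rows x kernel_cols`` rectangle centred on
    each pixel, clipped at the image boundary (edge replication), so the
    operation is extensive and idempotent on binary images.
    """
    binary = np.asarray(binary)
    for name, k in (("kernel_rows", kernel_rows), ("kernel_cols", kernel_cols)):
        if k < 1 or k % 2 == 0:
            raise ValueError(f"{name} must be odd and >= 1")
    m, n = binary.shape[:2]
    if kernel_rows > m or kernel_cols > n:
        raise ValueError(
            f"kernel {kernel_rows}x{kernel_cols} exceeds image {m}x{n}"
        )
    size = (kernel_rows, kernel_cols)
    dilated = ndi.maximum_filter(binary, size=size, mode="nearest")
    return ndi.minimum_filter(dilated, size=size, mode="nearest")


@dataclass(frozen=True)
class ComponentStats:
    """Bounding box and area of one connected foreground component.

    ``x``/``y`` are the bounding box's left column and top row; ``area`` is
    the number of foreground pixels (not the box area).
    """

    label: int
    x: int
    y: int
    w: int
    h: int
    area: int


def connected_components(binary: np.ndarray) -> list[ComponentStats]:
    """Label maximal 8-connected foreground regions with statistics.

    Foreground is every non-zero pixel; background is excluded.  Labels are
    contiguous from 1 in scan order.
    """
    fg = np.asarray(binary) > 0
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n_labels = ndi.label(fg, structure=structure)
    if n_labels == 0:
        return []
    areas = np.bincount(labels.ravel(), minlength=n_labels + 1)
    stats = []
    for i, sl in enumerate(ndi.find_objects(labels), start=1):
        rows, cols = sl
        stats.append(
            ComponentStats(
                label=i,
                x=int(cols.start),
                y=int(rows.start),
                w=int(cols.stop - cols.start),
                h=int(rows.stop - rows.start),
                area=int(areas[i]),
            )
        )
    return stats


def _border_majority_foreground(binary: np.ndarray) -> bool:
    """True when more than half the 1-px border frame is foreground."""
    top, bottom = binary[0, :], binary[-1, :]
    left, right = binary[1:-1, 0], binary[1:-1, -1]
    border = np.concatenate([top, bottom, left, right])
    return bool(np.count_nonzero(border) * 2 > border.size)


def segment_irregular(
    image: np.ndarray,
    config: FrameworkConfig | None = None,
    cls: ImageClass | None = None,
) -> SegmentationResult:
    """Segment an irregular multi-panel image into its component panels.

    Pipeline: grayscale -> Otsu binarization -> polarity normalization
    (panels must be foreground: if the border-pixel majority is foreground
    the page background binarized bright, so the binary image is inverted)
    -> morphological closing -> 8-connected components -> keep components
    whose foreground area exceeds ``area_fraction * M * N`` -> emit bounding
    boxes, cropping from the original image.

    When no component survives the area filter, the whole frame is returned
    as a single region with ``fallback=True`` and a warning.
    """
    config = config or FrameworkConfig()
    if cls is not None and cls.label is not ImageLabel.MULTI_PANEL_IRREGULAR:
        raise WrongBranchError(
            f"segment_irregular expects an irregular multi-panel image, got {cls.label}"
        )
    image = np.asarray(image)
    gray = to_grayscale(image)
    m, n = gray.shape
    t = otsu_threshold(gray)
    binary = binarize(gray, t)
    if _border_majority_foreground(binary):
        binary = (MAX_VALUE - binary).astype(np.uint8)
    closed = morphological_close(binary, config.kernel_rows, config.kernel_cols)
    components = connected_components(closed)
    area_threshold = config.area_fraction * m * n
    kept = [c for c in components if c.area > area_threshold]
    if not kept:
        warnings.warn("no component exceeded the area threshold; returning full frame")
        region = PanelRegion(0, m, 0, n, depth=0, branch=IRREGULAR_BRANCH)
        return SegmentationResult(
            regions=[region],
            crops=[image.copy()],
            source_class=cls,
            fallback=True,
        )
    regions = [
        PanelRegion(
            row_start=c.y,
            row_end=c.y + c.h,
            col_start=c.x,
            col_end=c.x + c.w,
            depth=0,
            branch=IRREGULAR_BRANCH,
        )
        for c in kept
    ]
    crops = [region.crop(image).copy() for region in regions]
    return SegmentationResult(regions=regions, crops=crops, source_class=cls)
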