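"""Regular multi-panel segmentation by recursive projection-profile cutting.

A regular montage has straight, (near-)white gutters spanning the full width
or height of the figure.  Segmentation cuts the image at each high-intensity
separator run along the axis with more separator indices, discards the
separator bands, trims one pixel from each new segment edge, and recurses on
every segment until no separators remain or the recursion bound is reached.
"""

from __future__ import annotations

import numpy as np

from .classify import ImageClass, ImageLabel
from .config import FrameworkConfig
from .core import (
    HORIZONTAL,
    VERTICAL,
    SeparatorIndexSet,
    high_intensity_indices,
    projection_profile,
    to_grayscale,
)
from .exceptions import WrongBranchError
from .regions import REGULAR_BRANCH, PanelRegion, SegmentationResult


def choose_direction(hlv: SeparatorIndexSet, vlv: SeparatorIndexSet) -> str | None:
    """Pick the first cut axis from the separator index counts.

    Horizontal segmentation (cutting rows) when HLV has strictly more
    elements than VLV, vertical otherwise; ties fall to vertical.  Returns
    ``None`` as the no-separator signal when both sets are empty.
    """
    if hlv.count == 0 and vlv.count == 0:
        return None
    return HORIZONTAL if hlv.count > vlv.count else VERTICAL


def segment_axis(
    image: np.ndarray,
    runs: list[tuple[int, int]] | tuple[tuple[int, int], ...],
    axis: str,
    *,
    min_extent: int = 16,
    edge_trim: int = 1,
    depth: int = 0,
) -> list[PanelRegion]:
    """Cut an image at separator runs along one axis.

    Segment *k* spans from the end of run *k-1* (exclusive) to the start of
    run *k* (exclusive); a final segment after the last run reaches the image
    edge.  The separator bands themselves are discarded.  Each segment is
    then trimmed by ``edge_trim`` pixels on all four sides and segments with
    either extent below ``min_extent`` are dropped.  With no runs the whole
    (untrimmed) image is returned as a single region.

    ``runs`` are inclusive ``(start, end)`` index pairs in the image's own
    frame, sorted and within bounds.
    """
    m, n = image.shape[:2]
    if not runs:
        return [PanelRegion(0, m, 0, n, depth=depth, branch=REGULAR_BRANCH)]

    extent = m if axis == HORIZONTAL else n
    bounds: list[tuple[int, int]] = []
    cursor = 0
    for start, end in runs:
        if start > cursor:
            bounds.append((cursor, start))
        cursor = end + 1
    if cursor < extent:
        bounds.append((cursor, extent))

    regions: list[PanelRegion] = []
    for a, b in bounds:
        if axis == HORIZONTAL:
            r0, r1, c0, c1 = a, b, 0, n
        else:
            r0, r1, c0, c1 = 0, m, a, b
        r0, r1 = r0 + edge_trim, r1 - edge_trim
        c0, c1 = c0 + edge_trim, c1 - edge_trim
        if r1 - r0 >= max(min_extent, 1) and c1 - c0 >= max(min_extent, 1):
            regions.append(
                PanelRegion(r0, r1, c0, c1, depth=depth, branch=REGULAR_BRANCH)
            )
    return regions


def segment_regular(
    image: np.ndarray,
    cls: ImageClass,
    config: FrameworkConfig | None = None,
) -> SegmentationResult:
    """Recursively segment a regular multi-panel image.

    At every recursion level the current region's mean-normalized profiles
    are recomputed, the cut axis is chosen by :func:`choose_direction`, and
    the region is split at the separator runs of that axis.  Recursion stops
    when a region has no separators or ``max_recursion_depth`` is reached.
    All returned regions are expressed in original-image coordinates and the
    crops are taken from the original (possibly color) image.

    Raises
    ------
    WrongBranchError
        If ``cls.label`` is not ``MULTI_PANEL_REGULAR``.
    """
    config = config or FrameworkConfig()
    if cls.label is not ImageLabel.MULTI_PANEL_REGULAR:
        raise WrongBranchError(
            f"segment_regular expects a regular multi-panel image, got {cls.label}"
        )
    image = np.asarray(image)
    gray = to_grayscale(image)
    m, n = gray.shape
    bt = config.border_trim
    out: list[PanelRegion] = []

    def recurse(r0: int, r1: int, c0: int, c1: int, depth: int) -> None:
        sub = gray[r0:r1, c0:c1]
        h_prof = projection_profile(sub, HORIZONTAL, normalize=True)
        v_prof = projection_profile(sub, VERTICAL, normalize=True)
        hlv = high_intensity_indices(h_prof, config)
        vlv = high_intensity_indices(v_prof, config)
        direction = choose_direction(hlv, vlv)
        if direction is None or depth >= config.max_recursion_depth:
            out.append(PanelRegion(r0, r1, c0, c1, depth=depth, branch=REGULAR_BRANCH))
            return
        runs = (hlv if direction == HORIZONTAL else vlv).runs
        segments = segment_axis(
            sub,
            runs,
            direction,
            min_extent=config.min_panel_extent,
            edge_trim=1,
            depth=depth + 1,
        )
        if not segments:
            # every candidate segment was a sliver; keep the parent region
            out.append(PanelRegion(r0, r1, c0, c1, depth=depth, branch=REGULAR_BRANCH))
            return
        for seg in segments:
            recurse(
                r0 + seg.row_start,
                r0 + seg.row_end,
                c0 + seg.col_start,
                c0 + seg.col_end,
                depth + 1,
            )

    recurse(bt, m - bt, bt, n - bt, 0)
    crops = [region.crop(image).copy() for region in out]
    return SegmentationResult(regions=out, crops=crops, source_class=cls)
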