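"""Image-type identification.

An input figure is labeled single-panel, regular multi-panel, or irregular
multi-panel from its horizontal/vertical separator index sets (HLV/VLV):
no high-intensity rows or columns at all means a single panel; a small number
of crisp separator lines per axis means a regular montage; extensive
high-intensity index ranges (wide white margins and empty expanses rather
than thin gutters) indicate an irregular layout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .config import FrameworkConfig
from .core import (
    HORIZONTAL,
    VERTICAL,
    SeparatorIndexSet,
    high_intensity_indices,
    projection_profile,
    to_grayscale,
    trim_border,
)


class ImageLabel(str, enum.Enum):
    SINGLE_PANEL = "single-panel"
    MULTI_PANEL_REGULAR = "multi-panel-regular"
    MULTI_PANEL_IRREGULAR = "multi-panel-irregular"


@dataclass(frozen=True)
class ImageClass:
    """Classification outcome plus the separator index sets that produced it.

    ``total_horizontal``/``total_vertical`` are raw index counts (the printed
    decision quantities); ``lines_horizontal``/``lines_vertical`` are the
    gutter-width-independent effective line counts actually used when
    ``count_mode == "lines"``.
    """

    label: ImageLabel
    hlv: SeparatorIndexSet
    vlv: SeparatorIndexSet
    total_horizontal: int
    total_vertical: int
    lines_horizontal: int
    lines_vertical: int


def count_separators(index_set: SeparatorIndexSet) -> int:
    """Number of individual high-intensity indices in the set."""
    return index_set.count


def classify_from_index_sets(
    hlv: SeparatorIndexSet,
    vlv: SeparatorIndexSet,
    config: FrameworkConfig | None = None,
) -> ImageClass:
    """Apply the two-stage decision rule to precomputed index sets.

    Stage 1: both raw counts <= ``threshold_single`` (default 0) means the
    image has no inter-panel borders and is single-panel.  Stage 2: the image
    is regular when the larger per-axis separator count is at most
    ``threshold_comp`` (default 5), irregular otherwise.  Which counting
    feeds stage 2 is governed by ``config.count_mode``.
    """
    config = config or FrameworkConfig()
    n_h = count_separators(hlv)
    n_v = count_separators(vlv)
    l_h = hlv.line_count(config.max_separator_width)
    l_v = vlv.line_count(config.max_separator_width)

    if n_h <= config.threshold_single and n_v <= config.threshold_single:
        label = ImageLabel.SINGLE_PANEL
    else:
        c_h, c_v = (l_h, l_v) if config.count_mode == "lines" else (n_h, n_v)
        if max(c_h, c_v) <= config.threshold_comp:
            label = ImageLabel.MULTI_PANEL_REGULAR
        else:
            label = ImageLabel.MULTI_PANEL_IRREGULAR

    return ImageClass(
        label=label,
        hlv=hlv,
        vlv=vlv,
        total_horizontal=n_h,
        total_vertical=n_v,
        lines_horizontal=l_h,
        lines_vertical=l_v,
    )


def classify_image(
    image: np.ndarray, config: FrameworkConfig | None = None
) -> ImageClass:
    """Classify a raster figure.

    Pipeline: grayscale -> outer-border trim -> mean-normalized projection
    profiles -> high-intensity index sets -> decision rule.  The returned
    record carries the index sets (in trimmed-frame coordinates) for reuse by
    the segmenters.
    """
    config = config or FrameworkConfig()
    gray = to_grayscale(np.asarray(image))
    if gray.size == 0:
        raise ValueError("cannot classify an empty image")
    trimmed = trim_border(gray, config.border_trim)
    h_prof = projection_profile(trimmed, HORIZONTAL, normalize=True)
    v_prof = projection_profile(trimmed, VERTICAL, normalize=True)
    hlv = high_intensity_indices(h_prof, config)
    vlv = high_intensity_indices(v_prof, config)
    return classify_from_index_sets(hlv, vlv, config)
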