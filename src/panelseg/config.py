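"""Framework configuration.

All tunable parameters of the classification/segmentation pipeline live in a
single immutable :class:`FrameworkConfig`.  Thresholds are expressed either in
pixels (structuring element, border trims, minimum panel size) or as fractions
(separator intensity, minimum component area) so that behaviour is independent
of image size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class FrameworkConfig:
    """Parameters governing every stage of the pipeline.

    Attributes
    ----------
    threshold_single:
        Maximum number of separator indices (per axis) an image may have and
        still be a single-panel image.  The default 0 means *any* detected
        inter-panel border makes the image multi-panel.
    threshold_comp:
        Maximum effective separator-line count (per axis) for a multi-panel
        image to be *regular*; montages observed in the biomedical literature
        rarely have more than five separators per direction.
    intensity_fraction:
        A row/column of the mean-normalized projection profile is a separator
        candidate when its value exceeds ``intensity_fraction * 255``.
        Separator gutters are near-white, hence the 0.95 default.
    border_trim:
        Pixels removed from every outer edge before profiles are computed, so
        the figure's own outer frame is not mistaken for a separator.
    min_panel_extent:
        Minimum side length (pixels) of an emitted panel; suppresses sliver
        regions produced by cutting inside wide gutters.
    kernel_rows, kernel_cols:
        Structuring-element size of the morphological closing applied to the
        binarized image in the irregular branch.  Must be odd.
    area_fraction:
        A connected component is kept as a panel only when its foreground area
        exceeds ``area_fraction * M * N``.
    max_recursion_depth:
        Bound on the alternating cut recursion of the regular branch.
    max_separator_width:
        Runs of contiguous high-intensity indices no wider than this count as
        a single logical separator line; wider runs (page margins, large empty
        expanses) contribute their raw index count, signalling an irregular
        layout.
    count_mode:
        ``"lines"`` (default) uses the effective line counts above for the
        regular/irregular decision; ``"indices"`` uses raw index counts.
    """

    threshold_single: int = 0
    threshold_comp: int = 5
    intensity_fraction: float = 0.95
    border_trim: int = 2
    min_panel_extent: int = 16
    kernel_rows: int = 29
    kernel_cols: int = 29
    area_fraction: float = 0.02
    max_recursion_depth: int = 4
    max_separator_width: int = 24
    count_mode: str = "lines"

    def __post_init__(self) -> None:
        if self.threshold_single < 0:
            raise ValueError("threshold_single must be >= 0")
        if self.threshold_comp < 1:
            raise ValueError("threshold_comp must be >= 1")
        if not 0.0 < self.intensity_fraction <= 1.0:
            raise ValueError("intensity_fraction must be in (0, 1]")
        if self.border_trim < 0:
            raise ValueError("border_trim must be >= 0")
        for name in ("kernel_rows", "kernel_cols"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1")
        if not 0.0 < self.area_fraction < 1.0:
            raise ValueError("area_fraction must be in (0, 1)")
        if self.max_recursion_depth < 1:
            raise ValueError("max_recursion_depth must be >= 1")
        if self.max_separator_width < 1:
            raise ValueError("max_separator_width must be >= 1")
        if self.count_mode not in ("lines", "indices"):
            raise ValueError("count_mode must be 'lines' or 'indices'")

    @property
    def intensity_threshold(self) -> float:
        """T of the high-intensity rule, on the 0..255 normalized scale."""
        return self.intensity_fraction * 255.0

    def replace(self, **changes) -> "FrameworkConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "FrameworkConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path) -> FrameworkConfig:
    """Read a YAML file whose keys mirror :class:`FrameworkConfig` fields."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return FrameworkConfig.from_dict(data)


def save_config(config: FrameworkConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
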