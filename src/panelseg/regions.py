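"""Axis-aligned panel regions and segmentation results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

REGULAR_BRANCH = "regular"
IRREGULAR_BRANCH = "irregular"
TRUTH_BRANCH = "truth"


@dataclass(frozen=True)
class PanelRegion:
    """A sub-image bounding box in the original image frame.

    Coordinates are 0-based and half-open: the region covers rows
    ``row_start <= r < row_end`` and columns ``col_start <= c < col_end``.
    ``depth`` records the recursion level that produced the region and
    ``branch`` the pipeline branch ("regular", "irregular" or "truth" for
    ground-truth boxes).
    """

    row_start: int
    row_end: int
    col_start: int
    col_end: int
    depth: int = 0
    branch: str = REGULAR_BRANCH

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValueError(f"invalid row extent [{self.row_start}, {self.row_end})")
        if not (0 <= self.col_start < self.col_end):
            raise ValueError(f"invalid col extent [{self.col_start}, {self.col_end})")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    @property
    def area(self) -> int:
        return self.height * self.width

    def intersection_area(self, other: "PanelRegion") -> int:
        dr = min(self.row_end, other.row_end) - max(self.row_start, other.row_start)
        dc = min(self.col_end, other.col_end) - max(self.col_start, other.col_start)
        return max(0, dr) * max(0, dc)

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_start : self.row_end, self.col_start : self.col_end]

    def to_dict(self) -> dict:
        return {
            "row_start": self.row_start,
            "row_end": self.row_end,
            "col_start": self.col_start,
            "col_end": self.col_end,
            "depth": self.depth,
            "branch": self.branch,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PanelRegion":
        return cls(
            row_start=int(data["row_start"]),
            row_end=int(data["row_end"]),
            col_start=int(data["col_start"]),
            col_end=int(data["col_end"]),
            depth=int(data.get("depth", 0)),
            branch=str(data.get("branch", REGULAR_BRANCH)),
        )


def regions_disjoint(regions: list[PanelRegion]) -> bool:
    """True when no two regions overlap (empty pairwise intersection)."""
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            if a.intersection_area(b) > 0:
                return False
    return True


@dataclass
class SegmentationResult:
    """Panel regions plus the corresponding crops of the source image."""

    regions: list[PanelRegion]
    crops: list[np.ndarray]
    source_class: Optional[object] = None
    fallback: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.crops):
            raise ValueError("regions and crops must correspond one-to-one")
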