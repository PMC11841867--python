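"""Pixel-level primitives shared by both segmentation branches.

Compound biomedical figures place panels on a (near-)white page, so the bands
separating panels show up as rows/columns whose summed intensity is close to
the maximum attainable value.  This module provides the operations both
branches build on: luminance grayscale conversion, outer-border trimming,
row/column projection profiles, and extraction of high-intensity index sets
together with their grouping into contiguous runs.

Conventions: images are ``numpy`` arrays of ``uint8``, rows before columns,
0-based indices; crops use half-open intervals while separator runs are stored
as inclusive ``(start, end)`` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FrameworkConfig
from .exceptions import DegenerateCropError, UnsupportedFormatError

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
GRAYSCALE_WEIGHTS = (0.2989, 0.5870, 0.1140)

HORIZONTAL = "horizontal"
VERTICAL = "vertical"


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale luminance.

    Each output pixel is ``round(0.2989*R + 0.5870*G + 0.1140*B)`` with
    round-half-up, clamped to [0, 255].  Grayscale input passes through
    unchanged.

    Raises
    ------
    UnsupportedFormatError
        If the image is neither single-channel nor 3-channel RGB.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        weights = np.asarray(GRAYSCALE_WEIGHTS, dtype=np.float64)
        lum = image.astype(np.float64) @ weights
        # round-half-up, then clamp to the 8-bit range
        return np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)
    raise UnsupportedFormatError(
        f"expected a 2-D grayscale or M x N x 3 RGB image, got shape {image.shape}"
    )


def trim_border(image: np.ndarray, margin: int) -> np.ndarray:
    """Return the interior crop with ``margin`` rows/columns removed per edge.

    Raises
    ------
    DegenerateCropError
        If ``2 * margin >= min(M, N)`` (nothing would remain).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return image
    m, n = image.shape[:2]
    if 2 * margin >= min(m, n):
        raise DegenerateCropError(
            f"margin {margin} leaves no interior in a {m}x{n} image"
        )
    return image[margin : m - margin, margin : n - margin]


@dataclass(frozen=True)
class ProjectionProfile:
    """Per-row (horizontal) or per-column (vertical) intensity sums.

    When ``normalized`` the sums are divided by the orthogonal dimension, so
    every value lies in [0, 255] for 8-bit input and an all-white separator
    band attains exactly 255 regardless of image size.
    """

    axis: str
    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        if self.axis not in (HORIZONTAL, VERTICAL):
            raise ValueError(f"axis must be '{HORIZONTAL}' or '{VERTICAL}'")


def projection_profile(
    image: np.ndarray, axis: str, normalize: bool = False
) -> ProjectionProfile:
    """Compute the row-sum (horizontal) or column-sum (vertical) profile.

    ``horizontal`` sums each row across its columns (length M); ``vertical``
    sums each column across its rows (length N).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise UnsupportedFormatError("projection profiles require a grayscale image")
    if image.size == 0:
        raise ValueError("cannot compute a projection profile of an empty image")
    m, n = image.shape
    if axis == HORIZONTAL:
        values = image.sum(axis=1, dtype=np.float64)
        if normalize:
            values = values / n
    elif axis == VERTICAL:
        values = image.sum(axis=0, dtype=np.float64)
        if normalize:
            values = values / m
    else:
        raise ValueError(f"axis must be '{HORIZONTAL}' or '{VERTICAL}'")
    return ProjectionProfile(axis=axis, values=values, normalized=normalize)


def group_runs(indices: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Group a sorted integer vector into maximal inclusive (start, end) runs."""
    indices = np.asarray(indices, dtype=np.intp)
    if indices.size == 0:
        return ()
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [indices.size - 1]))
    return tuple(
        (int(indices[s]), int(indices[e])) for s, e in zip(starts, ends)
    )


@dataclass(frozen=True)
class SeparatorIndexSet:
    """Rows (or columns) whose profile value exceeds the intensity threshold.

    ``indices`` is strictly increasing; ``runs`` partitions it into maximal
    contiguous inclusive intervals.  The number of raw indices and the number
    of *logical* separator lines (thin runs collapse to one) are both exposed
    because the two countings answer different questions: raw counts follow
    the printed decision rule, line counts are invariant to gutter width.
    """

    axis: str
    indices: tuple[int, ...]
    runs: tuple[tuple[int, int], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.runs is None:
            object.__setattr__(self, "runs", group_runs(np.asarray(self.indices)))

    @classmethod
    def from_indices(cls, indices, axis: str) -> "SeparatorIndexSet":
        idx = tuple(int(i) for i in indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing")
        return cls(axis=axis, indices=idx)

    @classmethod
    def from_runs(cls, runs, axis: str) -> "SeparatorIndexSet":
        """Build from inclusive (start, end) ranges, e.g. printed index spans."""
        indices: list[int] = []
        for start, end in runs:
            indices.extend(range(int(start), int(end) + 1))
        return cls.from_indices(indices, axis=axis)

    @property
    def count(self) -> int:
        """Number of individual high-intensity indices."""
        return len(self.indices)

    def line_count(self, max_separator_width: int) -> int:
        """Effective number of separator lines.

        A contiguous run no wider than ``max_separator_width`` is one physical
        gutter and counts as a single line; a wider run is not a crisp
        separator and contributes its raw index count.
        """
        total = 0
        for start, end in self.runs:
            width = end - start + 1
            total += 1 if width <= max_separator_width else width
        return total


def high_intensity_indices(
    profile: ProjectionProfile, config: FrameworkConfig
) -> SeparatorIndexSet:
    """Extract indices whose normalized profile value strictly exceeds T.

    ``T = intensity_fraction * 255``; equality stays below threshold.  The
    profile must be mean-normalized so T is independent of image size.
    """
    if not profile.normalized:
        raise ValueError("high-intensity extraction requires a normalized profile")
    t = config.intensity_threshold
    idx = np.flatnonzero(profile.values > t)
    return SeparatorIndexSet.from_indices(idx, axis=profile.axis)
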