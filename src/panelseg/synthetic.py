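"""Ground-truthed synthetic compound figures.

The generator emulates the three layout classes found in biomedical figure
collections: single-panel images, regular montages (an r x c grid of panels
separated by straight white gutters), and irregular mosaics (a handful of
panels of varying size placed on a white page with non-uniform gaps and
margins).  Panel content defaults to Gaussian noise with mean 120 and
standard deviation 30, mimicking the intensity statistics of a radiograph on
a white page so that a global threshold separates panels from background.

Every generated figure comes with its ground-truth panel boxes and the true
class label, making the classifier, both segmenters, and the evaluator
testable without access to curated figure collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ImageLabel
from .exceptions import PackingError
from .regions import TRUTH_BRANCH, PanelRegion

_MIN_PANEL_SIDE = 40


@dataclass(frozen=True)
class MontageSpec:
    """Full description of one synthetic figure.

    ``rows``/``cols``/``gutter_px`` apply to grid layouts; ``n_panels`` and
    ``jitter_px`` (perturbation of the recursive canvas partition) to
    irregular layouts.  Identical specs (including ``seed``) generate
    bit-identical images.
    """

    layout: str  # "single" | "grid" | "irregular"
    height: int = 256
    width: int = 256
    rows: int = 2
    cols: int = 2
    gutter_px: int = 6
    gutter_intensity: int = 255
    panel_texture: str = "gaussian-noise"  # "uniform" | "gaussian-noise" | "blob"
    panel_mean: float = 120.0
    panel_sd: float = 30.0
    n_panels: int = 4
    jitter_px: int = 12
    outer_margin: tuple[int, int] = (30, 40)
    inner_inset: tuple[int, int] = (16, 26)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("single", "grid", "irregular"):
            raise ValueError("layout must be 'single', 'grid' or 'irregular'")
        if self.panel_texture not in ("uniform", "gaussian-noise", "blob"):
            raise ValueError("unknown panel_texture")
        if self.height < 1 or self.width < 1:
            raise ValueError("canvas must be at least 1x1")
        if self.gutter_px < 0:
            raise ValueError("gutter_px must be >= 0")
        if not 0 <= self.panel_mean <= 255:
            raise ValueError("panel_mean must be in [0, 255]")
        if not 0 <= self.gutter_intensity <= 255:
            raise ValueError("gutter_intensity must be in [0, 255]")

    @classmethod
    def single(cls, seed: int = 0, *, height: int = 256, width: int = 256, **kw):
        return cls(layout="single", seed=seed, height=height, width=width, **kw)

    @classmethod
    def grid(
        cls,
        rows: int,
        cols: int,
        *,
        gutter_px: int = 6,
        seed: int = 0,
        height: int = 256,
        width: int = 256,
        **kw,
    ):
        return cls(
            layout="grid",
            rows=rows,
            cols=cols,
            gutter_px=gutter_px,
            seed=seed,
            height=height,
            width=width,
            **kw,
        )

    @classmethod
    def irregular(
        cls,
        n_panels: int,
        *,
        seed: int = 0,
        height: int = 600,
        width: int = 600,
        **kw,
    ):
        return cls(
            layout="irregular",
            n_panels=n_panels,
            seed=seed,
            height=height,
            width=width,
            **kw,
        )


def _fill_panel(canvas: np.ndarray, box: PanelRegion, spec: MontageSpec, rng) -> None:
    shape = (box.height, box.width)
    if spec.panel_texture == "uniform":
        patch = np.full(shape, round(spec.panel_mean), dtype=np.uint8)
    elif spec.panel_texture == "gaussian-noise":
        noise = rng.normal(spec.panel_mean, spec.panel_sd, size=shape)
        patch = np.clip(np.round(noise), 0, 255).astype(np.uint8)
    else:  # blob: flat panel with a few darker rectangles
        patch = np.full(shape, round(spec.panel_mean), dtype=np.uint8)
        for _ in range(rng.integers(3, 7)):
            bh = int(rng.integers(max(2, shape[0] // 8), max(3, shape[0] // 3)))
            bw = int(rng.integers(max(2, shape[1] // 8), max(3, shape[1] // 3)))
            r = int(rng.integers(0, max(1, shape[0] - bh)))
            c = int(rng.integers(0, max(1, shape[1] - bw)))
            level = int(rng.integers(0, max(1, int(spec.panel_mean * 0.7))))
            patch[r : r + bh, c : c + bw] = level
    canvas[box.row_start : box.row_end, box.col_start : box.col_end] = patch


def _grid_edges(total: int, parts: int, gutter: int) -> list[tuple[int, int]]:
    """Half-open panel extents along one axis of a gutter-separated grid."""
    panel_total = total - gutter * (parts - 1)
    if panel_total < parts:
        raise PackingError(
            f"{parts} panels with {gutter}-px gutters do not fit in {total} px"
        )
    base, rem = divmod(panel_total, parts)
    edges = []
    pos = 0
    for k in range(parts):
        size = base + (1 if k < rem else 0)
        edges.append((pos, pos + size))
        pos += size + gutter
    return edges


def _bsp_cells(
    rng, r0: int, r1: int, c0: int, c1: int, k: int, jitter: int
) -> list[tuple[int, int, int, int]]:
    """Recursively partition a rectangle into k cells with jittered splits."""
    if k == 1:
        return [(r0, r1, c0, c1)]
    h, w = r1 - r0, c1 - c0
    k1 = k // 2
    k2 = k - k1
    frac = k1 / k
    j = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
    if h >= w:
        cut = r0 + int(h * frac) + j
        cut = int(np.clip(cut, r0 + 1, r1 - 1))
        return _bsp_cells(rng, r0, cut, c0, c1, k1, jitter) + _bsp_cells(
            rng, cut, r1, c0, c1, k2, jitter
        )
    cut = c0 + int(w * frac) + j
    cut = int(np.clip(cut, c0 + 1, c1 - 1))
    return _bsp_cells(rng, r0, r1, c0, cut, k1, jitter) + _bsp_cells(
        rng, r0, r1, cut, c1, k2, jitter
    )


def generate(spec: MontageSpec) -> tuple[np.ndarray, list[PanelRegion], ImageLabel]:
    """Generate a synthetic figure with its ground truth.

    Returns ``(image, truth_boxes, label)`` where ``image`` is a 2-D uint8
    grayscale canvas, ``truth_boxes`` are pairwise-disjoint panel regions
    (branch "truth"), and ``label`` is the true class.  A 1 x 1 grid is a
    single panel and is labeled accordingly.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.height, spec.width

    if spec.layout == "single":
        canvas = np.zeros((m, n), dtype=np.uint8)
        box = PanelRegion(0, m, 0, n, branch=TRUTH_BRANCH)
        _fill_panel(canvas, box, spec, rng)
        return canvas, [box], ImageLabel.SINGLE_PANEL

    if spec.layout == "grid":
        canvas = np.full((m, n), spec.gutter_intensity, dtype=np.uint8)
        row_edges = _grid_edges(m, spec.rows, spec.gutter_px)
        col_edges = _grid_edges(n, spec.cols, spec.gutter_px)
        boxes = []
        for rs, re in row_edges:
            for cs, ce in col_edges:
                box = PanelRegion(rs, re, cs, ce, branch=TRUTH_BRANCH)
                _fill_panel(canvas, box, spec, rng)
                boxes.append(box)
        label = (
            ImageLabel.SINGLE_PANEL
            if spec.rows == 1 and spec.cols == 1
            else ImageLabel.MULTI_PANEL_REGULAR
        )
        return canvas, boxes, label

    # irregular: BSP partition into n_panels cells, then inset every panel by
    # a random margin so gaps are non-uniform, >= 2 * min(inner_inset) wide
    # between neighbours, with wide page margins at the canvas edge.
    if spec.n_panels < 2:
        raise PackingError("an irregular mosaic needs at least 2 panels")
    canvas = np.full((m, n), 255, dtype=np.uint8)
    cells = _bsp_cells(rng, 0, m, 0, n, spec.n_panels, spec.jitter_px)
    om_lo, om_hi = spec.outer_margin
    in_lo, in_hi = spec.inner_inset
    boxes = []
    for r0, r1, c0, c1 in cells:
        top = int(rng.integers(om_lo, om_hi + 1)) if r0 == 0 else int(
            rng.integers(in_lo, in_hi + 1)
        )
        bottom = int(rng.integers(om_lo, om_hi + 1)) if r1 == m else int(
            rng.integers(in_lo, in_hi + 1)
        )
        left = int(rng.integers(om_lo, om_hi + 1)) if c0 == 0 else int(
            rng.integers(in_lo, in_hi + 1)
        )
        right = int(rng.integers(om_lo, om_hi + 1)) if c1 == n else int(
            rng.integers(in_lo, in_hi + 1)
        )
        pr0, pr1 = r0 + top, r1 - bottom
        pc0, pc1 = c0 + left, c1 - right
        if pr1 - pr0 < _MIN_PANEL_SIDE or pc1 - pc0 < _MIN_PANEL_SIDE:
            raise PackingError(
                f"canvas {m}x{n} too small for {spec.n_panels} panels with the "
                f"requested margins"
            )
        box = PanelRegion(pr0, pr1, pc0, pc1, branch=TRUTH_BRANCH)
        _fill_panel(canvas, box, spec, rng)
        boxes.append(box)
    return canvas, boxes, ImageLabel.MULTI_PANEL_IRREGULAR
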