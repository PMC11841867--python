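# Methods

## Problem and model

Roughly half the figures in the biomedical literature are compound
(multi-panel) images; retrieval systems that index whole figures cannot
return their constituent panels.  `panelseg` implements a two-stage
classical-computer-vision pipeline:

1. **Type identification.**  The figure is converted to grayscale
   (`I = 0.2989 R + 0.5870 G + 0.1140 B`, round-half-up), a small outer
   border is trimmed, and mean-normalized projection profiles are computed:
   `H(i) = (1/N) Σ_j I(i, j)` over rows and `V(j) = (1/M) Σ_i I(i, j)` over
   columns.  Rows/columns with profile values strictly above
   `T = intensity_fraction · 255` form the horizontal/vertical separator
   index sets (HLV/VLV).  Empty sets on both axes mean a **single-panel**
   image.  Otherwise the image is **regular multi-panel** when the larger
   per-axis separator-line count is at most `threshold_comp` (default 5)
   and **irregular multi-panel** otherwise.

2. **Segmentation.**  Regular montages are cut recursively at their
   separator runs along the axis with more separator indices (horizontal
   when `|HLV| > |VLV|`, vertical otherwise), discarding the separator
   bands, trimming one pixel from each new segment edge, and recursing on
   each segment until no separators remain or `max_recursion_depth` is
   reached.  Irregular montages are binarized at Otsu's threshold, polarity
   is normalized so panels are foreground, small holes are filled with a
   morphological closing, 8-connected components are labeled, and
   components whose foreground area exceeds `area_fraction · M · N` are
   emitted as panel bounding boxes.

The key assumption throughout is a light (page-white) background with
panels darker than the separators.  Figures with dark or absent
backgrounds are explicitly outside the model.

## Separator counting

Printed separator positions in compound figures come in two flavours:
crisp gutters one to a couple of dozen pixels wide, and wide white
expanses (page margins, empty canvas) that span tens to hundreds of
indices.  A raw count of high-intensity indices conflates gutter *width*
with gutter *number*: a single 20-px gutter would count as 20 separator
lines and push a perfectly regular 2×2 montage over `threshold_comp`.

The decision rule therefore uses **effective line counts**: each maximal
contiguous run of high-intensity indices no wider than
`max_separator_width` (default 24 px) counts as one logical separator
line, while wider runs contribute their raw index count — a white band
wider than any plausible gutter is not a separator but a sign of an
irregular layout.  Both countings are recorded on the returned
`ImageClass` (`total_horizontal`/`total_vertical` raw,
`lines_horizontal`/`lines_vertical` effective), and
`count_mode="indices"` switches the decision to raw counting.  The default
of 24 px sits above the widest gutters the generator produces (20 px) and
below the margin widths that characterize irregular layouts; it
reproduces the worked decisions of the published examples under both
countings.

## Threshold T

The separator threshold is defined on *mean-normalized* profiles, so
`T = intensity_fraction × 255` is independent of image size and a
full-width pure-white gutter attains exactly 255.  The default
`intensity_fraction = 0.95` (T ≈ 242) tolerates mild JPEG ringing in
gutters while comfortably rejecting panel content.  Comparison is strictly
greater-than; equality stays below threshold.

## Parameters

| parameter             | default | units | role                                         |
| --------------------- | ------- | ----- | -------------------------------------------- |
| `threshold_single`    | 0       | count | max separator indices for single-panel       |
| `threshold_comp`      | 5       | count | max per-axis separator lines for regular     |
| `intensity_fraction`  | 0.95    | —     | separator threshold as fraction of 255       |
| `border_trim`         | 2       | px    | outer-edge trim before profiles              |
| `min_panel_extent`    | 16      | px    | minimum side of an emitted panel             |
| `kernel_rows/cols`    | 29×29   | px    | closing structuring element (must be odd)    |
| `area_fraction`       | 0.02    | —     | component area floor, relative to image area |
| `max_recursion_depth` | 4       | —     | bound on alternating cuts                    |
| `max_separator_width` | 24      | px    | run width above which a band is not a gutter |

The closing kernel matters geometrically: closing bridges any background
gap narrower than the kernel, so panels closer than 29 px merge into one
component.  The area floor is relative to image size rather than absolute,
which keeps behaviour stable across figure resolutions.

## Numerical choices

- Grayscale conversion rounds half-up and clamps to [0, 255].
- Otsu's threshold is computed vectorized over the 256-bin histogram; the
  *lowest* maximizer of the between-class variance is returned, and the
  class convention is pixels `<= t` → background.  A constant image has no
  two-class split: 0 is returned with a warning.
- Dilation/erosion use rectangular neighborhoods clipped at the image
  boundary (edge replication), which keeps closing extensive and
  idempotent.
- Coordinates are 0-based, rows before columns; crops are half-open
  intervals, separator runs inclusive `(start, end)` pairs.
- Cuts happen at run *boundaries* and the separator band is discarded;
  cutting at every individual high-intensity index would manufacture
  sliver "panels" inside wide gutters.
- Each segment produced by a cut is trimmed by 1 px on all four sides
  (the per-segment boundary computation); the degenerate no-runs case
  returns the untrimmed full extent.
- Ties in the cut-axis choice go to vertical.
- Greedy evaluation matching is one-to-one, truths in order, largest
  positive overlap first, earlier prediction index on ties; a prediction
  with zero overlap is never consumed.  Overlap exactly two-thirds is
  *not* correct (strict inequality).

## Synthetic study conditions

The generator produces the three layout classes with ground truth:

- **single**: one full-canvas panel (256×256 default).
- **grid**: r×c panels flush to the canvas edge, separated by straight
  gutters of uniform width at intensity 255 (256×256 default).  A 1×1
  "grid" is labeled single-panel.
- **irregular**: 2–6 panels on a white 600×600 canvas, placed by a
  jittered recursive binary partition; outer page margins are 30–40 px and
  inter-panel gaps at least 32 px (two 16-px insets), so gaps survive the
  29×29 closing and margins exceed `max_separator_width`, as in real
  mosaics where margins are much wider than gutters.

Panel content defaults to Gaussian noise with mean 120 and SD 30,
emulating radiograph-on-white-page intensity statistics: clearly darker
than separators, clearly separable from white by a global threshold.
Uniform and blob textures are available.  Generation is bit-reproducible
from `(spec, seed)`.

What the generator does **not** emulate: panel captions and label letters
inside gutters, JPEG compression artifacts, hairline black separator
strokes, panels brighter than the background, dark-background figures,
non-rectangular panels, and touching (zero-gap) stitched panels.  Passing
recovery tests on these conditions therefore demonstrates correctness of
the algorithmic machinery under the model's assumptions, not performance
on curated figure collections.

## Problem sizes

Randomized recovery checks use 100 seeded grid montages (r, c ∈ {1..4},
gutters 5–20 px) and 100 seeded irregular mosaics (2–6 panels), with
smaller batches in the unit suite; oracle-equivalence checks use
32×32 random images against naive exhaustive references.  These sizes give
stable pooled precision/recall while keeping the whole suite fast.

## Known limitations

- An irregular montage with no white gaps at all yields empty HLV/VLV and
  is classified single-panel; the decision rule has no signal to work
  with.  (Real irregular figures are rescued by their white margins.)
- Components whose bounding boxes overlap are emitted as-is, not merged.
- Wide-gutter vs. margin discrimination is a width heuristic
  (`max_separator_width`); montages with gutters wider than page margins
  would be misrouted.
- Only 8-bit grayscale/RGB input; no alpha, no 16-bit, no DICOM.
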