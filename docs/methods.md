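# Methods

## Background model and the flood-fill fixpoint

The extraction step assumes a scene whose background (a) touches the image
border everywhere along the frame, and (b) varies smoothly — adjacent
background pixels differ by much less than the color step from background to
fruit. Under those assumptions the background is exactly the set of pixels
reachable from the border through small color steps, which is what the
floating-range flood fill computes: the least set containing all border
pixels and closed under "neighbor at color distance < δ".

Implementation notes:

- The fixpoint is computed by frontier propagation: each iteration marks, in
  one vectorized pass per neighbor offset, every unmarked pixel adjacent to
  the current wavefront at distance < δ. Because set union is monotone and
  the marking rule is local, the fixpoint is independent of traversal order;
  the test suite verifies equality with a deliberately naive full-image-sweep
  oracle on randomized small images.
- The inequality is strict. δ = 0 therefore marks nothing beyond the border
  seeds, and for a threshold exactly equal to an adjacent-pair distance the
  pair does not merge (the 5×5 concentric test pins this at √1200 ≈ 34.64).
- Distances are computed in raw RGB; no color-space conversion is applied.
  Euclidean distance is the default metric, with per-channel-maximum
  (Chebyshev) available because several imaging toolkits express flood
  tolerances as per-channel bounds.
- 4-connectivity is the default (the 4-fill is always contained in the
  8-fill at equal threshold, so it is the conservative choice against
  leakage through diagonal gaps); 8 is selectable.
- A fixed-range variant (all candidates compared against the mean border
  color) is available behind `FloodParams(floating_range=False)` but off by
  default: it cannot follow background gradients, which is the common case
  in natural photographs.
- Degenerate 1×N / N×1 images are legal: every pixel is a border pixel and
  hence background.
- Extraction writes PNG. JPEG output would recompress and break the
  guarantee that non-background pixels are bit-identical to the input.

δ has no universal default. It must lie strictly between the largest
adjacent-pixel step inside the background and the smallest
background-to-foreground step, both of which depend on the imagery; the CLI
therefore requires `--max-distance` explicitly. For the synthetic scenes
the construction guarantees the open interval (55, 120), and the examples
use its midpoint 87.5.

## Augmentation geometry

The augmentation set is exactly five variants — identity, rotations by 90°,
180°, 270°, and a flip — so 400 annotated sources become 2000 images.
Rotations are counter-clockwise and the flip is horizontal; both choices are
conventions only (the *set* of augmented images is the same either way, and a
vertical flip equals rot180 ∘ hflip, so adding it would leave the five-variant
count behind). Under the CCW 90° rotation of a W-wide image a point (x, y)
maps to (y, W − x); boxes, kept half-open, transform by interval arithmetic
and are validated against a mask-rasterization oracle (rasterize the box,
permute the pixels, take the tight box) in the tests. Because every variant
is a pixel permutation and the flood fill seeds from the entire border,
augmentation and extraction commute exactly; the pipeline runs augmentation
first by default and exposes the other order as an option.

## Annotation conventions

labelimg's VOC XML uses 1-based inclusive pixel coordinates; internally all
boxes are 0-based half-open (x0 = xmin − 1, x1 = xmax), making widths plain
differences and the VOC round trip exact. YOLO labels store normalized
center/extent and are serialized with 6 decimals, so a YOLO round trip is
exact to within 0.5 px at any realistic image size. Boxes overflowing the
stated image size are clipped with a logged warning; inverted extents are
errors. Zero-object label files are empty files. Grade names default to
`grade_1..grade_4`; the name↔index map applies only at YOLO conversion, and
unknown grade names in VOC are carried verbatim.

## Dataset pipeline

The split is grouped by source image and stratified by grade: per grade,
`round(0.8 · n_sources)` randomly chosen source groups (all five variants
together) go to training. Grouping prevents an augmented copy of a test
photo from appearing in training — a leakage channel that per-image
splitting would open — while preserving the 1600/400 shape at 100 sources
per grade. When a test partition is required, every grade needs at least two
source groups, and the train count is clamped so neither side is empty. All
randomness flows through a single recorded seed; a rerun with identical
configuration reproduces a byte-identical manifest.

## Detection metrics

Matching is greedy in descending confidence (ties broken by input order, the
de-facto VOC/COCO convention): each detection claims the highest-IoU
unmatched same-class, same-image ground truth with IoU ≥ threshold. AP
integrates the precision envelope (max precision at any recall ≥ r) over
recall — all-point interpolation — with COCO's 101-point grid available
behind a flag; on dense curves the two differ by well under 0.02. Vacuous
cases are defined explicitly: no detections gives precision 1.0; no ground
truth and no false positives gives recall 1.0; a class present only in the
detections is excluded from the macro-average and reported in
`ignored_classes`. AP@[0.5:0.95] is the mean over thresholds 0.50 to 0.95
in steps of 0.05.

## Synthetic scenes: what they emulate and what they do not

Each scene is one roughly elliptical fruit with a stem on a smoothly shaded
background; the four grades differ in peel color (bright red → dull dark
red), defect-spot count (0, 1, 3, 6) and fruit size, standing in for the
external indicators a human grader uses. The scenes are 96×96 px by
default — large enough for non-trivial geometry, small enough that building
the full 2000-image dataset stays fast on one CPU.

The generator is built around a separation-margin guarantee rather than
realism: background gradient steps plus 3σ-truncated noise keep any adjacent
background pair below 55 intensity units of Euclidean distance, while every
foreground color is at least 120 units from every possible background color.
Any flood threshold in (55, 120) therefore recovers the ground-truth mask
*exactly* on noise-free scenes, making flood-fill correctness provable per
fixture rather than approximate. Default background noise is σ = 2 per
channel, at which recovery remains pixel-perfect or nearly so (mask IoU
≥ 0.99 over 100 random scenes).

Consequences for interpretation: passing tests demonstrate the algorithmic
contracts (fixpoint correctness, geometric consistency, conversion
exactness, metric definitions), not performance on real orchard photographs,
whose backgrounds violate the margin construction (hard shadows, adjacent
fruit, textured foliage). The grade parameters are visual stand-ins, not
calibrated to real cherries, and no claim about a trained detector's
accuracy follows from them. Training a detector is explicitly out of scope;
the output layout is merely detector-ready.

The mock detector exists to exercise the metrics: at quality 1 it emits the
ground truth verbatim with confidence 1 (all four report numbers exactly
1.0); lower quality drops ground truths with probability 1 − q, jitters
surviving boxes proportionally to 1 − q, and injects false positives at
Poisson rate 2(1 − q) per ground truth, so precision, recall and AP degrade
monotonically in expectation.

## Problem sizes

The acceptance script builds the full 400-source / 2000-image dataset,
measures noise-free exact recovery on 40 scenes and noisy mask IoU on 100
scenes, and evaluates the mock detector on a 40-scene collection; the whole
run completes in well under a minute on one CPU.
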