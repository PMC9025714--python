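# cherryprep

Dataset preparation and evaluation tooling for fruit-quality object
detection, built around **edge-seeded, floating-range flood-fill background
extraction**.

Grading cherries by eye is slow and inconsistent, so a natural approach is
to photograph the fruit and train an object detector on images labeled with
one of four external quality grades. Photographs taken across seasons and
environments carry background clutter that the detector must learn to
ignore, which slows training and hurts accuracy. `cherryprep` removes that
clutter *before* training: it whitens everything connected to the image
border whose color varies smoothly, leaving only the fruit, and then builds
a complete detector-ready dataset (augmentation, annotation conversion,
train/test split) around the extracted images.

## The core algorithm

Let `I : Ω → [0,255]³` be an RGB image and `d(·,·)` a color distance
(Euclidean in RGB by default). The background mask `B ⊆ Ω` is the least
fixpoint of

1. every border pixel of `Ω` is in `B`;
2. if `p ∈ B` and `q` is a 4- (or 8-) neighbor of `p` with
   `d(I(p), I(q)) < δ`, then `q ∈ B` (strict inequality),

where `δ` (`max_distance`) is the algorithm's single tuning parameter.
Because the distance is measured between *adjacent* pixels rather than
against a fixed seed color (a floating-range fill), the region chains across
smooth background gradients and stops exactly at the sharp color step onto
the fruit. Pixels in `B` are filled white; all other pixels are preserved
bit-for-bit.

Around this core the package provides:

- **`cherryprep.geometry`** — the five-variant augmentation set (identity,
  90°/180°/270° CCW rotations, horizontal flip) applied consistently to
  images and their bounding boxes; all variants are exact pixel
  permutations.
- **`cherryprep.annotations`** — labelimg-dialect Pascal VOC XML parsing and
  writing, and exact VOC ↔ YOLO label conversion (internally all boxes are
  0-based half-open pixel intervals).
- **`cherryprep.pipeline`** — the full build: extract → augment → convert →
  grouped, grade-stratified 4:1 train/test split, written out as a
  YOLOv5-style `images/`, `labels/`, `dataset.yaml` layout with a manifest.
- **`cherryprep.metrics`** — detection evaluation: IoU, greedy
  confidence-ordered matching, precision/recall, AP@0.5 and AP@[0.5:0.95]
  with all-point (default) or 101-point interpolation.
- **`cherryprep.synthetic`** — a cherry-scene generator with exact
  ground-truth masks and boxes, built so that flood-fill correctness is
  provable per scene, plus a quality-controllable mock detector for
  exercising the metrics end to end.

## Worked example

Generate 100 synthetic annotated scenes per grade and build the dataset:

```sh
cherryprep synth --n-per-grade 100 --out work/src --seed 17
cherryprep prepare --in work/src --out work/ds --max-distance 87.5 --seed 17
```

which prints

```
wrote 400 annotated scenes -> work/src
2000 images (1600 train / 400 test); per grade: {'grade_1': 500, 'grade_2': 500, 'grade_3': 500, 'grade_4': 500}
```

400 sources × 5 augmentation variants = 2000 background-extracted images,
500 per grade; the grouped stratified split puts four fifths (1600) in
training and one fifth (400) in test, with all five variants of any source
always on the same side. The threshold 87.5 sits midway between the
synthetic scenes' background-step bound (55) and their guaranteed
foreground/background separation margin (120), so extraction is exact on
noise-free scenes.

From Python, scoring a perfect detector against ground truth:

```python
from cherryprep import synthetic, metrics

records = synthetic.generate_dataset(n_per_grade=10, out_dir="work/eval", seed=5)
gts = synthetic.ground_truths_from_records(records)
report = metrics.evaluate(synthetic.mock_detector(gts, quality=1.0, seed=0), gts)
print(report.precision, report.recall, report.ap50, report.ap50_95)
# 1.0 1.0 1.0 1.0
```

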