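"""Synthetic cherry scenes with exact ground truth.

Each scene is a single roughly elliptical fruit with a stem on a smoothly
varying, border-connected background.  Four quality grades are emulated
through the external indicators a grader would use — peel color (bright red
through dull dark red), surface defects (dark spots, more per grade), and
size — so the grades are visually separable detection classes, not
calibrated models of real cherries.

The scenes are built around a *separation-margin* guarantee rather than
photorealism: parameters are chosen so that

* any two adjacent background pixels differ by less than half the margin
  (background gradient steps are tiny and the additive noise is truncated),
* every foreground/background adjacency differs by more than the margin.

An edge-seeded floating-range flood fill with ``max_distance`` anywhere
between the background step bound and the margin therefore recovers the
ground-truth foreground mask exactly on noise-free scenes — correctness is
provable per fixture, and the noise/gradient knobs become stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .annotations import DEFAULT_GRADES, BoundingBox, GradeMap, write_voc
from .metrics import Detection, GroundTruth

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "default_spec",
    "generate_scene",
    "generate_dataset",
    "mock_detector",
    "SEPARATION_MARGIN",
    "BACKGROUND_STEP_BOUND",
]

#: Guaranteed minimum color distance across any foreground/background edge.
SEPARATION_MARGIN = 120.0
#: Upper bound on the color distance between adjacent background pixels
#: (gradient step + truncated noise), kept below SEPARATION_MARGIN / 2.
BACKGROUND_STEP_BOUND = 55.0

# Grade-dependent appearance: peel color darkens and dulls, defect spots
# accumulate, fruit shrinks slightly with falling grade.
_GRADE_STYLE = {
    1: {"fruit_color": (205, 30, 45), "n_defects": 0, "radius_scale": 1.00},
    2: {"fruit_color": (180, 35, 40), "n_defects": 1, "radius_scale": 0.95},
    3: {"fruit_color": (150, 40, 35), "n_defects": 3, "radius_scale": 0.88},
    4: {"fruit_color": (105, 35, 30), "n_defects": 6, "radius_scale": 0.80},
}
_DEFECT_COLOR = (55, 30, 20)
_STEM_COLOR = (80, 60, 25)
_BACKGROUND_BASE = (185, 195, 175)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``noise_sigma`` is the standard deviation of the additive background
    noise (truncated at 3 sigma per channel); ``gradient_amplitude`` the
    total linear background shading across the image, per channel.
    """

    width: int = 96
    height: int = 96
    grade: int = 1
    center: tuple[float, float] = (48.0, 52.0)  # (cx, cy)
    axes: tuple[float, float] = (26.0, 21.0)  # (semi-major, semi-minor)
    angle: float = 0.3  # radians, ellipse orientation
    stem_length: float = 14.0
    stem_width: float = 2.0
    background_base: tuple[int, int, int] = _BACKGROUND_BASE
    gradient_amplitude: float = 14.0
    noise_sigma: float = 2.0
    separation_margin: float = SEPARATION_MARGIN

    def __post_init__(self) -> None:
        if self.grade not in _GRADE_STYLE:
            raise ValueError(f"grade must be 1..4, got {self.grade}")
        if self.separation_margin <= 0:
            raise ValueError("separation_margin must be positive")
        cx, cy = self.center
        a = max(self.axes)
        # fruit + stem must stay >= 2 px inside the border so the background
        # remains border-connected
        reach = a + self.stem_length
        if (
            cx - reach < 2
            or cy - reach < 2
            or cx + reach > self.width - 2
            or cy + reach > self.height - 2
        ):
            raise ValueError(
                f"fruit geometry (reach {reach:.1f} from center {self.center}) "
                f"violates the 2-px border margin of a {self.width}x{self.height} scene"
            )


@dataclass
class SceneTruth:
    """Exact ground truth of a rendered scene."""

    mask: np.ndarray  # (H, W) bool, True = foreground (fruit + stem)
    box: BoundingBox  # tight box of the mask
    grade: int


def default_spec(grade: int = 1, **overrides) -> SceneSpec:
    """A centered scene spec for ``grade`` with the default geometry."""
    return replace(SceneSpec(grade=grade), **overrides)


def _ellipse_mask(spec: SceneSpec, scale: float = 1.0) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cx, cy = spec.center
    a, b = spec.axes[0] * scale, spec.axes[1] * scale
    c, s = np.cos(spec.angle), np.sin(spec.angle)
    u = (xx - cx) * c + (yy - cy) * s
    v = -(xx - cx) * s + (yy - cy) * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _stem_mask(spec: SceneSpec) -> np.ndarray:
    # stem rises from the fruit top along the minor axis direction
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cx, cy = spec.center
    c, s = np.cos(spec.angle), np.sin(spec.angle)
    # top point of the ellipse in image coordinates
    tx, ty = cx + s * spec.axes[1], cy - c * spec.axes[1]
    # stem direction: straight up
    dx, dy = xx - tx, ty - yy
    along = dy
    across = np.abs(dx)
    return (0 <= along) & (along <= spec.stem_length) & (across <= spec.stem_width / 2)


def generate_scene(spec: SceneSpec, seed: int) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene; deterministic for a given ``(spec, seed)``.

    Returns the uint8 RGB image and its exact :class:`SceneTruth` (foreground
    mask, tight bounding box, grade).
    """
    rng = np.random.default_rng(seed)
    style = _GRADE_STYLE[spec.grade]
    h, w = spec.height, spec.width

    # background: base + linear gradient + truncated gaussian noise
    base = np.asarray(spec.background_base, dtype=np.float64)
    gx = np.linspace(0, 1, w)[None, :, None]
    gy = np.linspace(0, 1, h)[:, None, None]
    direction = rng.uniform(0, 1)
    gradient = spec.gradient_amplitude * (direction * gx + (1 - direction) * gy - 0.5)
    img = np.broadcast_to(base, (h, w, 3)) + gradient
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=(h, w, 3))
        clip = 3.0 * spec.noise_sigma
        img = img + np.clip(noise, -clip, clip)

    fruit = _ellipse_mask(spec, scale=style["radius_scale"])
    stem = _stem_mask(spec)
    fg = fruit | stem

    img[fruit] = np.asarray(style["fruit_color"], dtype=np.float64)
    # gentle radial shading on the peel (kept small so the margin holds)
    shade = _ellipse_mask(spec, scale=style["radius_scale"] * 0.55)
    img[shade] = np.asarray(style["fruit_color"], dtype=np.float64) + 18.0
    img[stem & ~fruit] = np.asarray(_STEM_COLOR, dtype=np.float64)

    # defect spots: small dark discs fully inside the fruit
    inner = _ellipse_mask(spec, scale=style["radius_scale"] * 0.7)
    ys, xs = np.nonzero(inner)
    for _ in range(style["n_defects"]):
        if len(ys) == 0:
            break
        k = rng.integers(len(ys))
        r = rng.uniform(1.5, 3.0)
        yy, xx = np.mgrid[0:h, 0:w]
        spot = (xx - xs[k]) ** 2 + (yy - ys[k]) ** 2 <= r**2
        img[spot & fruit] = np.asarray(_DEFECT_COLOR, dtype=np.float64)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ys, xs = np.nonzero(fg)
    box = BoundingBox(
        grade=DEFAULT_GRADES[spec.grade - 1],
        x0=float(xs.min()),
        x1=float(xs.max() + 1),
        y0=float(ys.min()),
        y1=float(ys.max() + 1),
    )
    return image, SceneTruth(mask=fg, box=box, grade=spec.grade)


def random_spec(
    grade: int,
    rng: np.random.Generator,
    width: int = 96,
    height: int = 96,
    noise_sigma: float | None = None,
) -> SceneSpec:
    """Draw a scene spec within grade-specific parameter ranges."""
    a = rng.uniform(20, 27)
    b = a * rng.uniform(0.75, 0.95)
    stem = rng.uniform(10, 15)
    reach = a + stem
    cx = rng.uniform(2 + reach, width - 2 - reach)
    cy = rng.uniform(2 + reach, height - 2 - reach)
    spec = SceneSpec(
        width=width,
        height=height,
        grade=grade,
        center=(cx, cy),
        axes=(a, b),
        angle=rng.uniform(0, np.pi),
        stem_length=stem,
        stem_width=rng.uniform(1.5, 2.5),
        gradient_amplitude=rng.uniform(8, 16),
    )
    if noise_sigma is not None:
        spec = replace(spec, noise_sigma=noise_sigma)
    return spec


def generate_dataset(
    n_per_grade: int, out_dir, seed: int, noise_sigma: float | None = None
) -> list[dict]:
    """Write ``n_per_grade x 4`` annotated scenes to ``out_dir``.

    Produces ``images/<id>.png`` and ``annotations/<id>.xml`` (labelimg
    VOC), one fruit per image.  Returns a record per scene (id, grade,
    paths).  With ``n_per_grade=100`` this emulates a 400-source collection,
    100 per grade.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    out = Path(out_dir)
    img_dir = out / "images"
    ann_dir = out / "annotations"
    img_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    records = []
    for grade in (1, 2, 3, 4):
        for i in range(n_per_grade):
            scene_id = f"cherry_g{grade}_{i:04d}"
            spec = random_spec(grade, rng, noise_sigma=noise_sigma)
            image, truth = generate_scene(spec, seed=int(rng.integers(2**31)))
            img_path = img_dir / f"{scene_id}.png"
            Image.fromarray(image).save(img_path)
            write_voc(
                filename=img_path.name,
                width=spec.width,
                height=spec.height,
                boxes=[truth.box],
                path=ann_dir / f"{scene_id}.xml",
            )
            records.append(
                {
                    "id": scene_id,
                    "grade": truth.box.grade,
                    "image": str(img_path),
                    "annotation": str(ann_dir / f"{scene_id}.xml"),
                }
            )
    return records


def mock_detector(gts, quality: float, seed: int) -> list[Detection]:
    """Emit detections of controllable quality against ground truth.

    ``quality=1`` reproduces the ground truth verbatim with confidence 1, so
    every evaluation metric is exactly 1.  As ``quality`` falls, ground
    truths are missed with probability ``1 - quality``, surviving boxes are
    jittered proportionally to ``1 - quality``, and false positives are
    injected at a rate proportional to ``1 - quality`` — recall, precision
    and AP all degrade monotonically in expectation.

    ``gts`` is a list of :class:`cherryprep.metrics.GroundTruth`.
    """
    if not 0 <= quality <= 1:
        raise ValueError(f"quality must be in [0,1], got {quality}")
    rng = np.random.default_rng(seed)
    dets: list[Detection] = []
    miss = 1.0 - quality
    for g in gts:
        if quality == 1.0:
            dets.append(
                Detection(
                    image_id=g.image_id,
                    class_index=g.class_index,
                    confidence=1.0,
                    box=g.box,
                )
            )
            continue
        if rng.uniform() < miss:
            continue
        jitter = miss * 0.35
        dx = rng.normal(0, jitter * g.box.width)
        dy = rng.normal(0, jitter * g.box.height)
        sw = max(0.2, 1 + rng.normal(0, jitter))
        sh = max(0.2, 1 + rng.normal(0, jitter))
        cx = (g.box.x0 + g.box.x1) / 2 + dx
        cy = (g.box.y0 + g.box.y1) / 2 + dy
        hw = g.box.width * sw / 2
        hh = g.box.height * sh / 2
        box = BoundingBox(
            grade=g.box.grade, x0=cx - hw, x1=cx + hw, y0=cy - hh, y1=cy + hh
        )
        conf = float(np.clip(quality + rng.normal(0, 0.1), 0.0, 1.0))
        dets.append(
            Detection(
                image_id=g.image_id,
                class_index=g.class_index,
                confidence=conf,
                box=box,
            )
        )
    # false positives: random boxes on random annotated images
    if miss > 0 and gts:
        n_fp = rng.poisson(2.0 * miss * len(gts))
        for _ in range(n_fp):
            g = gts[rng.integers(len(gts))]
            ci = int(rng.integers(4))
            w = rng.uniform(5, 25)
            h = rng.uniform(5, 25)
            x0 = rng.uniform(0, 70)
            y0 = rng.uniform(0, 70)
            dets.append(
                Detection(
                    image_id=g.image_id,
                    class_index=ci,
                    confidence=float(rng.uniform(0, max(quality, 0.3))),
                    box=BoundingBox(
                        grade=DEFAULT_GRADES[ci],
                        x0=x0,
                        x1=x0 + w,
                        y0=y0,
                        y1=y0 + h,
                    ),
                )
            )
    return dets


def ground_truths_from_records(records, grades: GradeMap | None = None) -> list[GroundTruth]:
    """Read back VOC annotations written by :func:`generate_dataset`."""
    from .annotations import parse_voc

    grades = grades or GradeMap()
    gts = []
    for rec in records:
        _, _, _, boxes = parse_voc(rec["annotation"])
        for b in boxes:
            gts.append(
                GroundTruth(
                    image_id=rec["id"], class_index=grades.index(b.grade), box=b
                )
            )
    return gts
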