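"""Dataset construction: extract, augment, convert, split, lay out on disk.

Reproduces the detection-dataset build: annotated source photos are expanded
into five right-angle variants each, the flood fill whitens the background,
boxes are converted to YOLO labels, and the items are partitioned 4:1 into
train/test.  With 400 annotated sources (100 per grade) the build yields
2000 images, 500 per grade, 1600 train / 400 test.

The split is *grouped by source* (all five variants of a photo land in the
same partition, so no augmented copy of a test photo leaks into training)
and *stratified by grade* (each grade contributes 4/5 of its sources to
training).  All randomness flows through one recorded seed, so a rerun with
identical configuration reproduces a byte-identical manifest.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .annotations import (
    BoundingBox,
    GradeMap,
    parse_voc,
    to_yolo,
    write_dataset_yaml,
    write_yolo_file,
)
from .flood import FloodParams, extract_foreground
from .geometry import VARIANT_SUFFIXES, augment_set

__all__ = ["ManifestItem", "DatasetManifest", "split_dataset", "prepare_dataset"]

logger = logging.getLogger(__name__)

MANIFEST_FIELDS = ("source_id", "variant", "grade", "image", "label", "partition")


@dataclass(frozen=True)
class ManifestItem:
    source_id: str
    variant: str
    grade: str
    image: str
    label: str
    partition: str = ""


@dataclass
class DatasetManifest:
    items: list[ManifestItem]
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {}
        for it in self.items:
            c[it.grade] = c.get(it.grade, 0) + 1
        return c

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(MANIFEST_FIELDS + ("seed",))
            for it in self.items:
                writer.writerow(
                    [it.source_id, it.variant, it.grade, it.image, it.label, it.partition, self.seed]
                )


def split_dataset(
    items: list[ManifestItem],
    train_fraction: float = 0.8,
    seed: int = 0,
    require_test: bool = True,
) -> list[ManifestItem]:
    """Assign each item a train/test partition, grouped and stratified.

    Items sharing a ``source_id`` always land in the same partition; within
    each grade, ``round(train_fraction * n_sources)`` source groups go to
    training.  Deterministic for a given seed.  With ``require_test`` (the
    default) a grade must have at least 2 source groups so both partitions
    are non-empty; pass ``require_test=False`` for degenerate splits such as
    ``train_fraction=1``.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError(f"train_fraction must be in (0,1], got {train_fraction}")
    by_grade: dict[str, list[str]] = {}
    seen: set[str] = set()
    for it in items:
        if it.source_id not in seen:
            seen.add(it.source_id)
            by_grade.setdefault(it.grade, []).append(it.source_id)

    rng = np.random.default_rng(seed)
    train_sources: set[str] = set()
    for grade in sorted(by_grade):
        sources = sorted(by_grade[grade])
        if require_test and len(sources) < 2:
            raise ValueError(
                f"grade {grade!r} has {len(sources)} source group(s); "
                "need >= 2 to populate both partitions"
            )
        n_train = int(round(train_fraction * len(sources)))
        if require_test:
            n_train = min(n_train, len(sources) - 1)
            n_train = max(n_train, 1)
        perm = rng.permutation(len(sources))
        train_sources.update(sources[i] for i in perm[:n_train])

    return [
        ManifestItem(
            source_id=it.source_id,
            variant=it.variant,
            grade=it.grade,
            image=it.image,
            label=it.label,
            partition="train" if it.source_id in train_sources else "test",
        )
        for it in items
    ]


def _load_sources(image_dir: Path, ann_dir: Path, on_missing: str):
    sources = []
    for img_path in sorted(image_dir.iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        ann_path = ann_dir / (img_path.stem + ".xml")
        if not ann_path.exists():
            msg = f"image {img_path.name} has no annotation; skipped"
            if on_missing == "error":
                raise FileNotFoundError(msg)
            logger.warning(msg)
            continue
        sources.append((img_path, ann_path))
    return sources


def prepare_dataset(
    image_dir,
    ann_dir,
    out_dir,
    flood_params: FloodParams | None,
    grades: GradeMap | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    augment: bool = True,
    extract: bool = True,
    order: str = "augment-then-extract",
    on_missing_annotation: str = "warn",
) -> DatasetManifest:
    """Build a detector-ready dataset layout from annotated source images.

    Stages (each optional): five-variant right-angle augmentation, flood-fill
    background extraction, VOC-to-YOLO conversion, grouped stratified split.
    Writes ``images/{train,test}/*.png``, ``labels/{train,test}/*.txt``,
    ``dataset.yaml`` and ``manifest.csv`` under ``out_dir`` and returns the
    manifest.  Because the augmentation transforms are pure pixel
    permutations and the flood fill is seeded from the whole border, the two
    stage orders produce identical pixels; ``order`` selects which runs
    first.
    """
    if extract and flood_params is None:
        raise ValueError("flood_params is required when extract=True")
    if order not in ("augment-then-extract", "extract-then-augment"):
        raise ValueError(f"unknown stage order {order!r}")
    grades = grades or GradeMap()
    image_dir, ann_dir, out = Path(image_dir), Path(ann_dir), Path(out_dir)
    for sub in ("images/train", "images/test", "labels/train", "labels/test"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    sources = _load_sources(image_dir, ann_dir, on_missing_annotation)
    logger.info("loaded %d annotated sources", len(sources))

    # stage 1+2: per-source augmentation and extraction (order configurable)
    produced: list[tuple[str, str, str, np.ndarray, list[BoundingBox]]] = []
    for img_path, ann_path in sources:
        _, width, height, boxes = parse_voc(ann_path)
        image = np.asarray(Image.open(img_path).convert("RGB"))
        if image.shape[1] != width or image.shape[0] != height:
            raise ValueError(
                f"{ann_path.name}: annotation size {width}x{height} does not "
                f"match image {image.shape[1]}x{image.shape[0]}"
            )
        grade = boxes[0].grade if boxes else "unlabeled"

        if extract and order == "extract-then-augment":
            image = extract_foreground(image, flood_params)
        variants = (
            augment_set(image, boxes)
            if augment
            else [("identity", image, list(boxes))]
        )
        for kind, vimg, vboxes in variants:
            if extract and order == "augment-then-extract":
                vimg = extract_foreground(vimg, flood_params)
            produced.append((img_path.stem, kind, grade, vimg, vboxes))

    # stage 3: split on provisional items (paths filled in after writing)
    provisional = [
        ManifestItem(source_id=sid, variant=kind, grade=grade, image="", label="")
        for sid, kind, grade, _, _ in produced
    ]
    split_items = split_dataset(
        provisional,
        train_fraction=train_fraction,
        seed=seed,
        require_test=train_fraction < 1,
    )

    # stage 4: write images, YOLO labels, manifest, dataset yaml
    final_items = []
    for (sid, kind, grade, vimg, vboxes), part_item in zip(produced, split_items):
        part = part_item.partition
        stem = f"{sid}{VARIANT_SUFFIXES[kind]}"
        img_rel = f"images/{part}/{stem}.png"
        lbl_rel = f"labels/{part}/{stem}.txt"
        Image.fromarray(vimg).save(out / img_rel)
        h, w = vimg.shape[:2]
        write_yolo_file([to_yolo(b, w, h, grades) for b in vboxes], out / lbl_rel)
        final_items.append(
            ManifestItem(
                source_id=sid, variant=kind, grade=grade,
                image=img_rel, label=lbl_rel, partition=part,
            )
        )

    manifest = DatasetManifest(
        items=final_items,
        seed=seed,
        config={
            "train_fraction": train_fraction,
            "augment": augment,
            "extract": extract,
            "order": order,
            "max_distance": flood_params.max_distance if flood_params else None,
        },
    )
    manifest.write_csv(out / "manifest.csv")
    write_dataset_yaml(out / "dataset.yaml", root=str(out), grades=grades)
    n_train = sum(1 for it in final_items if it.partition == "train")
    logger.info(
        "wrote %d images (%d train / %d test)",
        len(final_items), n_train, len(final_items) - n_train,
    )
    return manifest
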