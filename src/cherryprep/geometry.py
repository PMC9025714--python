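"""Right-angle augmentation transforms for images and bounding boxes.

The augmentation set is exactly five variants per annotated source image:
the identity, rotations by 90/180/270 degrees, and a horizontal flip.  All
five are lossless pixel permutations (no interpolation), so an annotated
source multiplies into five consistent image/label pairs.

Conventions: rotations are counter-clockwise; images are ``(H, W, 3)`` numpy
arrays indexed ``[y, x]``; boxes are half-open pixel intervals
``[x0, x1) x [y0, y1)``.  Under the 90-degree CCW rotation of a ``W``-wide
image the point ``(x, y)`` maps to ``(y, W - x)``, hence the box
``[x0, x1) x [y0, y1)`` maps to ``[y0, y1) x [W - x1, W - x0)``.
"""

from __future__ import annotations

import numpy as np

from .annotations import BoundingBox

__all__ = ["TRANSFORMS", "apply_to_image", "apply_to_box", "augment_set", "VARIANT_SUFFIXES"]

#: The five augmentation variants, in canonical order.
TRANSFORMS = ("identity", "rot90", "rot180", "rot270", "hflip")

#: Filename suffix for each variant.
VARIANT_SUFFIXES = {
    "identity": "_id",
    "rot90": "_r90",
    "rot180": "_r180",
    "rot270": "_r270",
    "hflip": "_hf",
}


def _check_kind(t: str) -> None:
    if t not in TRANSFORMS:
        raise ValueError(f"unknown transform {t!r}; expected one of {TRANSFORMS}")


def apply_to_image(t: str, image: np.ndarray) -> np.ndarray:
    """Apply transform ``t`` to an ``(H, W, 3)`` image array.

    rot90/rot270 swap height and width; all transforms permute pixels without
    interpolation.
    """
    _check_kind(t)
    arr = np.asarray(image)
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be non-empty")
    if t == "identity":
        return arr.copy()
    if t == "rot90":
        return np.rot90(arr, 1).copy()
    if t == "rot180":
        return np.rot90(arr, 2).copy()
    if t == "rot270":
        return np.rot90(arr, 3).copy()
    return arr[:, ::-1].copy()  # hflip


def apply_to_box(t: str, box: BoundingBox, width: int, height: int) -> BoundingBox:
    """Map a box through transform ``t`` of a ``width x height`` image.

    The output box is expressed in the transformed image's coordinate frame
    (whose dimensions are swapped for rot90/rot270).  Box area is preserved
    exactly.
    """
    _check_kind(t)
    if box.x1 <= box.x0 or box.y1 <= box.y0:
        raise ValueError(f"degenerate box {box}")
    if not (0 <= box.x0 and box.x1 <= width and 0 <= box.y0 and box.y1 <= height):
        raise ValueError(f"box {box} outside image bounds {width}x{height}")
    x0, x1, y0, y1 = box.x0, box.x1, box.y0, box.y1
    if t == "identity":
        nx0, nx1, ny0, ny1 = x0, x1, y0, y1
    elif t == "rot90":  # (x, y) -> (y, W - x)
        nx0, nx1, ny0, ny1 = y0, y1, width - x1, width - x0
    elif t == "rot180":  # (x, y) -> (W - x, H - y)
        nx0, nx1, ny0, ny1 = width - x1, width - x0, height - y1, height - y0
    elif t == "rot270":  # (x, y) -> (H - y, x)
        nx0, nx1, ny0, ny1 = height - y1, height - y0, x0, x1
    else:  # hflip: (x, y) -> (W - x, y)
        nx0, nx1, ny0, ny1 = width - x1, width - x0, y0, y1
    return BoundingBox(grade=box.grade, x0=nx0, x1=nx1, y0=ny0, y1=ny1)


def augment_set(image: np.ndarray, boxes) -> list[tuple[str, np.ndarray, list[BoundingBox]]]:
    """Produce the five augmentation variants of an annotated image.

    Returns ``[(kind, image, boxes), ...]`` in the order of
    :data:`TRANSFORMS`; the original image is the ``identity`` variant.
    Class labels are carried through unchanged.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    out = []
    for t in TRANSFORMS:
        timg = apply_to_image(t, arr)
        tboxes = [apply_to_box(t, b, w, h) for b in boxes]
        out.append((t, timg, tboxes))
    return out
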