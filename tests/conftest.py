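import numpy as np
import pytest

from cherryprep.flood import color_distance


def naive_background_mask(image, max_distance, connectivity=4, metric="euclidean"):
    """Independent fixpoint oracle: repeated full-image sweeps until no change.

    Deliberately naive (no frontier, no vectorization) so it shares no code
    path with the package implementation.
    """
    arr = np.asarray(image, dtype=float)
    h, w = arr.shape[:2]
    marked = [[y in (0, h - 1) or x in (0, w - 1) for x in range(w)] for y in range(h)]
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    changed = True
    while changed:
        changed = False
        for y in range(h):
            for x in range(w):
                if marked[y][x]:
                    continue
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and marked[ny][nx]:
                        if color_distance(arr[ny, nx], arr[y, x], metric) < max_distance:
                            marked[y][x] = True
                            changed = True
                            break
    return np.array(marked, dtype=bool)


def rasterize_box(box, width, height):
    """Boolean pixel mask of a half-open box on a height x width grid."""
    m = np.zeros((height, width), dtype=bool)
    m[int(box.y0) : int(box.y1), int(box.x0) : int(box.x1)] = True
    return m


def tight_box_of_mask(mask, grade):
    from cherryprep.annotations import BoundingBox

    ys, xs = np.nonzero(mask)
    return BoundingBox(
        grade=grade,
        x0=float(xs.min()),
        x1=float(xs.max() + 1),
        y0=float(ys.min()),
        y1=float(ys.max() + 1),
    )


def brute_force_ap(flags, n_gt):
    """Independent all-point AP oracle.

    Uses the identity AP = (1/n_gt) * sum over true positives of the maximum
    precision at or after that detection in the confidence-sorted list.
    """
    if n_gt == 0:
        return 0.0
    precisions = []
    tp = 0
    for k, f in enumerate(flags, start=1):
        tp += bool(f)
        precisions.append(tp / k)
    total = 0.0
    for k, f in enumerate(flags):
        if f:
            total += max(precisions[k:])
    return total / n_gt


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_dataset(tmp_path):
    """Eight annotated synthetic scenes (two per grade) on disk."""
    from cherryprep.synthetic import generate_dataset

    records = generate_dataset(n_per_grade=2, out_dir=tmp_path / "src", seed=11)
    return tmp_path, records
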