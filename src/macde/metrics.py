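"""Segmentation validation metrics: Jaccard, Dice, Hausdorff, rasterization.

Region-overlap metrics operate on binary masks (2-D {0, 1} arrays); the
Hausdorff distance operates on point sets, with masks reduced to their
8-connected boundary pixels.  ``rasterize`` converts a closed contour into
a mask so contour outputs can be scored against ground-truth regions.

Conventions: for two regions A and B,

    J(A, B) = |A n B| / |A u B|
    D(A, B) = 2 |A n B| / (|A| + |B|)         (= 2J / (1 + J))
    H(A, B) = max_{a in A} min_{b in B} ||a - b||   (directed)

Both indexes are 1 for identical regions and 0 for disjoint ones; two
empty masks compare as identical (J = D = 1) for continuity.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff
from shapely.geometry import Polygon

from .contour import Contour

__all__ = [
    "rasterize",
    "jaccard",
    "dice",
    "hausdorff",
    "boundary_points",
]

_ON_EDGE_TOL = 1e-9


def _as_mask(m, name="mask") -> np.ndarray:
    arr = np.asarray(m)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    return arr.astype(bool)


def rasterize(contour: Contour, shape) -> np.ndarray:
    """Fill a closed contour into a uint8 mask of the given (h, w) shape.

    Uses the even-odd scanline rule over pixel centers (pixel (r, c) has
    its center at x = c, y = r); centers lying exactly on the polygon
    boundary count as inside.  Self-intersecting contours trigger a
    warning but are still filled by the even-odd rule.
    """
    if not isinstance(contour, Contour):
        contour = Contour(np.asarray(contour, dtype=float))
    h, w = int(shape[0]), int(shape[1])
    pts = contour.points
    mask = np.zeros((h, w), dtype=np.uint8)

    # degenerate = all vertices collinear (signed area is also 0 for valid
    # even-odd shapes like a bowtie, so test collinearity, not area)
    rel = pts - pts[0]
    cross = rel[1:-1, 0] * rel[2:, 1] - rel[1:-1, 1] * rel[2:, 0]
    if np.abs(cross).max(initial=0.0) < _ON_EDGE_TOL:
        warnings.warn("degenerate (zero-area) contour rasterizes empty", stacklevel=2)
        return mask
    if not Polygon(pts).is_valid:
        warnings.warn(
            "self-intersecting contour; even-odd fill rule applied", stacklevel=2
        )

    x1 = pts[:, 0]
    y1 = pts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    cols = np.arange(w)
    for row in range(h):
        # half-open rule on y handles vertices on the scanline consistently
        crosses = (y1 > row) != (y2 > row)
        if not crosses.any():
            continue
        t = (row - y1[crosses]) / (y2[crosses] - y1[crosses])
        x_int = np.sort(x1[crosses] + t * (x2[crosses] - x1[crosses]))
        # inside iff an odd number of crossings lie strictly to the right
        n_right = len(x_int) - np.searchsorted(x_int, cols, side="right")
        mask[row] = (n_right % 2).astype(np.uint8)

    # boundary-inclusive: centers exactly on an edge segment are inside
    for (ax, ay), (bx, by) in zip(pts, np.c_[x2, y2]):
        lo_c = max(0, int(np.ceil(min(ax, bx) - _ON_EDGE_TOL)))
        hi_c = min(w - 1, int(np.floor(max(ax, bx) + _ON_EDGE_TOL)))
        lo_r = max(0, int(np.ceil(min(ay, by) - _ON_EDGE_TOL)))
        hi_r = min(h - 1, int(np.floor(max(ay, by) + _ON_EDGE_TOL)))
        if lo_c > hi_c or lo_r > hi_r:
            continue
        cc, rr = np.meshgrid(np.arange(lo_c, hi_c + 1), np.arange(lo_r, hi_r + 1))
        dx, dy = bx - ax, by - ay
        seg2 = dx * dx + dy * dy
        if seg2 < _ON_EDGE_TOL:
            continue
        t = np.clip(((cc - ax) * dx + (rr - ay) * dy) / seg2, 0.0, 1.0)
        d2 = (ax + t * dx - cc) ** 2 + (ay + t * dy - rr) ** 2
        on = d2 <= _ON_EDGE_TOL
        mask[rr[on], cc[on]] = 1
    return mask


def jaccard(a, b) -> float:
    """Jaccard index |A n B| / |A u B| in [0, 1]; both-empty gives 1."""
    a, b = _as_mask(a, "a"), _as_mask(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def dice(a, b) -> float:
    """Dice index 2|A n B| / (|A| + |B|) in [0, 1]; both-empty gives 1."""
    a, b = _as_mask(a, "a"), _as_mask(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = np.count_nonzero(a) + np.count_nonzero(b)
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / total


def boundary_points(mask) -> np.ndarray:
    """(x, y) coordinates of a mask's 8-connected boundary pixels.

    A foreground pixel is a boundary pixel when at least one of its eight
    neighbours (or the image frame) is background.
    """
    mask = _as_mask(mask)
    interior = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3), dtype=bool), border_value=0
    )
    rr, cc = np.nonzero(mask & ~interior)
    return np.column_stack([cc, rr]).astype(float)


def _as_points(obj, name) -> np.ndarray:
    arr = np.asarray(obj)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype != bool:
        pts = arr.astype(float)
    else:
        pts = boundary_points(arr)
    if len(pts) == 0:
        raise ValueError(f"{name} is empty; Hausdorff distance undefined")
    return pts


def hausdorff(a, b, mode: str = "directed") -> float:
    """Hausdorff distance between two point sets or masks.

    ``mode="directed"`` is max_a min_b ||a - b|| (not symmetric);
    ``mode="symmetric"`` is the max of both directions.  Masks are reduced
    to their 8-connected boundary pixel coordinates first.
    """
    pa = _as_points(a, "a")
    pb = _as_points(b, "b")
    if mode == "directed":
        return float(directed_hausdorff(pa, pb)[0])
    if mode == "symmetric":
        return float(
            max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
        )
    raise ValueError(f"mode must be 'directed' or 'symmetric', got {mode!r}")
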