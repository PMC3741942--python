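"""Synthetic test phantoms with exact ground-truth masks.

Three benchmark images exercise the failure modes the segmenter targets: a
star with deep concavities (160x160) where locally greedy snakes stall on
the convex hull, a disk corrupted by additive Gaussian noise (300x300,
sigma 0.04 on the normalized [0, 1] intensity scale) that litters the
distance map with spurious local minima, and a multi-lobed blob (150x150)
with several boundary concavities.  A plain clean disk and a sequential
"stack" of smoothly drifting slices round out the set.

Every phantom is star-convex about its center, so a single boundary point
exists on every polar ray from the center — the geometric assumption of
the polar-section segmenter.  Masks are exact, noiseless geometry; noise
only ever touches the image.  The same spec and seed always regenerate
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contour import Contour
from .metrics import rasterize

__all__ = [
    "PhantomSpec",
    "make_star",
    "make_noisy_circle",
    "make_concave_blob",
    "make_plain_circle",
    "make_stack",
    "make_phantom",
]

_MARGIN = 5  # minimum px between shape and image border


@dataclass
class PhantomSpec:
    """Declarative phantom description (used by the CLI and stack mode)."""

    kind: str  # star | noisy_circle | concave_blob | plain_circle
    size: tuple[int, int] | None = None
    params: dict = field(default_factory=dict)
    fg_value: float = 200.0
    bg_value: float = 0.0
    seed: int | None = None

    def make(self):
        return make_phantom(
            self.kind, size=self.size, fg=self.fg_value, bg=self.bg_value,
            seed=self.seed, **self.params,
        )


def _center(size) -> tuple[float, float]:
    h, w = size
    return w // 2, h // 2


def _paint(mask: np.ndarray, fg: float, bg: float) -> np.ndarray:
    return np.where(mask > 0, float(fg), float(bg))


def _disk_mask(size, center, radius: float) -> np.ndarray:
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    return (
        (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius * radius
    ).astype(np.uint8)


def star_polygon(center, n_points: int, r_outer: float, r_inner: float) -> Contour:
    """Regular star polygon: 2n vertices alternating outer/inner radius."""
    if n_points < 3:
        raise ValueError("a star needs at least 3 points")
    if r_inner > r_outer or r_inner <= 0:
        raise ValueError("need 0 < r_inner <= r_outer")
    k = np.arange(2 * n_points)
    ang = np.deg2rad(90.0 + k * 360.0 / (2 * n_points))  # one tip points up
    rad = np.where(k % 2 == 0, r_outer, r_inner)
    cx, cy = center
    pts = np.column_stack([cx + rad * np.cos(ang), cy - rad * np.sin(ang)])
    return Contour(pts)


def make_star(
    size=(160, 160),
    n_points: int = 5,
    r_outer: float | None = None,
    r_inner: float | None = None,
    fg: float = 200.0,
    bg: float = 0.0,
    seed=None,
):
    """Star phantom with deep concavities; returns ``(image, mask)``.

    Defaults: 160x160 image, 5-pointed star with outer/inner radii 60/25;
    for other sizes the default radii scale proportionally.
    ``r_inner == r_outer`` degenerates to a regular 2n-gon.
    """
    h, w = size
    if r_outer is None:
        r_outer = min(size) * (60.0 / 160.0)
    if r_inner is None:
        r_inner = min(size) * (25.0 / 160.0)
    cx, cy = _center(size)
    if r_outer > min(cx, cy, w - 1 - cx, h - 1 - cy) - _MARGIN:
        raise ValueError(f"r_outer={r_outer} leaves less than {_MARGIN} px margin")
    poly = star_polygon((cx, cy), n_points, r_outer, r_inner)
    mask = rasterize(poly, size)
    return _paint(mask, fg, bg), mask


def make_noisy_circle(
    size=(300, 300),
    radius: float | None = None,
    noise_sigma: float = 0.04,
    fg: float = 200.0,
    bg: float = 0.0,
    seed=None,
):
    """Disk plus additive Gaussian noise; returns ``(image, mask)``.

    The default radius is 100 at the default 300x300 size and scales
    proportionally for other sizes.  The noise has mean 0 and standard
    deviation ``noise_sigma`` on the normalized [0, 1] intensity scale;
    the image is rescaled to 0-255 and clipped.  The mask is the exact
    noiseless disk, so noise never alters the ground truth.  Deterministic
    per ``seed``.
    """
    if radius is None:
        radius = min(size) * (100.0 / 300.0)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    h, w = size
    cx, cy = _center(size)
    if radius > min(cx, cy, w - 1 - cx, h - 1 - cy) - _MARGIN:
        raise ValueError(f"radius={radius} leaves less than {_MARGIN} px margin")
    mask = _disk_mask(size, (cx, cy), radius)
    img = _paint(mask, fg, bg)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img / 255.0 + rng.normal(0.0, noise_sigma, size=img.shape)
        img = np.clip(img * 255.0, 0.0, 255.0)
    return img, mask


def make_plain_circle(size=(300, 300), radius: float | None = None,
                      fg: float = 200.0, bg: float = 0.0, seed=None):
    """Clean disk phantom (noise-free special case)."""
    return make_noisy_circle(size, radius, 0.0, fg, bg, seed)


_DEFAULT_LOBES = ((90.0, 26.0, 34.0), (210.0, 26.0, 34.0), (330.0, 26.0, 34.0))


def make_concave_blob(
    size=(150, 150),
    lobes=None,
    fg: float = 200.0,
    bg: float = 0.0,
    seed=None,
):
    """Union-of-disks blob with boundary concavities; ``(image, mask)``.

    ``lobes`` is a sequence of (angle_deg, offset, radius): each lobe is a
    disk of the given radius centered ``offset`` pixels from the image
    center along the given direction.  The default is three lobes at
    offset 26 / radius 34 for the default 150x150 size, scaled
    proportionally for other sizes.  Every lobe must contain the center
    (offset < radius) so the union is star-convex about it, and the result
    must be a single connected region.  Two or more lobes produce the
    concavities between them; a single lobe is a plain disk.
    """
    if lobes is None:
        lobes = [
            (a, o * min(size) / 150.0, r * min(size) / 150.0)
            for a, o, r in _DEFAULT_LOBES
        ]
    if len(lobes) < 1:
        raise ValueError("need at least one lobe")
    h, w = size
    cx, cy = _center(size)
    mask = np.zeros((h, w), dtype=np.uint8)
    for ang_deg, offset, radius in lobes:
        if radius <= 0:
            raise ValueError("lobe radius must be positive")
        if offset >= radius:
            raise ValueError(
                f"lobe offset {offset} >= radius {radius}: lobe would not "
                "contain the center and the blob would not be star-convex"
            )
        t = np.deg2rad(ang_deg)
        lx, ly = cx + offset * np.cos(t), cy - offset * np.sin(t)
        if radius + offset > min(cx, cy, w - 1 - cx, h - 1 - cy) - _MARGIN:
            raise ValueError("lobe extends into the border margin")
        mask |= _disk_mask(size, (lx, ly), radius)
    _, n_components = ndimage.label(mask)
    if n_components != 1:
        raise ValueError(f"lobes produce {n_components} disconnected regions")
    return _paint(mask, fg, bg), mask


def make_phantom(kind: str, size=None, **kwargs):
    """Dispatch on phantom kind; ``size=None`` selects each kind's default."""
    makers = {
        "star": (make_star, (160, 160)),
        "noisy_circle": (make_noisy_circle, (300, 300)),
        "concave_blob": (make_concave_blob, (150, 150)),
        "plain_circle": (make_plain_circle, (300, 300)),
    }
    if kind not in makers:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {sorted(makers)}")
    maker, default_size = makers[kind]
    return maker(size=size or default_size, **kwargs)


def make_stack(
    spec: PhantomSpec,
    n_slices: int,
    scale_drift: float = 0.0,
    center_drift: tuple[float, float] = (0.0, 0.0),
):
    """Sequential phantom series emulating a CT/MR slice stack.

    Slice k scales every radial parameter of the base phantom by
    ``1 + k * scale_drift`` and shifts the shape center by
    ``k * center_drift`` (the drift is applied to lobe/star geometry via
    the offset parameters where applicable; circles shift via an offset
    lobe representation is not needed — only radii scale, centers are
    common to keep one shared seed point valid).  The base image center is
    the shared seed point and must stay inside every slice's mask.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    radial_keys = {"radius", "r_outer", "r_inner", "offset"}
    slices = []
    size = spec.size or {
        "star": (160, 160), "noisy_circle": (300, 300),
        "concave_blob": (150, 150), "plain_circle": (300, 300),
    }[spec.kind]
    seed_pt = _center(size)
    for k in range(n_slices):
        scale = 1.0 + k * scale_drift
        if scale <= 0:
            raise ValueError(f"scale drift collapses slice {k}")
        params = dict(spec.params)
        for key in radial_keys & params.keys():
            params[key] = params[key] * scale
        base = min(size)  # kind defaults are relative so any slice size works
        if spec.kind == "star":
            params.setdefault("r_outer", base * (60.0 / 160.0) * scale)
            params.setdefault("r_inner", base * (25.0 / 160.0) * scale)
        elif spec.kind in ("noisy_circle", "plain_circle"):
            params.setdefault("radius", base * (100.0 / 300.0) * scale)
        elif spec.kind == "concave_blob" and "lobes" not in params:
            params["lobes"] = [
                (a, base * o / 150.0 * scale, base * r / 150.0 * scale)
                for a, o, r in _DEFAULT_LOBES
            ]
        slice_seed = None if spec.seed is None else spec.seed + k
        img, mask = make_phantom(
            spec.kind, size=size, fg=spec.fg_value, bg=spec.bg_value,
            seed=slice_seed, **params,
        )
        if center_drift != (0.0, 0.0):
            dx, dy = int(round(k * center_drift[0])), int(round(k * center_drift[1]))
            img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
            mask = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
        if not mask[int(seed_pt[1]), int(seed_pt[0])]:
            raise ValueError(
                f"drift ejects the shared seed point from the region at slice {k}"
            )
        slices.append((img, mask))
    return slices
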