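"""Closed polygonal contours: the common currency of the segmentation code.

A contour is an ordered list of continuous ``(x, y)`` positions (``x`` =
column, ``y`` = row) forming a closed polygon; the last point connects back
to the first.  Contours round-trip through CSV with an ``index,x,y`` header
and 0-based indices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Contour"]


@dataclass
class Contour:
    """Ordered closed polygon of control points (snaxels)."""

    points: np.ndarray  # (n, 2) array of (x, y)
    closed: bool = True
    extra: dict = field(default_factory=dict)  # optional per-point columns

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
        if len(pts) < 3:
            raise ValueError(f"a closed contour needs >= 3 points, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def area(self) -> float:
        """Signed shoelace area of the polygon (positive if CCW in x/y)."""
        x, y = self.x, self.y
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def centroid(self) -> tuple[float, float]:
        return float(self.x.mean()), float(self.y.mean())

    def to_csv(self, path, extra_fields: tuple[str, ...] = ()) -> None:
        """Write ``index,x,y[,extra...]`` rows (0-based index, x = column)."""
        fields = ["index", "x", "y", *extra_fields]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(fields)
            for i, (px, py) in enumerate(self.points):
                row = [i, repr(float(px)), repr(float(py))]
                row += [repr(float(self.extra[name][i])) for name in extra_fields]
                writer.writerow(row)

    @classmethod
    def from_csv(cls, path) -> "Contour":
        """Read a contour written by :meth:`to_csv` (extra columns kept)."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"x", "y"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected a CSV with x and y columns")
            extras = [f for f in reader.fieldnames if f not in ("index", "x", "y")]
            pts, cols = [], {name: [] for name in extras}
            for row in reader:
                pts.append((float(row["x"]), float(row["y"])))
                for name in extras:
                    cols[name].append(float(row[name]))
        return cls(np.array(pts), extra={k: np.array(v) for k, v in cols.items()})
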