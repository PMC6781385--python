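"""Closed planar contours: the common currency of the pipeline.

A :class:`Contour` is an ordered closed polygon of ``(x, y)`` vertices in a
right-handed frame (x to the right, y up).  Pixel-derived contours use
``x = column`` and ``y = -row`` so that image-space and geometry-space tests
read identically.  The canonical orientation throughout the package is
counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon


@dataclass
class Contour:
    """Ordered closed polygon of 2-D vertices.

    Parameters
    ----------
    vertices : (N, 2) float array
        Ordered vertex coordinates.  The polygon is closed implicitly: the
        last vertex is *not* a repeat of the first.
    closed : bool
        Always true in this pipeline; kept explicit for clarity.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"vertices must be (N, 2), got {v.shape}")
        if len(v) < 4:
            raise ValueError(f"a contour needs >= 4 vertices, got {len(v)}")
        if np.any(np.all(v == np.roll(v, -1, axis=0), axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        self.vertices = v

    # -- geometry ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise orientation."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return 0.5 * float(np.sum(x * yn - xn * y))

    @property
    def orientation(self) -> str:
        return "ccw" if self.signed_area >= 0 else "cw"

    @property
    def perimeter(self) -> float:
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def centroid(self) -> np.ndarray:
        """Vertex mean (adequate for uniformly resampled contours)."""
        return self.vertices.mean(axis=0)

    def edge_lengths(self) -> np.ndarray:
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return np.hypot(d[:, 0], d[:, 1])

    def ensure_ccw(self) -> "Contour":
        """Return a counter-clockwise copy (reversing order if needed)."""
        if self.signed_area < 0:
            # keep the start vertex in place while reversing traversal
            v = np.roll(self.vertices[::-1], 1, axis=0)
            return Contour(v, closed=self.closed)
        return self

    def is_simple(self) -> bool:
        """True when the polygon does not self-intersect."""
        return Polygon(self.vertices).is_valid

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + np.array([dx, dy]), closed=self.closed)

    def scaled(self, s: float) -> "Contour":
        if s <= 0:
            raise ValueError("scale must be positive")
        return Contour(self.vertices * s, closed=self.closed)

    def rotated(self, theta: float) -> "Contour":
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        return Contour(self.vertices @ rot.T, closed=self.closed)

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(self.vertices, columns=["x", "y"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Contour":
        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(dtype=float))
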