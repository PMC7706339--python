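"""Planar affine transforms shared by the raster, detection and synthesis code.

A single convention is used throughout the package: pixel coordinates are
``(x, y)`` with ``x`` the column index growing rightward and ``y`` the row
index growing downward, 0-based, with integer values at pixel *corners* so
half-open pixel intervals map to polygons that tile exactly.  World
coordinates live in a local planar metric frame (no geodesy).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = ["Affine2D"]


@dataclass(frozen=True)
class Affine2D:
    """Affine map ``(x, y) -> (a*x + b*y + c, d*x + e*y + f)``.

    Mirrors the familiar GIS "geotransform" (an invertible 2x3 matrix); used
    both as raster pixel->world transform and as the rotated->original pixel
    map of the detection stage.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

    @classmethod
    def translation(cls, tx: float, ty: float) -> "Affine2D":
        return cls(1.0, 0.0, tx, 0.0, 1.0, ty)

    @classmethod
    def rotation(cls, angle_deg: float) -> "Affine2D":
        """Rotation about the origin by ``angle_deg`` (x->y positive)."""
        t = math.radians(angle_deg)
        cos, sin = math.cos(t), math.sin(t)
        return cls(cos, -sin, 0.0, sin, cos, 0.0)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "Affine2D":
        m = np.asarray(m, dtype=float)
        return cls(m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2])

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix."""
        return np.array(
            [[self.a, self.b, self.c], [self.d, self.e, self.f], [0.0, 0.0, 1.0]]
        )

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    def __matmul__(self, other: "Affine2D") -> "Affine2D":
        return Affine2D.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "Affine2D":
        det = self.determinant
        if det == 0.0:
            raise ValueError("affine transform is singular")
        ia, ib = self.e / det, -self.b / det
        id_, ie = -self.d / det, self.a / det
        return Affine2D(
            ia, ib, -(ia * self.c + ib * self.f),
            id_, ie, -(id_ * self.c + ie * self.f),
        )

    def apply(self, xy) -> np.ndarray:
        """Transform an ``(N, 2)`` array (or a single pair) of points."""
        pts = np.atleast_2d(np.asarray(xy, dtype=float))
        out = np.empty_like(pts)
        out[:, 0] = self.a * pts[:, 0] + self.b * pts[:, 1] + self.c
        out[:, 1] = self.d * pts[:, 0] + self.e * pts[:, 1] + self.f
        return out if np.ndim(xy) == 2 else out[0]

    def is_axis_aligned(self, tol: float = 1e-12) -> bool:
        return abs(self.b) <= tol and abs(self.d) <= tol
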