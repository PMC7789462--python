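"""Closed lung-outline polygons in physical (mm) coordinates.

Coordinate convention used throughout the package: ``x`` increases from
anterior to posterior, ``y`` increases from caudal to cranial.  Contours are
stored as open rings (first vertex not repeated) oriented counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.geometry as sgeom


class ContourError(ValueError):
    """Raised for degenerate or invalid lung contours."""


@dataclass(frozen=True)
class LungContour:
    """Ordered closed polygon of the lung outline, in mm.

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of ``(x_mm, y_mm)`` points.  The ring is implicitly
        closed; the first vertex is not repeated.  Stored counter-clockwise.
    """

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContourError("vertices must be an (n, 2) array")
        # drop a repeated closing vertex if present
        if v.shape[0] > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 8:
            raise ContourError(f"contour needs >= 8 vertices, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ContourError("contour contains non-finite coordinates")
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def polygon(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.vertices)

    def area(self) -> float:
        """Absolute shoelace area in mm^2."""
        return abs(_signed_area(self.vertices))

    def centroid(self) -> np.ndarray:
        """Area centroid (centre of gravity of the enclosed region)."""
        a = _signed_area(self.vertices)
        if abs(a) < 1e-12:
            raise ContourError("zero-area polygon has no centroid")
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    def is_simple(self) -> bool:
        return bool(self.polygon.is_valid)

    def transformed(self, *, rotation_rad: float = 0.0,
                    translation_mm: tuple[float, float] = (0.0, 0.0),
                    scale: float = 1.0) -> "LungContour":
        """Rigidly rotate about the origin, scale, then translate."""
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        rot = np.array([[c, -s], [s, c]])
        v = scale * (self.vertices @ rot.T) + np.asarray(translation_mm, float)
        return LungContour(v)


def _signed_area(vertices: np.ndarray) -> float:
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise rings."""
    return _signed_area(np.asarray(vertices, dtype=float))
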