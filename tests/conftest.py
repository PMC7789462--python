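"""Shared fixtures: canonical shapes and randomized phantom contours."""

from __future__ import annotations

import numpy as np
import pytest

from diaquant import LungContour, phantom


def densify(points: np.ndarray, per_edge: int = 12) -> np.ndarray:
    """Subdivide polygon edges so shapes meet the minimum vertex count."""
    pts = np.asarray(points, dtype=float)
    out = []
    for i in range(len(pts)):
        a, b = pts[i], pts[(i + 1) % len(pts)]
        for t in np.linspace(0.0, 1.0, per_edge, endpoint=False):
            out.append(a + t * (b - a))
    return np.array(out)


def circle_contour(radius: float, center=(0.0, 0.0), n: int = 720
                   ) -> LungContour:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return LungContour(np.column_stack([center[0] + radius * np.cos(theta),
                                        center[1] + radius * np.sin(theta)]))


def ellipse_contour(a: float, b: float, angle: float = 0.0,
                    center=(0.0, 0.0), n: int = 720) -> LungContour:
    """Ellipse with semi-axis ``a`` along +y and ``b`` along +x, rotated by
    ``angle`` (counter-clockwise)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = b * np.cos(t)
    y = a * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    pts = np.column_stack([c * x - s * y + center[0],
                           s * x + c * y + center[1]])
    return LungContour(pts)


@pytest.fixture
def square_contour() -> LungContour:
    """Unit square with densified edges."""
    return LungContour(densify(np.array([[0, 0], [1, 0], [1, 1], [0, 1]],
                                        dtype=float)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_phantom_contour(rng: np.random.Generator,
                           *, rotate: bool = True) -> LungContour:
    """A randomized anatomical phantom outline, optionally rigidly moved.

    Heights are kept comfortably larger than the width: a sagittal lung is
    taller than deep, which is what anchors the major-axis orientation.
    """
    width = rng.uniform(90.0, 160.0)
    cap = rng.uniform(40.0, 110.0)
    wall = rng.uniform(70.0, 160.0)
    wall = max(wall, 1.2 * width - cap)
    poly = phantom.lung_polygon(
        width_mm=width,
        wall_height_mm=wall,
        cap_height_mm=cap,
        dome_height_mm=rng.uniform(10.0, 45.0),
        dome_power=rng.uniform(1.0, 2.5),
        cap_exponent=rng.uniform(1.0, 4.0),
        n_vertices=int(rng.integers(220, 420)))
    angle = rng.uniform(-0.25, 0.25) if rotate else 0.0
    shift = tuple(rng.uniform(-40.0, 40.0, size=2))
    return poly.transformed(rotation_rad=angle, translation_mm=shift)
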