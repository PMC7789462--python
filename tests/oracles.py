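"""Independent brute-force reference implementations for the landmark and
outcome definitions.  Deliberately written as plain loops / rasterised mass
computations, sharing no code with the package, so they can serve as oracles.
"""

from __future__ import annotations

import math

import numpy as np


def principal_axis_angle(points: np.ndarray) -> float:
    """Orientation of the dominant scatter axis, measured from +y toward +x."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, int(np.argmax(evals))]
    if u[1] < 0 or (u[1] == 0 and u[0] < 0):
        u = -u
    ang = math.atan2(u[0], u[1])
    if ang <= -math.pi / 2:
        ang += math.pi
    return ang


def apex_by_scan(vertices: np.ndarray, axis_angle: float) -> np.ndarray:
    """Exhaustive max-projection vertex; ties to the smallest x."""
    u = np.array([math.sin(axis_angle), math.cos(axis_angle)])
    best, best_proj = None, -math.inf
    for v in vertices:
        proj = v[0] * u[0] + v[1] * u[1]
        if proj > best_proj + 1e-9:
            best, best_proj = v, proj
        elif abs(proj - best_proj) <= 1e-9 and v[0] < best[0]:
            best = v
    return np.array(best)


def centroid_by_raster(vertices: np.ndarray, resolution: float = 0.25
                       ) -> np.ndarray:
    """Centre of mass of a fine rasterisation of the polygon interior."""
    from matplotlib.path import Path as MplPath

    v = np.asarray(vertices, dtype=float)
    path = MplPath(v, closed=False)
    xmin, ymin = v.min(axis=0)
    xmax, ymax = v.max(axis=0)
    # cell-centre sampling so the grid carries no half-cell boundary bias
    xs = np.arange(xmin + resolution / 2, xmax, resolution)
    ys = np.arange(ymin + resolution / 2, ymax, resolution)
    xg, yg = np.meshgrid(xs, ys)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    inside = path.contains_points(pts)
    return pts[inside].mean(axis=0)


def area_by_raster(vertices: np.ndarray, resolution: float = 0.25) -> float:
    """Pixel-count area of a fine rasterisation."""
    from matplotlib.path import Path as MplPath

    v = np.asarray(vertices, dtype=float)
    path = MplPath(v, closed=False)
    xmin, ymin = v.min(axis=0)
    xmax, ymax = v.max(axis=0)
    xs = np.arange(xmin + resolution / 2, xmax, resolution)
    ys = np.arange(ymin + resolution / 2, ymax, resolution)
    xg, yg = np.meshgrid(xs, ys)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    return float(path.contains_points(pts).sum()) * resolution ** 2


def corners_by_scan(vertices: np.ndarray, axis_angle: float,
                    centroid: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive farthest-from-centroid search in the lower lung halves."""
    u = np.array([math.sin(axis_angle), math.cos(axis_angle)])
    w = np.array([u[1], -u[0]])
    best = {"ant": None, "post": None}
    key = {"ant": None, "post": None}
    for v in vertices:
        rel = v - centroid
        if rel @ u >= 0:
            continue  # not in the lower part
        side = "ant" if rel @ w < 0 else "post"
        dist = math.hypot(*rel)
        # maximise distance; ties -> caudal-most, then smallest x
        k = (round(dist / 1e-9), -round((rel @ u) / 1e-9), -round(v[0] / 1e-9))
        if key[side] is None or k > key[side]:
            key[side], best[side] = k, v
    ant, post = best["ant"], best["post"]
    assert ant is not None and post is not None
    if ant[0] > post[0]:
        ant, post = post, ant
    return np.array(ant), np.array(post)


def point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Perpendicular distance from p to the infinite line through a, b."""
    num = abs((b[0] - a[0]) * (a[1] - p[1]) - (a[0] - p[0]) * (b[1] - a[1]))
    return num / math.hypot(b[0] - a[0], b[1] - a[1])


def raw_apex_by_scan(path_points: np.ndarray
                     ) -> tuple[np.ndarray, float, float]:
    """Exhaustive farthest-from-chord scan; returns point, fraction, dist."""
    pts = np.asarray(path_points, dtype=float)
    a, b = pts[0], pts[-1]
    seg = [0.0]
    for i in range(1, len(pts)):
        seg.append(seg[-1] + math.hypot(*(pts[i] - pts[i - 1])))
    total = seg[-1]
    best_i, best_d = 0, -1.0
    for i, p in enumerate(pts):
        d = point_line_distance(p, a, b)
        if d > best_d + 1e-9:
            best_i, best_d = i, d
    return pts[best_i], seg[best_i] / total, best_d


def interpolate_along(path_points: np.ndarray, fraction: float) -> np.ndarray:
    """Arc-length interpolation along a polyline, written independently."""
    pts = np.asarray(path_points, dtype=float)
    seg = [0.0]
    for i in range(1, len(pts)):
        seg.append(seg[-1] + math.hypot(*(pts[i] - pts[i - 1])))
    target = fraction * seg[-1]
    for i in range(1, len(pts)):
        if seg[i] >= target:
            span = seg[i] - seg[i - 1]
            t = 0.0 if span == 0 else (target - seg[i - 1]) / span
            return pts[i - 1] + t * (pts[i] - pts[i - 1])
    return pts[-1]


def signed_area_between_by_raster(path_points: np.ndarray,
                                  resolution: float = 0.1) -> float:
    """Signed area between a polyline and its end-point chord.

    Positive where the path lies on the cranial (+y for a left-to-right
    chord) side, computed by signed column sums on a fine grid.
    """
    pts = np.asarray(path_points, dtype=float)
    a, b = pts[0], pts[-1]
    # rotate so the chord is horizontal
    theta = math.atan2(b[1] - a[1], b[0] - a[0])
    rot = np.array([[math.cos(-theta), -math.sin(-theta)],
                    [math.sin(-theta), math.cos(-theta)]])
    local = (pts - a) @ rot.T
    xs = local[:, 0]
    total = 0.0
    for x in np.arange(xs.min(), xs.max(), resolution):
        # path height at this x: linear interpolation over crossings
        heights = []
        for i in range(1, len(local)):
            x0, x1 = local[i - 1, 0], local[i, 0]
            if (x0 - x) * (x1 - x) <= 0 and x0 != x1:
                t = (x - x0) / (x1 - x0)
                heights.append(local[i - 1, 1]
                               + t * (local[i, 1] - local[i - 1, 1]))
        if heights:
            total += np.mean(heights) * resolution
    return total


def spearman_by_ranks(x, y) -> float:
    """Rank correlation with average ranks, from first principles."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))
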