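"""Per-frame anatomical reference points on a sagittal lung contour.

Five landmarks drive every outcome: the lung apex, the area centroid, the
anterior and posterior costophrenic angles (the basal corners where the
diaphragm meets the chest wall), and the diaphragm apex.  The raw diaphragm
apex — the diaphragm point farthest from the chord joining the two corners —
is noisy from frame to frame, so a *derived* apex is used downstream: the
median arc-length fraction of the raw apex across all frames of a series,
re-applied to each frame's diaphragm contour.

Orientation is normalised first by fitting an ellipse to the outline; the
major axis plays the role of the cranio-caudal body axis, which makes
"highest point" and "lower part of the lung" well-defined for tilted
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

from .contour import ContourError, LungContour


@dataclass(frozen=True)
class EllipseFit:
    """Best-fit ellipse of the lung outline, used only for orientation.

    ``major_axis_angle_rad`` is measured from the +y (cranio-caudal) axis,
    positive tilting toward +x (posterior), in (-pi/2, pi/2].
    """

    center: np.ndarray
    semi_major_mm: float
    semi_minor_mm: float
    major_axis_angle_rad: float

    @property
    def major_axis_cranial(self) -> np.ndarray:
        """Unit vector along the major axis with positive cranial component."""
        a = self.major_axis_angle_rad
        return np.array([np.sin(a), np.cos(a)])


@dataclass(frozen=True)
class DiaphragmContour:
    """Polyline from the anterior to the posterior costophrenic angle."""

    points: np.ndarray
    cumulative_arclength_mm: np.ndarray

    @property
    def total_length_mm(self) -> float:
        return float(self.cumulative_arclength_mm[-1])

    @property
    def anterior(self) -> np.ndarray:
        return self.points[0]

    @property
    def posterior(self) -> np.ndarray:
        return self.points[-1]

    def point_at_fraction(self, fraction: float) -> np.ndarray:
        """Point at a given arc-length fraction (0 = anterior, 1 = posterior)."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {fraction}")
        target = fraction * self.total_length_mm
        s = self.cumulative_arclength_mm
        i = int(np.searchsorted(s, target, side="right")) - 1
        i = min(max(i, 0), len(s) - 2)
        seg = s[i + 1] - s[i]
        t = 0.0 if seg <= 0 else (target - s[i]) / seg
        return (1 - t) * self.points[i] + t * self.points[i + 1]


@dataclass(frozen=True)
class RawApex:
    point: np.ndarray
    fraction: float
    distance_mm: float
    degenerate: bool = False  # set when the diaphragm is flat (collinear)


@dataclass(frozen=True)
class LandmarkSet:
    """The reference points of one frame."""

    lung_apex: np.ndarray
    centroid: np.ndarray
    anterior_angle: np.ndarray
    posterior_angle: np.ndarray
    apex_raw: np.ndarray
    apex_raw_fraction: float
    apex_derived: np.ndarray
    frame_index: int = 0


# --------------------------------------------------------------------------
# orientation


def _principal_axes_fit(v: np.ndarray) -> EllipseFit:
    center = v.mean(axis=0)
    cov = np.cov((v - center).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # boundary samples of an ellipse have variance a^2/2 along each axis
    semi = np.sqrt(np.maximum(2.0 * evals, 0.0))
    u = evecs[:, 0]
    return EllipseFit(center=center,
                      semi_major_mm=float(semi[0]),
                      semi_minor_mm=float(max(semi[1], 1e-12)),
                      major_axis_angle_rad=_angle_from_cranial(u))


def _angle_from_cranial(u: np.ndarray) -> float:
    """Angle of axis direction u from +y, normalised into (-pi/2, pi/2]."""
    ux, uy = u
    if uy < 0 or (uy == 0 and ux < 0):
        ux, uy = -ux, -uy
    ang = float(np.arctan2(ux, uy))
    if ang <= -np.pi / 2:
        ang += np.pi
    return ang


def fit_orientation(contour: LungContour) -> EllipseFit:
    """Fit an ellipse to the outline by direct algebraic least squares.

    Falls back to the principal axes of the vertex scatter when the algebraic
    fit is degenerate (near-collinear vertices, failed or wildly eccentric
    solutions).
    """
    v = contour.vertices
    if v.shape[0] < 8:
        raise ContourError("ellipse fit needs >= 8 vertices")
    params = None
    try:
        if hasattr(EllipseModel, "from_estimate"):
            model = EllipseModel.from_estimate(v)
            if model:  # failed fits are falsy
                params = (*model.center, *model.axis_lengths, model.theta)
        else:  # skimage < 0.26
            model = EllipseModel()
            if model.estimate(v):
                params = tuple(model.params)
    except Exception:
        params = None
    if params is not None:
        xc, yc, a, b, theta = params
        if np.all(np.isfinite([xc, yc, a, b, theta])) and a > 0 and b > 0:
            if b > a:
                a, b = b, a
                theta += np.pi / 2
            # reject absurd fits (e.g. huge circumscribing solutions)
            span = float(np.ptp(v, axis=0).max())
            if a < 5 * span and a / b < 50:
                u = np.array([np.cos(theta), np.sin(theta)])
                return EllipseFit(center=np.array([xc, yc]),
                                  semi_major_mm=float(a),
                                  semi_minor_mm=float(b),
                                  major_axis_angle_rad=_angle_from_cranial(u))
    return _principal_axes_fit(v)


# --------------------------------------------------------------------------
# point landmarks


def find_lung_apex(contour: LungContour, ellipse: EllipseFit) -> np.ndarray:
    """Most cranial vertex measured along the ellipse's major axis.

    Ties (equal projection within 1e-9 mm) go to the vertex with smaller x.
    """
    u = ellipse.major_axis_cranial
    proj = contour.vertices @ u
    best = proj.max()
    cand = np.flatnonzero(proj >= best - 1e-9)
    i = cand[np.argmin(contour.vertices[cand, 0])]
    return contour.vertices[i].copy()


def compute_centroid(contour: LungContour) -> np.ndarray:
    """Area centroid (centre of gravity) of the lung region."""
    return contour.centroid()


def find_costophrenic_angles(contour: LungContour, ellipse: EllipseFit,
                             centroid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Basal corners: farthest-from-centroid vertices in the lower lung.

    "Lower" means the major-axis projection is caudal to the centroid's;
    the lower vertex set is split into an anterior and a posterior side by
    the major-axis line through the centroid.  In each side the vertex with
    the largest Euclidean distance to the centroid is returned (ties broken
    caudal-most, then smallest x).
    """
    v = contour.vertices
    u = ellipse.major_axis_cranial
    w = np.array([u[1], -u[0]])  # perpendicular, pointing anterior -> posterior
    proj = (v - centroid) @ u
    side = (v - centroid) @ w
    lower = proj < 0

    def pick(mask: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ContourError("degenerate contour: no vertices on one side "
                               "of the lower lung")
        d = np.linalg.norm(v[idx] - centroid, axis=1)
        best = d.max()
        cand = idx[d >= best - 1e-9]
        # ties: caudal-most (smallest major-axis projection), then smallest x
        order = np.lexsort((v[cand, 0], proj[cand]))
        return v[cand[order[0]]].copy()

    anterior = pick(lower & (side < 0))
    posterior = pick(lower & (side >= 0))
    if anterior[0] > posterior[0]:  # enforce the anatomical x-order
        anterior, posterior = posterior, anterior
    return anterior, posterior


# --------------------------------------------------------------------------
# diaphragm contour and apex


def _vertex_index(contour: LungContour, point: np.ndarray) -> int:
    d = np.linalg.norm(contour.vertices - point, axis=1)
    i = int(np.argmin(d))
    if d[i] > 1e-6:
        raise ContourError("landmark is not a contour vertex")
    return i


def diaphragm_contour(contour: LungContour, anterior: np.ndarray,
                      posterior: np.ndarray,
                      lung_apex: np.ndarray) -> DiaphragmContour:
    """The boundary path between the two corners that avoids the lung apex.

    Returned oriented anterior -> posterior with cumulative arc length.
    """
    ia = _vertex_index(contour, anterior)
    ip = _vertex_index(contour, posterior)
    ix = _vertex_index(contour, lung_apex)
    if ix in (ia, ip):
        raise ContourError("lung apex coincides with a costophrenic angle")
    n = contour.n_vertices

    def ring_path(start: int, stop: int) -> np.ndarray:
        if start <= stop:
            return np.arange(start, stop + 1)
        return np.concatenate([np.arange(start, n), np.arange(0, stop + 1)])

    path1 = ring_path(ia, ip)
    path2 = ring_path(ip, ia)[::-1]  # also anterior -> posterior
    chosen = path2 if ix in set(path1[1:-1]) else path1
    pts = contour.vertices[chosen]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return DiaphragmContour(points=pts, cumulative_arclength_mm=cum)


def find_diaphragm_apex_raw(dia: DiaphragmContour) -> RawApex:
    """Diaphragm point farthest from the chord between the two corners.

    Ties go to the smaller arc-length fraction.  A flat diaphragm (all points
    on the chord) is flagged degenerate with fraction 0.5.
    """
    pts = dia.points
    if pts.shape[0] < 3:
        raise ContourError("diaphragm contour needs >= 3 points")
    a, b = pts[0], pts[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        raise ContourError("coincident costophrenic angles")
    u = chord / norm
    rel = pts - a
    dist = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    dmax = dist.max()
    if dmax < 1e-9 * max(1.0, norm):
        return RawApex(point=dia.point_at_fraction(0.5), fraction=0.5,
                       distance_mm=0.0, degenerate=True)
    cand = np.flatnonzero(dist >= dmax - 1e-9)
    i = int(cand[0])  # smallest arc-length fraction among ties
    total = dia.total_length_mm
    fraction = float(dia.cumulative_arclength_mm[i] / total) if total > 0 else 0.5
    return RawApex(point=pts[i].copy(), fraction=fraction,
                   distance_mm=float(dmax))


def derive_apex(fractions: list[float] | np.ndarray,
                dia_per_frame: list[DiaphragmContour]) -> tuple[float, list[np.ndarray]]:
    """Median raw-apex fraction of the series, re-applied to every frame.

    Returns the median fraction and, per frame, the point at that arc-length
    fraction along the frame's diaphragm contour (linear interpolation).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0:
        raise ValueError("empty fraction series")
    if fractions.size != len(dia_per_frame):
        raise ValueError("one fraction per frame is required")
    median = float(np.median(fractions))
    points = [dia.point_at_fraction(median) for dia in dia_per_frame]
    return median, points


def detect_landmarks(contour: LungContour, frame_index: int = 0
                     ) -> tuple[EllipseFit, np.ndarray, np.ndarray,
                                np.ndarray, np.ndarray, DiaphragmContour, RawApex]:
    """Run the full per-frame landmark chain on one contour."""
    ellipse = fit_orientation(contour)
    apex = find_lung_apex(contour, ellipse)
    centroid = compute_centroid(contour)
    anterior, posterior = find_costophrenic_angles(contour, ellipse, centroid)
    dia = diaphragm_contour(contour, anterior, posterior, apex)
    raw = find_diaphragm_apex_raw(dia)
    return ellipse, apex, centroid, anterior, posterior, dia, raw
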