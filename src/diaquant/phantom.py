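"""Synthetic respiratory-motion phantom with closed-form ground truth.

The phantom emulates a sagittal lung silhouette: a vertical-walled body of
width ``W`` (the AP extent) topped by a super-elliptic apex cap and closed
caudally by a diaphragm dome spanning the two basal (costophrenic) corners.
Every outcome has a closed form:

* dome profile ``y = d * (1 - (2s-1)^2)^p`` over the chord, with area
  ``W * d * f(p)``, ``f(p) = sqrt(pi) * Gamma(p+1) / (2 * Gamma(p+3/2))`` —
  the exponent ``p`` decouples dome area (DA) from dome height (DH);
* apex cap ``y = c * (1 - |2s-1|^q)^(1/q)`` with area ``W * c * g(q)``,
  ``g(q) = Gamma(1+1/q)^2 / Gamma(1+2/q)`` — the exponent ``q`` decouples
  lung area from the CC and AP extents (measured cohorts expand their area
  faster than CC x AP, because the expiratory lung is wedge-like and the
  inspiratory lung columnar);
* a circular-segment dome is also available for closed-form validation
  shapes (a half-disc dome of radius r has DA = pi r^2 / 2 and DH = r).

Frames interpolate geometrically between the end-expiration and
end-inspiration states; only the two end frames enter the ratios.  The
generator returns exact polygons, optional rasterised masks, and the
analytic ground-truth outcome record of the realised geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .contour import LungContour
from .io import FrameSeries, MaskFrame, Orientation, extract_contour
from .outcomes import OutcomeRecord


class PhantomError(ValueError):
    """Raised for inconsistent phantom parameters."""


# --------------------------------------------------------------------------
# closed-form shape factors


def power_dome_area_factor(p: float) -> float:
    """Area of the dome ``d*(1-(2s-1)^2)^p`` divided by chord x height."""
    if p < 0:
        raise PhantomError("dome exponent must be non-negative")
    return float(np.exp(0.5 * np.log(np.pi) + gammaln(p + 1.0)
                        - gammaln(p + 1.5)) / 2.0)


def superellipse_cap_factor(q: float) -> float:
    """Area of the half super-ellipse cap divided by width x height."""
    if q <= 0:
        raise PhantomError("cap exponent must be positive")
    return float(np.exp(2.0 * gammaln(1.0 + 1.0 / q)
                        - gammaln(1.0 + 2.0 / q)))


def circular_segment_area(chord_mm: float, height_mm: float) -> float:
    """Area of a circular segment from its chord and sagitta."""
    a = chord_mm / 2.0
    d = height_mm
    if d <= 0 or a <= 0 or d > a:
        raise PhantomError("circular segment needs 0 < height <= chord/2")
    r = (a * a + d * d) / (2.0 * d)
    half_angle = math.atan2(a, r - d)
    return r * r * (half_angle - math.sin(half_angle) * math.cos(half_angle))


def _solve_dome_exponent(area_factor: float) -> float:
    """Invert ``power_dome_area_factor`` (monotone decreasing in p)."""
    if not 0.0 < area_factor < 1.0:
        raise PhantomError(f"dome area factor {area_factor:.4f} outside (0, 1): "
                           "the requested DA ratio is unreachable")
    return float(brentq(lambda p: power_dome_area_factor(p) - area_factor,
                        1e-9, 500.0, xtol=1e-12))


# --------------------------------------------------------------------------
# polygon construction


def lung_polygon(width_mm: float, wall_height_mm: float, cap_height_mm: float,
                 dome_height_mm: float, *, dome_kind: str = "power",
                 dome_power: float = 1.0, cap_exponent: float = 2.0,
                 x_anterior: float = 0.0, y_base: float = 0.0,
                 n_vertices: int = 512) -> LungContour:
    """Assemble the phantom lung outline as an exact polygon.

    The basal corners sit at ``(x_anterior, y_base)`` and
    ``(x_anterior + width, y_base)``; both corners, the cap apex and the dome
    apex are exact vertices.
    """
    W, R, c, d = width_mm, wall_height_mm, cap_height_mm, dome_height_mm
    if min(W, R, c) <= 0 or d < 0:
        raise PhantomError("extents must be positive")
    if d >= R:
        raise PhantomError(f"dome height {d} must be smaller than the wall "
                           f"height {R} (dome deeper than lung)")
    if n_vertices < 64:
        raise PhantomError("need at least 64 vertices")
    a = W / 2.0
    # rough piece lengths for proportional vertex allocation
    len_dome = math.hypot(W, 2.5 * d)
    len_cap = math.pi / 2.0 * math.hypot(a, c)
    budget = max(n_vertices - 4, 48)
    total = len_dome + len_cap + 2.0 * R

    def npts(length: float, minimum: int = 8) -> int:
        n = max(minimum, int(round(budget * length / total)))
        return n + (n % 2)  # even interval count keeps midpoints exact

    n_dome, n_cap = npts(len_dome, 16), npts(len_cap, 16)
    n_wall = max(8, (budget - n_dome - n_cap) // 2)

    x0, y0 = x_anterior, y_base
    pieces = []
    # dome, anterior -> posterior (counter-clockwise start)
    s = np.linspace(0.0, 1.0, n_dome + 1)
    if d == 0:
        dome_y = np.zeros_like(s)
    elif dome_kind == "power":
        dome_y = d * np.power(np.clip(1.0 - (2.0 * s - 1.0) ** 2, 0.0, None),
                              dome_power)
    elif dome_kind == "circular":
        if d > a:
            raise PhantomError("circular dome height cannot exceed half the "
                               "chord")
        r = (a * a + d * d) / (2.0 * d)
        half = math.atan2(a, r - d)
        theta = np.linspace(math.pi / 2.0 + half, math.pi / 2.0 - half,
                            n_dome + 1)
        pieces.append(np.column_stack([x0 + a + r * np.cos(theta),
                                       y0 + (d - r) + r * np.sin(theta)]))
        dome_y = None
    else:
        raise PhantomError(f"unknown dome kind {dome_kind!r}")
    if dome_y is not None:
        pieces.append(np.column_stack([x0 + s * W, y0 + dome_y]))
    # posterior wall up
    yw = np.linspace(y0, y0 + R, n_wall + 1)[1:]
    pieces.append(np.column_stack([np.full_like(yw, x0 + W), yw]))
    # cap, posterior -> anterior
    t = np.linspace(1.0, -1.0, n_cap + 1)[1:]
    cap_y = c * np.power(np.clip(1.0 - np.abs(t) ** cap_exponent, 0.0, None),
                         1.0 / cap_exponent)
    pieces.append(np.column_stack([x0 + a + a * t, y0 + R + cap_y]))
    # anterior wall down (excluding both endpoints; the ring closes itself)
    yw = np.linspace(y0 + R, y0, n_wall + 1)[1:-1]
    pieces.append(np.column_stack([np.full_like(yw, x0), yw]))
    return LungContour(np.vstack(pieces))


def half_disc_validation_polygon(radius_mm: float = 30.0,
                                 base_margin_mm: float = 30.0,
                                 wall_height_mm: float = 100.0,
                                 cap_height_mm: float = 45.0,
                                 n_vertices: int = 1024) -> LungContour:
    """Validation shape with closed-form DA and DH.

    A half-disc dome of the given radius bulges cranially from the middle of
    a flat base, so DA = pi r^2 / 2 and DH = r exactly, while the basal
    corners remain sharp right angles that survive rasterisation (a
    half-disc meeting the wall directly has a vertical tangent there, and
    the resulting sub-pixel sliver cannot be represented on any raster).
    """
    r, m = radius_mm, base_margin_mm
    W = 2.0 * m + 2.0 * r
    n_arc = max(64, n_vertices // 2)
    n_arc += n_arc % 2
    n_side = max(8, (n_vertices - n_arc) // 6)
    x0 = 0.0
    pieces = []
    # base flat, anterior corner -> disc edge
    xs = np.linspace(x0, x0 + m, n_side + 1)
    pieces.append(np.column_stack([xs, np.zeros_like(xs)]))
    # half-disc arc bulging cranially, anterior -> posterior
    theta = np.linspace(np.pi, 0.0, n_arc + 1)[1:]
    pieces.append(np.column_stack([x0 + m + r + r * np.cos(theta),
                                   r * np.sin(theta)]))
    # base flat, disc edge -> posterior corner
    xs = np.linspace(x0 + m + 2 * r, x0 + W, n_side + 1)[1:]
    pieces.append(np.column_stack([xs, np.zeros_like(xs)]))
    # posterior wall, cap, anterior wall
    ys = np.linspace(0.0, wall_height_mm, n_side + 1)[1:]
    pieces.append(np.column_stack([np.full_like(ys, x0 + W), ys]))
    n_cap = 2 * n_side
    t = np.linspace(1.0, -1.0, n_cap + 1)[1:]
    cap_y = cap_height_mm * np.sqrt(np.clip(1.0 - t * t, 0.0, None))
    pieces.append(np.column_stack([x0 + W / 2 + (W / 2) * t,
                                   wall_height_mm + cap_y]))
    ys = np.linspace(wall_height_mm, 0.0, n_side + 1)[1:-1]
    pieces.append(np.column_stack([np.full_like(ys, x0), ys]))
    return LungContour(np.vstack(pieces))


def rasterize_series(polygons: list[LungContour], spacing_mm: float,
                     *, margin_mm: float = 6.0,
                     grid_offset_px: tuple[float, float] = (0.5, 0.5)
                     ) -> list[MaskFrame]:
    """Rasterise a polygon series onto one shared pixel grid.

    Row 0 is cranial and anterior is at smaller column index, matching the
    ``anterior_left`` reading convention.  A pixel is foreground iff its
    centre falls inside the polygon (the unbiased emulation of a manual
    segmentation; scan-fill rasterisers that include boundary pixels inflate
    the region by a fraction of a pixel along the whole perimeter).
    """
    import shapely

    allv = np.vstack([c.vertices for c in polygons])
    xmin, ymin = allv.min(axis=0) - margin_mm
    xmax, ymax = allv.max(axis=0) + margin_mm
    sr = sc = float(spacing_mm)
    orow, ocol = grid_offset_px
    n_rows = int(math.ceil((ymax - ymin) / sr)) + 2
    n_cols = int(math.ceil((xmax - xmin) / sc)) + 2
    # pixel-centre physical coordinates of the shared grid
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    y_centers = ymax - (rows - orow) * sr
    x_centers = xmin + (cols - ocol) * sc
    xg, yg = np.meshgrid(x_centers, y_centers)
    frames = []
    for i, contour in enumerate(polygons):
        poly = contour.polygon
        shapely.prepare(poly)
        mask = shapely.contains_xy(poly, xg.ravel(), yg.ravel())
        frames.append(MaskFrame(mask.reshape(n_rows, n_cols), (sr, sc),
                                frame_index=i,
                                orientation_flag=Orientation.ANTERIOR_LEFT))
    return frames


# --------------------------------------------------------------------------
# parameterised phantom series


@dataclass
class PhantomParams:
    """Ground-truth geometry and motion of one synthetic subject.

    Extents describe the end-expiration state; ``*_ratio_true`` are the
    end-inspiration / end-expiration targets.  ``area_ratio_true`` and
    ``da_ratio_true`` default to whatever the base geometry produces when
    left unset.
    """

    cc_exp_mm: float = 140.0
    ap_exp_mm: float = 120.0
    dome_height_exp_mm: float = 30.0
    cc_ratio_true: float = 1.0
    ap_ratio_true: float = 1.0
    dh_ratio_true: float = 1.0
    area_ratio_true: float | None = None
    da_ratio_true: float | None = None
    posterior_displacement_mm: float | None = None
    n_frames: int = 15
    vertices_per_contour: int = 512
    raster_spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cc_exp_mm, self.ap_exp_mm, self.dome_height_exp_mm) <= 0:
            raise PhantomError("extents must be positive")
        if self.dome_height_exp_mm >= self.cc_exp_mm:
            raise PhantomError("dome height must be smaller than the CC extent")
        for name in ("cc_ratio_true", "ap_ratio_true", "dh_ratio_true"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if self.n_frames < 2:
            raise PhantomError("need at least 2 frames")
        if self.vertices_per_contour < 64:
            raise PhantomError("need at least 64 vertices per contour")
        if self.raster_spacing_mm <= 0:
            raise PhantomError("raster spacing must be positive")


_GAMMA_CAP = 0.45      # cap height as a fraction of the above-chord extent
_Q_RANGE = (1.0, 4.0)  # cap exponent range swept by the area solve
# Expiratory dome exponent.  Chosen > 1 so that the solved inspiratory
# exponents of all phenotype presets also stay >= 1: exponents below 1 give
# the dome a vertical tangent at the corners, a degenerate geometry that
# both rasterises poorly and is anatomically implausible.
_P_EXP = 1.5


def _state_area(W: float, S: float, gamma: float, q: float,
                dome_area: float) -> float:
    return W * S * (1.0 - gamma * (1.0 - superellipse_cap_factor(q))) - dome_area


@dataclass(frozen=True)
class _State:
    """Realised geometry of one respiratory extreme."""

    W: float        # AP width = chord between basal corners
    cc: float       # lung apex to dome apex
    d: float        # dome height
    p: float        # dome exponent
    q: float        # cap exponent
    y_base: float   # chord level
    x_ant: float    # anterior corner x

    @property
    def S(self) -> float:
        return self.cc + self.d

    @property
    def dome_area(self) -> float:
        return self.W * self.d * power_dome_area_factor(self.p)

    @property
    def area(self) -> float:
        return _state_area(self.W, self.S, _GAMMA_CAP, self.q, self.dome_area)


def _solve_states(params: PhantomParams) -> tuple[_State, _State]:
    """Turn ratio targets into realised expiration/inspiration geometries."""
    W_e, cc_e, d_e = params.ap_exp_mm, params.cc_exp_mm, params.dome_height_exp_mm
    W_i = W_e * params.ap_ratio_true
    cc_i = cc_e * params.cc_ratio_true
    d_i = d_e * params.dh_ratio_true
    S_e, S_i = cc_e + d_e, cc_i + d_i
    gamma = _GAMMA_CAP
    for name, d, S in (("expiratory", d_e, S_e), ("inspiratory", d_i, S_i)):
        if d >= (1.0 - gamma) * S:
            raise PhantomError(f"{name} dome deeper than the lung body")

    dome_e = W_e * d_e * power_dome_area_factor(_P_EXP)
    if params.da_ratio_true is None:
        p_i = _P_EXP
    else:
        dome_i = params.da_ratio_true * dome_e
        p_i = _solve_dome_exponent(dome_i / (W_i * d_i))
    dome_i = W_i * d_i * power_dome_area_factor(p_i)

    q_lo, q_hi = _Q_RANGE
    if params.area_ratio_true is None:
        q_e = q_i = 2.0
    else:
        def ratio(t: float) -> float:
            qe = q_hi + t * (q_lo - q_hi)
            qi = q_lo + t * (q_hi - q_lo)
            return (_state_area(W_i, S_i, gamma, qi, dome_i)
                    / _state_area(W_e, S_e, gamma, qe, dome_e))

        lo, hi = ratio(0.0), ratio(1.0)
        target = params.area_ratio_true
        if not lo <= target <= hi:
            raise PhantomError(
                f"area_ratio_true={target:.3f} outside the feasible range "
                f"[{lo:.3f}, {hi:.3f}] for these CC/AP/DA/DH targets")
        t = float(brentq(lambda t: ratio(t) - target, 0.0, 1.0, xtol=1e-12))
        q_e = q_hi + t * (q_lo - q_hi)
        q_i = q_lo + t * (q_hi - q_lo)

    # basal chord drop realising the requested posterior-corner displacement
    dW = W_i - W_e
    if params.posterior_displacement_mm is None:
        dy = 0.0
    else:
        P = params.posterior_displacement_mm
        dy = -math.sqrt(P * P - dW * dW) if P > abs(dW) else 0.0

    exp = _State(W=W_e, cc=cc_e, d=d_e, p=_P_EXP, q=q_e, y_base=0.0, x_ant=0.0)
    insp = _State(W=W_i, cc=cc_i, d=d_i, p=p_i, q=q_i, y_base=dy, x_ant=0.0)
    return exp, insp


def feasible_area_ratio_range(params: PhantomParams) -> tuple[float, float]:
    """Achievable lung-area ratios for the given CC/AP/DA/DH targets."""
    probe = replace(params, area_ratio_true=None)
    exp, insp = _solve_states(probe)
    lows, highs = [], []
    q_lo, q_hi = _Q_RANGE
    for qe, qi in ((q_hi, q_lo), (q_lo, q_hi)):
        r = (_state_area(insp.W, insp.S, _GAMMA_CAP, qi, insp.dome_area)
             / _state_area(exp.W, exp.S, _GAMMA_CAP, qe, exp.dome_area))
        lows.append(r)
        highs.append(r)
    return min(lows), max(highs)


def _state_polygon(state: _State, n_vertices: int) -> LungContour:
    S = state.S
    return lung_polygon(state.W, (1.0 - _GAMMA_CAP) * S, _GAMMA_CAP * S,
                        state.d, dome_kind="power", dome_power=state.p,
                        cap_exponent=state.q, x_anterior=state.x_ant,
                        y_base=state.y_base, n_vertices=n_vertices)


def _ground_truth(exp: _State, insp: _State, subject_id: str) -> OutcomeRecord:
    rec = OutcomeRecord(subject_id=subject_id)
    rec.cc_ratio = insp.cc / exp.cc
    rec.ap_ratio = insp.W / exp.W
    rec.cc_ap_ratio = rec.cc_ratio / rec.ap_ratio
    rec.area_ratio = insp.area / exp.area
    rec.da_ratio = insp.dome_area / exp.dome_area
    rec.dh_ratio = insp.d / exp.d
    dy = insp.y_base - exp.y_base
    rec.ant_displacement_mm = abs(dy)
    rec.post_displacement_mm = math.hypot(insp.W - exp.W, dy)
    return rec


@dataclass
class PhantomSeries:
    """A generated subject: exact polygons, optional masks, analytic truth."""

    series: FrameSeries
    ground_truth: OutcomeRecord
    params: PhantomParams
    masks: list[MaskFrame] | None = None

    def mask_series(self) -> FrameSeries:
        """Contours re-extracted from the rasterised masks."""
        if self.masks is None:
            raise PhantomError("series was generated without rasterisation")
        return FrameSeries([extract_contour(f) for f in self.masks],
                           subject_id=self.series.subject_id,
                           spacing_mm=self.masks[0].spacing_mm)


def generate_phantom_series(params: PhantomParams, *, rasterize: bool = False,
                            subject_id: str = "phantom") -> PhantomSeries:
    """Generate one subject's respiratory frame series with known truth.

    The seed drives only nuisance randomness (a rigid whole-series
    translation and the sub-pixel placement of the raster grid), so the
    ground truth is exactly the analytic record of the solved geometry.
    """
    exp, insp = _solve_states(params)
    rng = np.random.default_rng(params.seed)
    shift = rng.uniform(-5.0, 5.0, size=2)
    grid_offset = tuple(rng.uniform(0.0, 1.0, size=2))

    n = params.n_frames
    polygons = []
    for k in range(n):
        u = k / (n - 1)
        state = _State(
            W=exp.W * (insp.W / exp.W) ** u,
            cc=exp.cc * (insp.cc / exp.cc) ** u,
            d=exp.d * (insp.d / exp.d) ** u,
            p=exp.p + u * (insp.p - exp.p),
            q=exp.q + u * (insp.q - exp.q),
            y_base=exp.y_base + u * (insp.y_base - exp.y_base),
            x_ant=exp.x_ant)
        poly = _state_polygon(state, params.vertices_per_contour)
        polygons.append(poly.transformed(translation_mm=tuple(shift)))

    series = FrameSeries(polygons, subject_id=subject_id)
    masks = None
    if rasterize:
        masks = rasterize_series(polygons, params.raster_spacing_mm,
                                 grid_offset_px=grid_offset)
    return PhantomSeries(series=series,
                         ground_truth=_ground_truth(exp, insp, subject_id),
                         params=params, masks=masks)


# --------------------------------------------------------------------------
# phenotype presets (group-mean outcome targets)

#: Group-mean outcome targets per phenotype.  The three cohort presets carry
#: the measured group means (CC, lung-area, CC-AP, DA, DH ratios and the
#: posterior-corner displacement); ``severe`` encodes the qualitative
#: severe-weakness picture: no net diaphragm excursion (CC ratio 1), largely
#: preserved chest-wall motion, strongly increased inspiratory curvature.
PRESETS: dict[str, dict[str, float]] = {
    "healthy": {"cc": 1.72, "area": 2.54, "cc_ap": 1.38, "da": 0.91,
                "dh": 0.82, "post_disp": 70.7},
    "normal_spiro_pompe": {"cc": 1.60, "area": 2.57, "cc_ap": 1.22,
                           "da": 1.34, "dh": 1.08, "post_disp": 70.6},
    "decreased_spiro_pompe": {"cc": 1.32, "area": 1.95, "cc_ap": 1.04,
                              "da": 1.79, "dh": 1.41, "post_disp": 35.6},
    "severe": {"cc": 1.00, "area": 1.25, "cc_ap": 0.909, "da": 2.20,
               "dh": 1.80, "post_disp": 10.0},
}

#: Order of increasing diaphragmatic weakness.
SEVERITY_ORDER = ("healthy", "normal_spiro_pompe", "decreased_spiro_pompe",
                  "severe")


def preset(name: str, *, seed: int = 0, n_frames: int = 15,
           raster_spacing_mm: float = 1.0) -> PhantomParams:
    """Phantom parameters whose true ratios equal a phenotype's group means."""
    try:
        tgt = PRESETS[name]
    except KeyError:
        raise PhantomError(f"unknown preset {name!r}; choose from "
                           f"{sorted(PRESETS)}") from None
    return PhantomParams(
        cc_ratio_true=tgt["cc"],
        ap_ratio_true=tgt["cc"] / tgt["cc_ap"],
        area_ratio_true=tgt["area"],
        da_ratio_true=tgt["da"],
        dh_ratio_true=tgt["dh"],
        posterior_displacement_mm=tgt["post_disp"],
        seed=seed, n_frames=n_frames, raster_spacing_mm=raster_spacing_mm)


# --------------------------------------------------------------------------
# cohorts, covariates and rater simulation


@dataclass
class GroupSpec:
    """One cohort group: a preset mean plus between-subject variation."""

    label: str
    n: int
    preset: str
    ratio_sd: dict[str, float] = field(default_factory=dict)
    age_mean: float = 43.0
    age_sd: float = 14.0
    male_fraction: float = 0.5

    #: documented defaults for the between-subject spread of the true ratios
    DEFAULT_SD = {"cc": 0.15, "ap": 0.08, "area": 0.25, "da": 0.25,
                  "dh": 0.20, "post_disp": 8.0}

    def sd(self, key: str) -> float:
        return self.ratio_sd.get(key, self.DEFAULT_SD[key])


@dataclass
class CohortSpec:
    """Group structure of a simulated cohort."""

    groups: list[GroupSpec]

    def __post_init__(self) -> None:
        if not self.groups:
            raise PhantomError("cohort needs at least one group")
        for g in self.groups:
            if g.n < 2:
                raise PhantomError(f"group {g.label!r} needs n >= 2")


def default_cohort_spec() -> CohortSpec:
    """Three-group cohort mirroring the study structure (22 / 13 / 18)."""
    return CohortSpec(groups=[
        GroupSpec("decreased_spiro_pompe", 22, "decreased_spiro_pompe",
                  age_mean=45, age_sd=16),
        GroupSpec("normal_spiro_pompe", 13, "normal_spiro_pompe",
                  age_mean=31, age_sd=14),
        GroupSpec("healthy", 18, "healthy", age_mean=43, age_sd=14),
    ])


# Linear link from the true CC ratio to simulated pulmonary-function values:
# (intercept, slope, noise sd).  Anchored so the cohort presets land near the
# study's group-mean PFT values, with noise sd matching the printed
# within-group spread (~10 for supine FVC, ~5 for the postural drop, ~24/28
# for mouth pressures).
_PFT_LINKS = {
    "fvc_supine_pct": (-78.6, 105.0, 10.0),
    "delta_fvc_pct": (77.2, -42.5, 5.0),
    "mip_pct": (-40.2, 85.0, 24.0),
    "mep_pct": (27.2, 40.0, 28.0),
}


def _simulate_pft(cc_true: float, rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for key, (intercept, slope, sd) in _PFT_LINKS.items():
        out[key] = intercept + slope * cc_true + rng.normal(0.0, sd)
    out["delta_fvc_pct"] = float(np.clip(out["delta_fvc_pct"], 0.0, 60.0))
    out["fvc_upright_pct"] = out["fvc_supine_pct"] + out["delta_fvc_pct"]
    return out


@dataclass
class CohortResult:
    """A simulated cohort: per-subject phantoms plus tabular truth/metadata."""

    subjects: list[PhantomSeries]
    truth: pd.DataFrame
    metadata: pd.DataFrame


def generate_cohort(spec: CohortSpec, seed: int, *, rasterize: bool = False,
                    n_frames: int = 15,
                    raster_spacing_mm: float = 1.0) -> CohortResult:
    """Draw per-subject true ratios around each group mean and generate.

    Draws outside the geometrically feasible lung-area band are clipped to
    it; everything is reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    subjects, truth_rows, meta_rows = [], [], []
    sid = 0
    for group in spec.groups:
        tgt = PRESETS[group.preset]
        ap_mean = tgt["cc"] / tgt["cc_ap"]
        for _ in range(group.n):
            sid += 1
            subject_id = f"S{sid:03d}"
            cc = max(0.85, rng.normal(tgt["cc"], group.sd("cc")))
            ap = max(0.85, rng.normal(ap_mean, group.sd("ap")))
            dh = max(0.20, rng.normal(tgt["dh"], group.sd("dh")))
            da = max(0.20, rng.normal(tgt["da"], group.sd("da")))
            # keep the drawn DA ratio inside the dome family's reachable
            # band (the dome area factor must stay within (0, 1))
            f_exp = power_dome_area_factor(_P_EXP)
            da = float(np.clip(da, 0.10 * ap * dh / f_exp,
                               0.95 * ap * dh / f_exp))
            area = rng.normal(tgt["area"], group.sd("area"))
            post = max(1.0, rng.normal(tgt["post_disp"], group.sd("post_disp")))
            params = PhantomParams(
                cc_ratio_true=cc, ap_ratio_true=ap, dh_ratio_true=dh,
                da_ratio_true=da, area_ratio_true=None,
                posterior_displacement_mm=post, n_frames=n_frames,
                raster_spacing_mm=raster_spacing_mm,
                seed=int(rng.integers(0, 2**31 - 1)))
            lo, hi = feasible_area_ratio_range(params)
            eps = 1e-3 * (hi - lo)
            params.area_ratio_true = float(np.clip(area, lo + eps, hi - eps))
            phantom = generate_phantom_series(params, rasterize=rasterize,
                                              subject_id=subject_id)
            subjects.append(phantom)
            truth_rows.append(phantom.ground_truth.as_dict()
                              | {"group": group.label})
            pft = _simulate_pft(cc, rng)
            meta_rows.append({
                "subject_id": subject_id, "group": group.label,
                "age": float(np.clip(rng.normal(group.age_mean, group.age_sd),
                                     8.0, 90.0)),
                "sex": "M" if rng.random() < group.male_fraction else "F",
                **{k: round(v, 1) for k, v in pft.items()},
            })
    return CohortResult(subjects=subjects,
                        truth=pd.DataFrame(truth_rows),
                        metadata=pd.DataFrame(meta_rows))


def simulate_raters(truth_values, rater_bias: float, noise_sd: float,
                    seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two paired measurement lists emulating a two-observer design.

    Rater A measures the truth plus Gaussian noise; rater B adds a constant
    bias on top of independent noise of the same magnitude.
    """
    if noise_sd < 0:
        raise PhantomError("noise_sd must be non-negative")
    v = np.asarray(truth_values, dtype=float)
    rng = np.random.default_rng(seed)
    a = v + rng.normal(0.0, noise_sd, size=v.shape)
    b = v + rater_bias + rng.normal(0.0, noise_sd, size=v.shape)
    return a, b
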