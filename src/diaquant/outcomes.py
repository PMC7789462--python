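"""Thorax- and diaphragm-related outcome measures.

Four thorax-related quantities (cranio-caudal distance CC, anterior-posterior
distance AP, their ratio-of-ratios CC-AP, and lung area) and four
diaphragm-related quantities (diaphragm dome area DA, dome height DH, and the
displacements of the anterior and posterior costophrenic angles) are measured
per frame, and summarised per subject as end-inspiration / end-expiration
ratios — ratios remove inter-subject anatomical size differences.

Sign convention: DA and DH are signed, positive when the dome bulges toward
the lung interior (cranial of the corner chord).  A dome that inverts between
expiration and inspiration (paradoxical motion) therefore flips sign rather
than silently folding onto its magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contour import ContourError, LungContour, signed_area
from .landmarks import DiaphragmContour, LandmarkSet


@dataclass(frozen=True)
class FrameOutcomes:
    """The per-frame measurements behind the subject-level ratios."""

    cc_mm: float
    ap_mm: float
    lung_area_mm2: float
    da_mm2: float
    dh_mm: float
    frame_index: int = 0


@dataclass
class OutcomeRecord:
    """Per-subject outcome ratios and corner displacements.

    Ratios are end-inspiration / end-expiration.  ``dh_ratio`` and
    ``da_ratio`` are NaN (with the corresponding flag set) when the
    expiratory denominator is too close to zero to be meaningful.
    """

    subject_id: str = ""
    cc_ratio: float = math.nan
    ap_ratio: float = math.nan
    cc_ap_ratio: float = math.nan
    area_ratio: float = math.nan
    da_ratio: float = math.nan
    dh_ratio: float = math.nan
    ant_displacement_mm: float = math.nan
    post_displacement_mm: float = math.nan
    dh_ratio_undefined: bool = False
    da_ratio_undefined: bool = False
    dome_sign_flip: bool = False
    ant_path_length_mm: float = field(default=math.nan, repr=False)
    post_path_length_mm: float = field(default=math.nan, repr=False)

    FIELDS = ("cc_ratio", "ap_ratio", "cc_ap_ratio", "area_ratio",
              "da_ratio", "dh_ratio", "ant_displacement_mm",
              "post_displacement_mm")

    def as_dict(self) -> dict:
        d = {"subject_id": self.subject_id}
        d.update({k: getattr(self, k) for k in self.FIELDS})
        d["dh_ratio_undefined"] = self.dh_ratio_undefined
        d["da_ratio_undefined"] = self.da_ratio_undefined
        d["dome_sign_flip"] = self.dome_sign_flip
        d["ant_path_length_mm"] = self.ant_path_length_mm
        d["post_path_length_mm"] = self.post_path_length_mm
        return d


def cc_distance(lung_apex: np.ndarray, apex_derived: np.ndarray) -> float:
    """Cranio-caudal extent: distance from lung apex to diaphragm apex."""
    return float(np.linalg.norm(np.asarray(lung_apex, float)
                                - np.asarray(apex_derived, float)))


def ap_distance(contour: LungContour) -> float:
    """Longest front-to-back extent along the orientation-normalised x axis."""
    x = contour.vertices[:, 0]
    return float(x.max() - x.min())


def lung_area(contour: LungContour) -> float:
    """Area of the segmentation (absolute shoelace area of the outline)."""
    if not contour.is_simple():
        raise ContourError("lung area is undefined for a self-intersecting "
                           "contour")
    return contour.area()


def diaphragm_area(dia: DiaphragmContour) -> float:
    """Signed area between the diaphragm contour and the corner chord.

    Positive when the dome bulges cranially (toward the lung interior).
    """
    pts = dia.points
    if pts.shape[0] < 3:
        raise ContourError("diaphragm contour needs >= 3 points")
    # closed loop: anterior -> dome -> posterior -> (chord back to anterior).
    # traversing a cranial bulge this way is clockwise, i.e. negative
    # shoelace, hence the sign flip.
    return float(-signed_area(pts))


def diaphragm_height(apex_derived: np.ndarray, anterior: np.ndarray,
                     posterior: np.ndarray) -> float:
    """Signed perpendicular distance from the diaphragm apex to the chord.

    Positive toward the lung interior (cranial side of the chord).
    """
    a = np.asarray(anterior, float)
    b = np.asarray(posterior, float)
    p = np.asarray(apex_derived, float)
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        raise ContourError("coincident costophrenic angles")
    u = chord / norm
    rel = p - a
    # left of the anterior->posterior direction = cranial for y-up frames
    return float(rel[0] * u[1] - rel[1] * u[0]) * -1.0


def corner_displacement(series: list[LandmarkSet], which: str,
                        *, mode: str = "net") -> float:
    """Displacement of a costophrenic angle across the series.

    ``mode='net'`` (the primary definition) is the Euclidean distance between
    the corner at the first and last frame; ``mode='path'`` is the summed
    frame-to-frame path length, exported as a jitter diagnostic.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 frames for a displacement")
    attr = {"anterior": "anterior_angle", "posterior": "posterior_angle"}[which]
    pts = np.array([getattr(lm, attr) for lm in series], dtype=float)
    if mode == "net":
        return float(np.linalg.norm(pts[-1] - pts[0]))
    if mode == "path":
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    raise ValueError(f"unknown displacement mode {mode!r}")


def compute_ratios(exp: FrameOutcomes, insp: FrameOutcomes,
                   *, min_exp_dh_mm: float = 0.5,
                   min_exp_da_mm2: float = 25.0,
                   subject_id: str = "") -> OutcomeRecord:
    """End-inspiration / end-expiration ratios of the frame outcomes.

    A near-flat expiratory diaphragm makes the DH (and DA) ratio numerically
    meaningless, so those ratios are flagged undefined (NaN) below the given
    denominator thresholds instead of being returned as huge numbers.
    """
    for name, val in (("cc", exp.cc_mm), ("ap", exp.ap_mm),
                      ("area", exp.lung_area_mm2)):
        if abs(val) < 1e-12:
            raise ZeroDivisionError(f"expiratory {name} is zero")
    rec = OutcomeRecord(subject_id=subject_id)
    rec.cc_ratio = insp.cc_mm / exp.cc_mm
    rec.ap_ratio = insp.ap_mm / exp.ap_mm
    rec.cc_ap_ratio = rec.cc_ratio / rec.ap_ratio
    rec.area_ratio = insp.lung_area_mm2 / exp.lung_area_mm2
    if abs(exp.dh_mm) < min_exp_dh_mm:
        rec.dh_ratio_undefined = True
    else:
        rec.dh_ratio = insp.dh_mm / exp.dh_mm
    if abs(exp.da_mm2) < min_exp_da_mm2:
        rec.da_ratio_undefined = True
    else:
        rec.da_ratio = insp.da_mm2 / exp.da_mm2
    if exp.dh_mm * insp.dh_mm < 0:
        rec.dome_sign_flip = True
    return rec
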