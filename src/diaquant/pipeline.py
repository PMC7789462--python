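"""End-to-end measurement: contours in, subject-level outcome record out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import landmarks as lm
from . import outcomes as oc
from .io import FrameSeries


@dataclass
class SubjectResult:
    """Everything measured for one subject's frame series."""

    series: FrameSeries
    landmark_sets: list[lm.LandmarkSet]
    frame_outcomes: list[oc.FrameOutcomes]
    record: oc.OutcomeRecord
    median_apex_fraction: float

    def landmarks_frame(self) -> pd.DataFrame:
        """Long-format per-frame landmark table."""
        rows = []
        for s in self.landmark_sets:
            for name in ("lung_apex", "centroid", "anterior_angle",
                         "posterior_angle", "apex_raw", "apex_derived"):
                x, y = getattr(s, name)
                frac = s.apex_raw_fraction if name == "apex_raw" else float("nan")
                rows.append((self.series.subject_id, s.frame_index, name,
                             x, y, frac))
        return pd.DataFrame(rows, columns=["subject_id", "frame_index",
                                           "landmark_name", "x_mm", "y_mm",
                                           "fraction"])

    def outcomes_frame(self) -> pd.DataFrame:
        """Long-format per-frame outcome table."""
        rows = [(self.series.subject_id, f.frame_index, f.cc_mm, f.ap_mm,
                 f.lung_area_mm2, f.da_mm2, f.dh_mm)
                for f in self.frame_outcomes]
        return pd.DataFrame(rows, columns=["subject_id", "frame_index",
                                           "cc_mm", "ap_mm", "lung_area_mm2",
                                           "da_mm2", "dh_mm"])


def measure_series(series: FrameSeries, *, min_exp_dh_mm: float = 0.5,
                   min_exp_da_mm2: float = 25.0) -> SubjectResult:
    """Measure all eight outcomes for one subject.

    Per frame: fit the orientation ellipse, locate the five reference points,
    isolate the diaphragm contour and its raw apex.  Across frames: take the
    median raw-apex arc-length fraction and re-apply it per frame (derived
    apex), then form end-inspiration / end-expiration ratios and the corner
    displacements between the two breath-hold frames.
    """
    per_frame = []
    for i, contour in enumerate(series.contours):
        ellipse, apex, centroid, anterior, posterior, dia, raw = \
            lm.detect_landmarks(contour, frame_index=i)
        per_frame.append((contour, ellipse, apex, centroid, anterior,
                          posterior, dia, raw))

    fractions = [raw.fraction for *_, raw in per_frame]
    dias = [dia for *_, dia, _ in per_frame]
    median_fraction, derived_points = lm.derive_apex(fractions, dias)

    landmark_sets = []
    frame_outcomes = []
    for i, ((contour, ellipse, apex, centroid, anterior, posterior, dia,
             raw), derived) in enumerate(zip(per_frame, derived_points)):
        landmark_sets.append(lm.LandmarkSet(
            lung_apex=apex, centroid=centroid, anterior_angle=anterior,
            posterior_angle=posterior, apex_raw=raw.point,
            apex_raw_fraction=raw.fraction, apex_derived=derived,
            frame_index=i))
        frame_outcomes.append(oc.FrameOutcomes(
            cc_mm=oc.cc_distance(apex, derived),
            ap_mm=oc.ap_distance(contour),
            lung_area_mm2=oc.lung_area(contour),
            da_mm2=oc.diaphragm_area(dia),
            dh_mm=oc.diaphragm_height(derived, anterior, posterior),
            frame_index=i))

    i_exp = series.end_expiration_index
    i_insp = series.end_inspiration_index
    record = oc.compute_ratios(frame_outcomes[i_exp], frame_outcomes[i_insp],
                               min_exp_dh_mm=min_exp_dh_mm,
                               min_exp_da_mm2=min_exp_da_mm2,
                               subject_id=series.subject_id)
    ends = [landmark_sets[i_exp], landmark_sets[i_insp]]
    record.ant_displacement_mm = oc.corner_displacement(ends, "anterior")
    record.post_displacement_mm = oc.corner_displacement(ends, "posterior")
    ordered = landmark_sets[min(i_exp, i_insp):max(i_exp, i_insp) + 1]
    record.ant_path_length_mm = oc.corner_displacement(ordered, "anterior",
                                                       mode="path")
    record.post_path_length_mm = oc.corner_displacement(ordered, "posterior",
                                                        mode="path")
    return SubjectResult(series=series, landmark_sets=landmark_sets,
                         frame_outcomes=frame_outcomes, record=record,
                         median_apex_fraction=median_fraction)
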