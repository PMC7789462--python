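"""Landmark detection against brute-force oracles and analytic shapes."""

from __future__ import annotations

import numpy as np
import pytest

import diaquant as dq
from diaquant.contour import ContourError
from diaquant.landmarks import detect_landmarks

from conftest import circle_contour, densify, ellipse_contour, \
    random_phantom_contour
import oracles


class TestFitOrientation:
    def test_axis_aligned_ellipse(self):
        contour = ellipse_contour(60.0, 30.0)
        fit = dq.fit_orientation(contour)
        assert fit.major_axis_angle_rad == pytest.approx(0.0, abs=0.01)
        assert fit.semi_major_mm == pytest.approx(60.0, rel=0.01)
        assert fit.semi_minor_mm == pytest.approx(30.0, rel=0.01)

    @pytest.mark.parametrize("angle", [0.3, -0.3, 0.15])
    def test_rotated_ellipse_angle_matches_principal_axes(self, angle):
        contour = ellipse_contour(60.0, 30.0, angle=angle, n=10_000)
        fit = dq.fit_orientation(contour)
        oracle = oracles.principal_axis_angle(contour.vertices)
        assert fit.major_axis_angle_rad == pytest.approx(oracle, abs=0.01)
        assert abs(fit.major_axis_angle_rad) == pytest.approx(abs(angle),
                                                              abs=0.01)

    def test_circle_has_equal_axes(self):
        fit = dq.fit_orientation(circle_contour(40.0))
        assert fit.semi_major_mm == pytest.approx(fit.semi_minor_mm, rel=0.01)
        assert fit.semi_major_mm == pytest.approx(40.0, rel=0.01)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ContourError):
            dq.LungContour(np.array([[0, 0], [1, 0], [1, 1]], float))

    def test_cranial_axis_has_positive_y_component(self, rng):
        for _ in range(10):
            contour = random_phantom_contour(rng)
            fit = dq.fit_orientation(contour)
            assert fit.major_axis_cranial[1] > 0


class TestLungApex:
    def test_upright_ellipse_apex_is_topmost(self):
        contour = ellipse_contour(60.0, 30.0, center=(10.0, 5.0))
        fit = dq.fit_orientation(contour)
        apex = dq.find_lung_apex(contour, fit)
        assert apex[1] == pytest.approx(65.0, abs=0.05)

    def test_matches_exhaustive_scan_on_tilted_contours(self, rng):
        for _ in range(25):
            contour = random_phantom_contour(rng)
            fit = dq.fit_orientation(contour)
            apex = dq.find_lung_apex(contour, fit)
            oracle = oracles.apex_by_scan(contour.vertices,
                                          fit.major_axis_angle_rad)
            assert np.allclose(apex, oracle)

    def test_tie_broken_by_smaller_x(self):
        pts = densify(np.array([[0, 0], [10, 0], [10, 5], [0, 5]], float),
                      per_edge=6)
        contour = dq.LungContour(pts)
        fit = dq.EllipseFit(center=np.array([5.0, 2.5]), semi_major_mm=5.0,
                            semi_minor_mm=2.5, major_axis_angle_rad=0.0)
        apex = dq.find_lung_apex(contour, fit)
        assert apex[1] == pytest.approx(5.0)
        assert apex[0] == pytest.approx(0.0)


class TestCentroid:
    def test_unit_square(self, square_contour):
        assert np.allclose(dq.compute_centroid(square_contour), [0.5, 0.5])

    def test_l_shape_matches_raster_mass(self):
        # two stacked unit squares forming an L: area centroid, not vertex mean
        pts = densify(np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2],
                                [0, 2]], float), per_edge=8)
        contour = dq.LungContour(pts)
        centroid = dq.compute_centroid(contour)
        oracle = oracles.centroid_by_raster(contour.vertices, resolution=0.005)
        assert np.allclose(centroid, oracle, atol=1e-3)

    def test_translation_equivariance(self, square_contour):
        moved = square_contour.transformed(translation_mm=(7.0, -3.0))
        assert np.allclose(dq.compute_centroid(moved),
                           dq.compute_centroid(square_contour) + [7.0, -3.0])


def _d_shape() -> dq.LungContour:
    """D-shaped phantom: sharp basal corners at (10, 0) and (90, 0)."""
    theta = np.linspace(np.pi, 0.0, 160)[1:-1]
    arc = np.column_stack([50.0 + 40.0 * np.cos(theta),
                           120.0 * np.sin(theta) ** 0.8])
    base = np.column_stack([np.linspace(10.0, 90.0, 40),
                            np.zeros(40)])
    return dq.LungContour(np.vstack([base, arc[::-1]])[::-1])


class TestCostophrenicAngles:
    def test_d_shape_sharp_corners(self):
        contour = _d_shape()
        fit = dq.fit_orientation(contour)
        centroid = dq.compute_centroid(contour)
        ant, post = dq.find_costophrenic_angles(contour, fit, centroid)
        assert np.allclose(ant, [10.0, 0.0], atol=1e-6)
        assert np.allclose(post, [90.0, 0.0], atol=1e-6)

    def test_half_disc_corners_are_chord_endpoints(self):
        theta = np.linspace(np.pi, 0.0, 200)
        dome = np.column_stack([50.0 + 50.0 * np.cos(theta),
                                50.0 * np.sin(theta)])
        contour = dq.LungContour(dome[::-1])
        fit = dq.fit_orientation(contour)
        centroid = dq.compute_centroid(contour)
        ant, post = dq.find_costophrenic_angles(contour, fit, centroid)
        assert np.allclose(ant, [0.0, 0.0], atol=1e-6)
        assert np.allclose(post, [100.0, 0.0], atol=1e-6)

    def test_rotation_moves_corners_with_the_contour(self):
        contour = _d_shape()
        fit = dq.fit_orientation(contour)
        centroid = dq.compute_centroid(contour)
        ant, post = dq.find_costophrenic_angles(contour, fit, centroid)
        angle = 0.2
        rotated = contour.transformed(rotation_rad=angle)
        rfit = dq.fit_orientation(rotated)
        rcentroid = dq.compute_centroid(rotated)
        rant, rpost = dq.find_costophrenic_angles(rotated, rfit, rcentroid)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        assert np.allclose(rant, rot @ ant, atol=0.5)
        assert np.allclose(rpost, rot @ post, atol=0.5)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(25):
            contour = random_phantom_contour(rng)
            fit = dq.fit_orientation(contour)
            centroid = dq.compute_centroid(contour)
            ant, post = dq.find_costophrenic_angles(contour, fit, centroid)
            oant, opost = oracles.corners_by_scan(contour.vertices,
                                                  fit.major_axis_angle_rad,
                                                  centroid)
            assert np.allclose(ant, oant)
            assert np.allclose(post, opost)


class TestDiaphragmContour:
    def test_circle_bottom_semicircle(self):
        # corners given at the lateral extremes, apex at the top: the path
        # avoiding the apex is the bottom semicircle
        contour = circle_contour(40.0, n=720)
        ant = np.array([-40.0, 0.0])
        post = np.array([40.0, 0.0])
        apex = np.array([0.0, 40.0])
        dia = dq.diaphragm_contour(contour, ant, post, apex)
        # the selected path avoids the apex and is the caudal half
        assert dia.points[:, 1].min() == pytest.approx(-40.0, abs=0.1)
        assert dia.points[:, 1].max() <= 1.0
        assert dia.total_length_mm == pytest.approx(np.pi * 40.0, rel=0.01)

    def test_orientation_normalised_anterior_to_posterior(self):
        contour = circle_contour(40.0, n=720)
        reversed_contour = dq.LungContour(contour.vertices[::-1])
        for c in (contour, reversed_contour):
            fit = dq.fit_orientation(c)
            centroid = dq.compute_centroid(c)
            apex = dq.find_lung_apex(c, fit)
            ant, post = dq.find_costophrenic_angles(c, fit, centroid)
            dia = dq.diaphragm_contour(c, ant, post, apex)
            assert dia.points[0, 0] < dia.points[-1, 0]

    def test_apex_on_corner_is_an_error(self, square_contour):
        v = square_contour.vertices
        with pytest.raises(ContourError):
            dq.diaphragm_contour(square_contour, v[0], v[1], v[0])


class TestRawApex:
    def test_half_disc_dome(self):
        theta = np.linspace(np.pi, 2.0 * np.pi, 301)
        pts = np.column_stack([30.0 + 30.0 * np.cos(theta),
                               -30.0 * np.abs(np.sin(theta))])
        pts[:, 1] = 30.0 * np.abs(np.sin(theta))  # dome bulging up
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        dia = dq.DiaphragmContour(pts, np.concatenate([[0], np.cumsum(seg)]))
        raw = dq.find_diaphragm_apex_raw(dia)
        assert raw.distance_mm == pytest.approx(30.0, abs=1e-6)
        assert raw.fraction == pytest.approx(0.5, abs=1e-6)
        assert not raw.degenerate

    def test_flat_diaphragm_flagged(self):
        pts = np.column_stack([np.linspace(0, 60, 31), np.zeros(31)])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        dia = dq.DiaphragmContour(pts, np.concatenate([[0], np.cumsum(seg)]))
        raw = dq.find_diaphragm_apex_raw(dia)
        assert raw.degenerate
        assert raw.distance_mm == 0.0
        assert raw.fraction == pytest.approx(0.5)

    def test_asymmetric_dome_matches_scan(self, rng):
        for _ in range(20):
            contour = random_phantom_contour(rng)
            _, apex, centroid, ant, post, dia, raw = detect_landmarks(contour)
            opoint, ofrac, odist = oracles.raw_apex_by_scan(dia.points)
            assert np.allclose(raw.point, opoint)
            assert raw.fraction == pytest.approx(ofrac, abs=1e-9)
            assert raw.distance_mm == pytest.approx(odist, abs=1e-6)


class TestDerivedApex:
    def test_median_fraction_examples(self):
        theta = np.linspace(np.pi, 0.0, 201)
        pts = np.column_stack([30.0 + 30.0 * np.cos(theta),
                               30.0 * np.sin(theta)])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        dia = dq.DiaphragmContour(pts, np.concatenate([[0], np.cumsum(seg)]))
        median, points = dq.derive_apex([0.40, 0.50, 0.60], [dia] * 3)
        assert median == pytest.approx(0.5)
        assert np.allclose(points[0], [30.0, 30.0], atol=0.01)
        median, _ = dq.derive_apex([0.2, 0.2, 0.9], [dia] * 3)
        assert median == pytest.approx(0.2)

    def test_interpolation_matches_oracle(self, rng):
        for _ in range(10):
            contour = random_phantom_contour(rng)
            *_, dia, raw = detect_landmarks(contour)
            fraction = rng.uniform(0.1, 0.9)
            _, points = dq.derive_apex([fraction], [dia])
            oracle = oracles.interpolate_along(dia.points, fraction)
            assert np.allclose(points[0], oracle, atol=1e-6)

    def test_empty_series_is_an_error(self):
        with pytest.raises(ValueError):
            dq.derive_apex([], [])


class TestEquivariance:
    def test_rigid_motion_moves_all_landmarks(self, rng):
        for _ in range(8):
            contour = random_phantom_contour(rng, rotate=False)
            angle = rng.uniform(-0.2, 0.2)
            shift = rng.uniform(-30.0, 30.0, size=2)
            moved = contour.transformed(rotation_rad=angle,
                                        translation_mm=tuple(shift))
            rot = np.array([[np.cos(angle), -np.sin(angle)],
                            [np.sin(angle), np.cos(angle)]])
            _, apex, centroid, ant, post, _, raw = detect_landmarks(contour)
            _, mapex, mcentroid, mant, mpost, _, mraw = \
                detect_landmarks(moved)
            for src, dst in ((apex, mapex), (centroid, mcentroid),
                             (ant, mant), (post, mpost),
                             (raw.point, mraw.point)):
                assert np.allclose(rot @ src + shift, dst, atol=0.75), \
                    f"landmark moved inconsistently under rigid motion"
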