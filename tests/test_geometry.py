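"""Contour geometry: azimuth ordering, shoelace area, acircularity."""
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import ConvexHull

import fazmorph as fm
from fazmorph import DegenerateContour, PixelScale, PointSet, ZeroRadius

from conftest import random_star_contour


def dense_acircularity_oracle(radii):
    """Independent sigma(R)/mean(R): plain-Python population statistics."""
    radii = [float(r) for r in radii]
    mean_r = sum(radii) / len(radii)
    var = sum((r - mean_r) ** 2 for r in radii) / len(radii)
    return math.sqrt(var) / mean_r


class TestSortByAzimuth:
    def test_square_corners_counterclockwise_from_smallest_azimuth(self, unit_square):
        contour = fm.sort_by_azimuth(unit_square)
        assert contour.points.tolist() == [[0, 0], [1, 0], [1, 1], [0, 1]]

    def test_already_sorted_input_is_stable(self):
        theta = np.linspace(-np.pi + 0.1, np.pi - 0.1, 50)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        out = fm.sort_by_azimuth(PointSet(pts)).points
        assert np.allclose(out, pts)

    @pytest.mark.parametrize("seed", range(10))
    def test_convex_cloud_sorts_to_hull_polygon(self, seed):
        """On convex boundaries the sorted polygon equals the convex hull."""
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, 200)
        a, b = rng.uniform(20, 60, 2)
        pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        area = fm.shoelace_area(fm.sort_by_azimuth(PointSet(pts)))
        hull = ConvexHull(pts)
        assert area == pytest.approx(hull.volume, rel=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(DegenerateContour):
            fm.sort_by_azimuth(PointSet(np.array([[0, 0], [1, 1]])))
        with pytest.raises(DegenerateContour):
            fm.sort_by_azimuth(PointSet(np.array([[0, 0], [1, 1], [2, 2], [3, 3]])))
        with pytest.raises(DegenerateContour):
            fm.sort_by_azimuth(PointSet(np.array([[0, 0], [0, 0], [1, 1], [1, 1]])))


class TestShoelaceArea:
    def test_closed_forms(self):
        square = fm.Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
        assert fm.shoelace_area(square) == pytest.approx(1.0)
        collinear = fm.Contour(np.array([[0, 0], [1, 1], [2, 2]]))
        assert fm.shoelace_area(collinear) == 0.0

    @pytest.mark.parametrize("n,r", [(3, 1.0), (6, 10.0), (360, 100.0)])
    def test_regular_ngon_matches_closed_form(self, n, r):
        theta = 2 * np.pi * np.arange(n) / n
        poly = fm.Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        expected = 0.5 * n * r**2 * math.sin(2 * math.pi / n)
        assert fm.shoelace_area(poly) == pytest.approx(expected, rel=1e-12)

    def test_orientation_independent(self):
        pts = np.array([[0, 0], [4, 0], [4, 3], [0, 3]], dtype=float)
        assert fm.shoelace_area(fm.Contour(pts)) == fm.shoelace_area(fm.Contour(pts[::-1]))


class TestUnitConversion:
    def test_triton_style_scale(self):
        scale = PixelScale.isotropic(3.0 / 320.0)
        assert fm.to_mm2(10000.0, scale) == pytest.approx(10000 * (3 / 320) ** 2)

    def test_identity_and_zero(self, identity_scale):
        assert fm.to_mm2(0.0, identity_scale) == 0.0
        assert fm.to_mm2(42.5, identity_scale) == 42.5

    def test_anisotropic_scale(self):
        assert fm.to_mm2(100.0, PixelScale(0.01, 0.02)) == pytest.approx(0.02)


class TestCentreAndRadii:
    def test_centre_is_coordinate_mean(self, unit_square):
        assert fm.contour_centre(unit_square) == (0.5, 0.5)
        tri = fm.Contour(np.array([[0, 0], [3, 0], [0, 3]]))
        assert fm.contour_centre(tri) == (1.0, 1.0)

    def test_circle_centre_recovered(self):
        theta = 2 * np.pi * np.arange(720) / 720
        pts = np.column_stack([5 + 2 * np.cos(theta), -3 + 2 * np.sin(theta)])
        cx, cy = fm.contour_centre(fm.Contour(pts))
        assert abs(cx - 5) < 1e-9 and abs(cy + 3) < 1e-9

    def test_radial_coordinates_order_and_values(self):
        contour = fm.Contour(np.array([[0, 0], [4, 0], [0, 3]]))
        radii = fm.radial_coordinates(contour, (0.0, 0.0))
        assert np.allclose(radii, [0.0, 4.0, 3.0])
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]])
        radii = fm.radial_coordinates(fm.Contour(square), (0.5, 0.5))
        assert np.allclose(radii, math.sqrt(0.5))


class TestAcircularity:
    def test_perfect_circle_is_zero(self):
        theta = 2 * np.pi * np.arange(360) / 360
        pts = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta)])
        assert fm.acircularity(fm.Contour(pts)) < 1e-12

    @pytest.mark.parametrize("a", [0.02, 0.05, 0.1, 0.2])
    def test_single_harmonic_continuum_value(self, a):
        """r(θ)=R0(1+a·cos kθ) has acircularity a/sqrt(2) in the dense limit."""
        theta = 2 * np.pi * np.arange(2000) / 2000
        r = 80 * (1 + a * np.cos(5 * theta))
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert fm.acircularity(fm.Contour(pts)) == pytest.approx(a / math.sqrt(2), abs=1e-3)

    def test_monotone_in_harmonic_amplitude(self):
        theta = 2 * np.pi * np.arange(2000) / 2000
        values = []
        for a in (0.02, 0.05, 0.1, 0.2):
            r = 80 * (1 + a * np.cos(5 * theta))
            pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            values.append(fm.acircularity(fm.Contour(pts)))
        assert values == sorted(values) and len(set(values)) == 4

    def test_ellipse_matches_dense_sampling_oracle(self):
        theta = 2 * np.pi * np.arange(2000) / 2000
        pts = np.column_stack([2.0 * np.cos(theta), 1.0 * np.sin(theta)])
        contour = fm.sort_by_azimuth(PointSet(pts))
        centre = fm.contour_centre(contour)
        expected = dense_acircularity_oracle(fm.radial_coordinates(contour, centre))
        assert fm.acircularity(contour) == pytest.approx(expected, abs=1e-6)

    def test_sample_sd_option_uses_n_minus_1(self):
        pts = np.array([[0, 0], [4, 0], [1, 2]], dtype=float)  # unequal radii
        contour = fm.Contour(pts)
        radii = fm.radial_coordinates(contour, fm.contour_centre(contour))
        pop = fm.acircularity(contour)
        samp = fm.acircularity(contour, ddof=1)
        assert samp == pytest.approx(statistics.stdev(radii) / np.mean(radii))
        assert samp > pop

    def test_all_points_at_centre_raises(self):
        pts = np.array([[1.0, 1.0]] * 5)
        with pytest.raises((ZeroRadius, DegenerateContour)):
            fm.acircularity(fm.Contour(pts))


class TestComputeMetrics:
    def test_unit_square_metrics(self, unit_square, identity_scale):
        m = fm.compute_metrics(unit_square, identity_scale)
        assert m.area_mm2 == pytest.approx(1.0)
        assert m.acircularity == pytest.approx(0.0, abs=1e-15)
        assert m.n_points == 4
        assert m.star_shaped
        assert m.acircularity == m.radial_sd_px / m.mean_radius_px
        assert m.radial_sd_px <= 1e-12  # bounded by max deviation (0 here)

    def test_rendered_circle_area_with_device_scale(self, meta):
        theta = 2 * np.pi * np.arange(2000) / 2000
        pts = np.unique(
            np.rint(np.column_stack([160 + 50 * np.cos(theta), 160 + 50 * np.sin(theta)])),
            axis=0,
        )
        m = fm.compute_metrics(PointSet(pts.astype(int)), PixelScale.isotropic(3 / 320))
        assert m.area_mm2 == pytest.approx(math.pi * 50**2 * (3 / 320) ** 2, rel=0.02)

    def test_translation_invariance_integer_shift(self, identity_scale):
        rng = np.random.default_rng(3)
        pts = random_star_contour(rng)
        m0 = fm.compute_metrics(PointSet(pts), identity_scale)
        m1 = fm.compute_metrics(PointSet(pts + np.array([37, -12])), identity_scale)
        assert m1.area_px2 == pytest.approx(m0.area_px2, rel=1e-9)
        assert m1.acircularity == pytest.approx(m0.acircularity, rel=1e-9)

    def test_self_intersecting_polygon_is_flagged_not_fatal(self, identity_scale):
        # bowtie vertex order: the closed polygon crosses itself
        bowtie = fm.Contour(np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]]))
        m = fm.compute_metrics(bowtie, identity_scale)
        assert not m.star_shaped

    def test_radial_sd_bounded_by_max_deviation(self, identity_scale):
        rng = np.random.default_rng(11)
        pts = random_star_contour(rng)
        m = fm.compute_metrics(PointSet(pts), identity_scale)
        contour = fm.sort_by_azimuth(PointSet(pts))
        radii = fm.radial_coordinates(contour, m.centre)
        assert m.radial_sd_px <= np.max(np.abs(radii - m.mean_radius_px)) + 1e-12


class TestInvarianceProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        tx=st.floats(-1e3, 1e3),
        ty=st.floats(-1e3, 1e3),
        s=st.floats(0.1, 50.0),
    )
    def test_translation_and_scale_laws(self, seed, tx, ty, s):
        identity_scale = PixelScale.isotropic(1.0)
        pts = random_star_contour(np.random.default_rng(seed), n=120)
        m0 = fm.compute_metrics(PointSet(pts), identity_scale, check_star_shaped=False)
        m_t = fm.compute_metrics(
            PointSet(pts + np.array([tx, ty])), identity_scale, check_star_shaped=False
        )
        assert m_t.area_px2 == pytest.approx(m0.area_px2, rel=1e-9)
        assert m_t.acircularity == pytest.approx(m0.acircularity, rel=1e-9, abs=1e-12)
        m_s = fm.compute_metrics(PointSet(pts * s), identity_scale, check_star_shaped=False)
        assert m_s.area_px2 == pytest.approx(m0.area_px2 * s**2, rel=1e-9)
        assert m_s.acircularity == pytest.approx(m0.acircularity, rel=1e-9, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), angle=st.floats(0, 2 * math.pi))
    def test_rotation_invariance(self, seed, angle):
        pts = random_star_contour(np.random.default_rng(seed), n=120)
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        a0 = fm.acircularity(fm.sort_by_azimuth(PointSet(pts)))
        a1 = fm.acircularity(fm.sort_by_azimuth(PointSet(pts @ rot.T)))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_circle_area_error_second_order_in_samples(self):
        r = 100.0
        errors = []
        for n in (64, 256):
            theta = 2 * np.pi * np.arange(n) / n
            pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            errors.append(math.pi * r**2 - fm.shoelace_area(fm.Contour(pts)))
        assert errors[1] < errors[0] / 4  # inscribed-polygon error is O(n^-2)
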