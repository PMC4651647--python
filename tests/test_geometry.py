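"""Curvature, ruled surfaces, interhelical area and surface torsion."""

import numpy as np
import pytest

from helixgeom import (
    AxisPolynomial,
    SingularGeometryError,
    build_ruled_surface,
    centre_line,
    compute_groove_descriptors,
    curvature,
    curvature_integral,
    distance_profile,
    distance_summary,
    extract_axis,
    fit_axis_polynomial,
    interhelical_area,
    surface_torsion,
)
from helixgeom.axis import AxisPoints, axis_u_grid

from conftest import random_rigid_motion


def line_poly(direction, origin=(0, 0, 0), domain=(1.0, 11.0)):
    d, o = np.asarray(direction, float), np.asarray(origin, float)
    return AxisPolynomial.from_coefficients(np.column_stack([o, d]), domain)


def transform_poly(poly, R, t):
    """Rigidly move a curve by transforming a dense resampling exactly."""
    raw = poly.coefficients
    new = np.asarray(R) @ raw
    new[:, 0] += t
    return AxisPolynomial.from_coefficients(new, poly.domain)


class TestCurvature:
    def test_straight_line_zero(self):
        poly = line_poly([1, 0, 0])
        u = np.linspace(1, 11, 20)
        np.testing.assert_allclose(curvature(poly, u), 0.0, atol=1e-14)
        assert curvature_integral(poly) == pytest.approx(0.0, abs=1e-12)

    def test_parabola_closed_form(self):
        # c(u) = (u, u^2, 0): kappa = 2 / (1 + 4u^2)^(3/2)
        poly = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 1], [0, 0, 0]], (-1.0, 1.0)
        )
        assert curvature(poly, 0.0) == pytest.approx(2.0, rel=1e-12)
        u = np.linspace(-1, 1, 11)
        np.testing.assert_allclose(
            curvature(poly, u), 2.0 / (1 + 4 * u**2) ** 1.5, rtol=1e-10
        )

    def test_circle_fit_recovers_radius(self):
        # degree-2 LS fit over a short arc of radius R: kappa ~ 1/R
        R = 2.0
        t = np.linspace(-0.15, 0.15, 12)
        pts = np.column_stack([R * np.sin(t), R * (1 - np.cos(t)), np.zeros_like(t)])
        axis = AxisPoints(pts, np.linspace(1.0, 13.0, 12), source_n_atoms=13)
        poly = fit_axis_polynomial(axis, 2)
        mid = 0.5 * (poly.domain[0] + poly.domain[1])
        # quadratic truncation of sin/cos over a +-0.15 rad arc leaves a
        # relative error of order t^2 ~ 0.4%
        assert curvature(poly, mid) == pytest.approx(1.0 / R, rel=5e-3)

    def test_quarter_arc_turning_angle(self):
        # dense degree-8 model of a quarter circle: integral ~ pi/2
        t = np.linspace(0, np.pi / 2, 200)
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        u = np.linspace(1.0, 200.0, 200)
        axis = AxisPoints(pts, u, source_n_atoms=201)
        poly = fit_axis_polynomial(axis, 8)
        assert curvature_integral(poly, n_points=2000) == pytest.approx(
            np.pi / 2, abs=1e-3
        )

    def test_quadrature_converged_at_default_resolution(self):
        poly = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 0.02], [0, 0, 0]], (1.0, 31.0)
        )
        a = curvature_integral(poly, n_points=100)
        b = curvature_integral(poly, n_points=200)
        assert abs(b - a) / abs(b) < 1e-3

    def test_vanishing_tangent_reported(self):
        # c(u) = (u^2, 0, 0) has c'(0) = 0
        poly = AxisPolynomial.from_coefficients(
            [[0, 0, 1], [0, 0, 0], [0, 0, 0]], (-1.0, 1.0)
        )
        with pytest.raises(SingularGeometryError):
            curvature(poly, 0.0)


class TestRuledSurface:
    def test_parallel_lines_constant_distance(self):
        s = build_ruled_surface(line_poly([1, 0, 0]), line_poly([1, 0, 0], [0, 2.0, 0]))
        np.testing.assert_allclose(distance_profile(s), 2.0, rtol=1e-12)
        assert distance_summary(s)["median"] == pytest.approx(2.0)

    def test_l_is_min_rule(self):
        s = build_ruled_surface(
            line_poly([1, 0, 0], domain=(1.0, 76.0)),
            line_poly([1, 0, 0], [0, 1, 0], domain=(1.0, 80.0)),
        )
        assert s.L == 76 and len(s.rulings) == 76

    def test_orientation_auto_idempotent(self):
        p1 = line_poly([1, 0, 0])
        d, o = np.array([1.0, 0.1, 0.0]), np.array([0.0, 2.0, 0.0])
        p2 = line_poly(d, o)  # c2(u) = o + u·d on [1, 11]
        p2_reversed = line_poly(-d, o + 12.0 * d)  # same line, parameter reversed
        s_fwd = build_ruled_surface(p1, p2)
        s_rev = build_ruled_surface(p1, p2_reversed)
        assert not s_fwd.orientation_reversed and s_rev.orientation_reversed
        np.testing.assert_allclose(s_fwd.rulings, s_rev.rulings, atol=1e-9)

    def test_linearly_diverging_distances(self):
        p1 = line_poly([1, 0, 0])
        p2 = line_poly([1, 0.1, 0], [0, 1.0, 0])  # gap grows linearly in x
        s = build_ruled_surface(p1, p2)
        d = distance_profile(s)
        np.testing.assert_allclose(np.diff(d, 2), 0.0, atol=1e-12)
        # gap is 1 + 0.1u on u in [1, 11]
        assert d[0] == pytest.approx(1.1) and d[-1] == pytest.approx(2.1)

    def test_distance_matches_direct_reevaluation(self, rng):
        c1 = AxisPolynomial.from_coefficients(rng.normal(size=(3, 3)), (1.0, 21.0))
        c2 = AxisPolynomial.from_coefficients(
            rng.normal(size=(3, 3)) + [[5], [5], [5]], (1.0, 21.0)
        )
        s = build_ruled_surface(c1, c2, orientation_policy="keep")
        brute = np.linalg.norm(c2(s.u_grid2) - c1(s.u_grid1), axis=1)
        np.testing.assert_allclose(distance_profile(s), brute, rtol=1e-9)


class TestArea:
    def test_flat_rectangle_exact(self):
        ell, d = 10.0, 2.0
        s = build_ruled_surface(line_poly([1, 0, 0]), line_poly([1, 0, 0], [0, d, 0]))
        assert interhelical_area(s) == pytest.approx(ell * d, rel=1e-12)

    def test_translated_curve_band(self):
        # helix 2 = helix 1 shifted perpendicular to its plane of curvature
        d = 0.5
        c1 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 0.05], [0, 0, 0]], (1.0, 31.0)
        )
        c2 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 0.05], [d, 0, 0]], (1.0, 31.0)
        )
        s = build_ruled_surface(c1, c2)
        u = np.linspace(1, 31, 3001)
        arc = np.trapezoid(np.linalg.norm(c1.derivative(u), axis=1), u)
        assert interhelical_area(s) == pytest.approx(d * arc, rel=0.01)

    def test_swap_symmetric(self, rng):
        c1 = AxisPolynomial.from_coefficients(rng.normal(size=(3, 3)), (1.0, 21.0))
        c2 = AxisPolynomial.from_coefficients(
            rng.normal(size=(3, 3)) + [[4], [0], [0]], (1.0, 21.0)
        )
        a12 = interhelical_area(build_ruled_surface(c1, c2))
        a21 = interhelical_area(build_ruled_surface(c2, c1))
        assert a12 == pytest.approx(a21, rel=1e-12)


class TestCentreLine:
    def test_midline_of_parallel_lines(self):
        s = build_ruled_surface(line_poly([1, 0, 0]), line_poly([1, 0, 0], [0, 2, 0]))
        mid = centre_line(s)
        pts = mid(np.linspace(1, s.L, 5))
        np.testing.assert_allclose(pts[:, 1], 1.0, atol=1e-12)

    def test_identical_curves_give_same_line(self):
        c1 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 0.05], [0, 0, 0]], (1.0, 11.0)
        )
        c2 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 0.05], [1e-6, 0, 0]], (1.0, 11.0)
        )
        s = build_ruled_surface(c1, c2)
        mid = centre_line(s)
        np.testing.assert_allclose(mid(s.s_grid), c1(s.u_grid1), atol=1e-6)

    def test_opposite_parabolas_cancel(self):
        a = 0.05
        c1 = AxisPolynomial.from_coefficients([[0, 1, 0], [0, 0, a], [1, 0, 0]], (1.0, 11.0))
        c2 = AxisPolynomial.from_coefficients([[0, 1, 0], [0, 0, -a], [-1, 0, 0]], (1.0, 11.0))
        mid = centre_line(build_ruled_surface(c1, c2))
        assert curvature_integral(mid) == pytest.approx(0.0, abs=1e-12)


class TestSurfaceTorsion:
    def test_parallel_rulings_developable(self):
        s = build_ruled_surface(line_poly([1, 0, 0]), line_poly([1, 0, 0], [0, 2, 0]))
        tau, T = surface_torsion(s)
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)
        assert T == pytest.approx(0.0, abs=1e-12)

    def test_planar_surface_zero_torsion(self):
        # both curves and rulings in the xy-plane
        c1 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 0.05], [0, 0, 0]], (1.0, 11.0)
        )
        c2 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [1.5, 0.02, 0.05], [0, 0, 0]], (1.0, 11.0)
        )
        tau, T = surface_torsion(build_ruled_surface(c1, c2))
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)

    def test_rotating_ruling_matches_finite_difference_oracle(self):
        # ruling tilts linearly out of plane along the path
        eps = 0.05
        c1 = line_poly([1, 0, 0], domain=(1.0, 21.0))
        c2 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [1, 0, 0], [-eps * 11, eps, 0]], (1.0, 21.0)
        )
        s = build_ruled_surface(c1, c2, orientation_policy="keep")
        tau, _ = surface_torsion(s)

        grid = s.s_grid
        h = 1e-6
        X = lambda x: s.q2(x) - s.q1(x)
        for i in [2, 10, 18]:
            x0 = grid[i]
            Xp = (X(x0 + h) - X(x0 - h)) / (2 * h)
            m1 = 0.5 * (s.q1.derivative(x0) + s.q2.derivative(x0))
            t = m1 / np.linalg.norm(m1)
            oracle = np.cross(X(x0), Xp) @ t / (X(x0) @ X(x0))
            assert tau[i] == pytest.approx(oracle, abs=1e-4)

    def test_printed_convention_annihilates_torsion(self):
        eps = 0.05
        c1 = line_poly([1, 0, 0], domain=(1.0, 21.0))
        c2 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [1, 0, 0], [-eps * 11, eps, 0]], (1.0, 21.0)
        )
        s = build_ruled_surface(c1, c2, orientation_policy="keep")
        tau_c, T_c = surface_torsion(s, convention="corrected")
        tau_p, T_p = surface_torsion(s, convention="printed")
        assert np.abs(tau_c).max() > 1e-3
        np.testing.assert_allclose(tau_p, 0.0, atol=1e-12)

    def test_mirror_flips_torsion_sign_keeps_curvature_and_area(self, rng):
        c1 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 0.05], [0.5, 0.01, 0]], (1.0, 21.0)
        )
        c2 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [2, 0, -0.02], [0, 0.03, 0.002]], (1.0, 21.0)
        )
        M = np.diag([1.0, 1.0, -1.0])
        m1 = transform_poly(c1, M, np.zeros(3))
        m2 = transform_poly(c2, M, np.zeros(3))
        d = compute_groove_descriptors(c1, c2)
        dm = compute_groove_descriptors(m1, m2)
        np.testing.assert_allclose(dm.torsion_profile, -d.torsion_profile, atol=1e-10)
        assert dm.torsion_integral == pytest.approx(-d.torsion_integral, abs=1e-10)
        assert dm.area == pytest.approx(d.area, rel=1e-12)
        assert dm.curvature_integral_1 == pytest.approx(d.curvature_integral_1, rel=1e-12)

    def test_zero_length_ruling_reported(self):
        c1 = line_poly([1, 0, 0])
        with pytest.raises(SingularGeometryError):
            surface_torsion(build_ruled_surface(c1, c1, orientation_policy="keep"))


class TestInvariance:
    def test_descriptors_invariant_under_common_rigid_motion(self, rng):
        c1 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [0, 0, 0.05], [0.5, 0.01, 0]], (1.0, 31.0)
        )
        c2 = AxisPolynomial.from_coefficients(
            [[0, 1, 0], [2, 0, -0.02], [0, 0.03, 0.002]], (1.0, 31.0)
        )
        d0 = compute_groove_descriptors(c1, c2)
        for _ in range(3):
            R, t = random_rigid_motion(rng)
            d1 = compute_groove_descriptors(
                transform_poly(c1, R, t), transform_poly(c2, R, t)
            )
            for attr in (
                "curvature_integral_1",
                "curvature_integral_2",
                "area",
                "torsion_integral",
                "centreline_curvature_integral",
            ):
                a, b = getattr(d0, attr), getattr(d1, attr)
                assert b == pytest.approx(a, rel=1e-9, abs=1e-11), attr
            np.testing.assert_allclose(
                d1.distance_profile, d0.distance_profile, rtol=1e-9
            )
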