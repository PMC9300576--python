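"""Geometric primitive tests: sphere/circle fits, planes, projections,
RANSAC trial counts, vector angles, IDW interpolation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares

from femnsa import geometry as geo


def octahedron():
    return np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    )


def fibonacci_sphere(n):
    i = np.arange(n)
    z = 1 - (2 * i + 1) / n
    rho = np.sqrt(1 - z**2)
    phi = np.pi * (np.sqrt(5) - 1) * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


class TestSphereFit:
    def test_exact_octahedron(self):
        s = geo.fit_sphere_lsq(octahedron())
        np.testing.assert_allclose(s.center, [0, 0, 0], atol=1e-12)
        assert s.radius == pytest.approx(1.0, abs=1e-12)

    def test_translation_equivariance(self):
        s = geo.fit_sphere_lsq(octahedron() + [10, 20, 30])
        np.testing.assert_allclose(s.center, [10, 20, 30], atol=1e-9)
        assert s.radius == pytest.approx(1.0, abs=1e-9)

    def test_rotation_equivariance(self, random_rotation):
        R = random_rotation(3)
        pts = 22.0 * fibonacci_sphere(200) + [5, -3, 2]
        a = geo.fit_sphere_lsq(pts)
        b = geo.fit_sphere_lsq(pts @ R.T)
        np.testing.assert_allclose(b.center, R @ a.center, atol=1e-9)
        assert b.radius == pytest.approx(a.radius, abs=1e-9)

    def test_noisy_fit_matches_geometric_lsq_oracle(self):
        # oracle: iterative geometric least squares started at the truth
        rng = np.random.default_rng(7)
        true_c = np.array([5.0, -3.0, 2.0])
        pts = true_c + 22.0 * fibonacci_sphere(2048) + rng.normal(0, 0.5, (2048, 3))

        def resid(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        oracle = least_squares(resid, np.r_[true_c, 22.0], method="lm").x
        fit = geo.fit_sphere_lsq(pts)
        assert np.linalg.norm(fit.center - oracle[:3]) <= 0.05
        assert fit.radius == pytest.approx(oracle[3], abs=0.05)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            geo.fit_sphere_lsq(octahedron()[:3])
        coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]], float)
        with pytest.raises(geo.DegenerateGeometryError):
            geo.fit_sphere_lsq(coplanar)


class TestCentroid:
    def test_arithmetic_mean(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], float)
        np.testing.assert_allclose(geo.centroid(pts), [0.5, 0.5, 0.5])

    def test_single_point_identity(self):
        np.testing.assert_allclose(geo.centroid([[3.0, 1.0, -2.0]]), [3, 1, -2])

    def test_rotation_equivariance(self, random_rotation):
        R = random_rotation(1)
        pts = np.random.default_rng(0).normal(size=(40, 3))
        np.testing.assert_allclose(geo.centroid(pts @ R.T), R @ geo.centroid(pts), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geo.centroid(np.empty((0, 3)))


class TestPlane:
    def test_coordinate_plane(self):
        p = geo.plane_from_points([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert abs(abs(p.C) - 1.0) < 1e-12
        assert abs(p.A) < 1e-12 and abs(p.B) < 1e-12 and abs(p.D) < 1e-12

    def test_containment_residual(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tri = rng.normal(scale=50, size=(3, 3))
            plane = geo.plane_from_points(*tri)
            assert np.all(np.abs(plane.signed_distance(tri)) <= 1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(geo.DegenerateGeometryError):
            geo.plane_from_points([0, 0, 0], [1, 1, 1], [2, 2, 2])


class TestProjection:
    def test_axis_aligned(self):
        plane = geo.plane_from_points([0, 0, 0], [1, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(geo.project_point(plane, [1, 1, 1]), [1, 1, 0], atol=1e-12)

    def test_oblique_plane_foot(self):
        # x + y + z - 3 = 0; from the origin t = -1 and the foot is (1,1,1)
        plane = geo.plane_from_points([3, 0, 0], [0, 3, 0], [0, 0, 3])
        np.testing.assert_allclose(geo.project_point(plane, [0, 0, 0]), [1, 1, 1], atol=1e-9)

    def test_idempotent_and_minimizing(self):
        rng = np.random.default_rng(5)
        plane = geo.plane_from_points(*rng.normal(scale=10, size=(3, 3)))
        p = rng.normal(scale=10, size=3)
        foot = geo.project_point(plane, p)
        np.testing.assert_allclose(geo.project_point(plane, foot), foot, atol=1e-9)
        # any other plane point is farther away
        e1, e2 = geo.plane_basis(plane, foot)
        for q2 in rng.normal(scale=5, size=(25, 2)):
            q = geo.from_plane_coords(q2, foot, e1, e2)
            assert np.linalg.norm(p - foot) <= np.linalg.norm(p - q) + 1e-12

    def test_projection_commutes_with_centroid(self):
        rng = np.random.default_rng(6)
        plane = geo.plane_from_points(*rng.normal(scale=10, size=(3, 3)))
        pts = rng.normal(scale=30, size=(100, 3))
        lhs = geo.project_point(plane, geo.centroid(pts))
        rhs = geo.centroid(geo.project_point(plane, pts))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestPlaneBasis:
    def test_orthonormal_and_roundtrip(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            plane = geo.plane_from_points(*rng.normal(scale=10, size=(3, 3)))
            origin = geo.project_point(plane, rng.normal(scale=10, size=3))
            e1, e2 = geo.plane_basis(plane, origin)
            n = plane.normal
            assert abs(e1 @ e2) <= 1e-12 and abs(e1 @ n) <= 1e-12 and abs(e2 @ n) <= 1e-12
            assert abs(np.linalg.norm(e1) - 1) <= 1e-12
            p = geo.project_point(plane, rng.normal(scale=10, size=3))
            back = geo.from_plane_coords(geo.to_plane_coords(p, origin, e1, e2), origin, e1, e2)
            np.testing.assert_allclose(back, p, atol=1e-9)

    def test_deterministic_for_plane(self):
        plane = geo.plane_from_points([0, 0, 1], [1, 0, 1], [0, 1, 1])
        a = geo.plane_basis(plane, np.array([0.0, 0.0, 1.0]))
        b = geo.plane_basis(plane, np.array([5.0, 5.0, 1.0]))
        np.testing.assert_allclose(a[0], b[0])
        np.testing.assert_allclose(a[1], b[1])


class TestRansacTrials:
    def test_reference_value(self):
        assert geo.ransac_trials(0.99, 0.5, 3) == 35

    def test_all_inliers(self):
        assert geo.ransac_trials(0.99, 1.0, 3) == 1

    def test_monotone(self):
        base = geo.ransac_trials(0.99, 0.5, 3)
        assert geo.ransac_trials(0.999, 0.5, 3) >= base
        assert geo.ransac_trials(0.99, 0.4, 3) >= base

    def test_matches_arbitrary_precision(self):
        # oracle: 50-digit decimal evaluation of the trial-count formula
        import decimal
        import math

        ctx = decimal.Context(prec=50)
        for P in ("0.9", "0.99", "0.999"):
            for rho10 in range(2, 10):
                for K in (3, 4):
                    good = ctx.power(decimal.Decimal(rho10) / 10, K)
                    s = ctx.divide(
                        ctx.ln(1 - decimal.Decimal(P)), ctx.ln(1 - good)
                    )
                    assert geo.ransac_trials(float(P), rho10 / 10, K) == math.ceil(s)


def circle_points(center, radius, n, rng=None, sigma=0.0):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.asarray(center) + radius * np.column_stack([np.cos(ang), np.sin(ang)])
    if sigma and rng is not None:
        pts = pts + rng.normal(0, sigma, pts.shape)
    return pts


class TestCircleRansac:
    def test_noiseless_consensus(self):
        pts = circle_points([3, 4], 10, 100)
        circ, mask = geo.fit_circle_ransac(pts, geo.RansacConfig(seed=0))
        np.testing.assert_allclose(circ.center, [3, 4], atol=1e-9)
        assert mask.all()

    def test_minimal_set_is_circumcircle(self):
        tri = np.array([[0, 0], [2, 0], [1, 1]], float)
        circ, _ = geo.fit_circle_ransac(tri, geo.RansacConfig(seed=1))
        ref = geo.circumcircle_2d(*tri)
        np.testing.assert_allclose(circ.center, ref.center, atol=1e-9)
        assert circ.radius == pytest.approx(ref.radius, abs=1e-9)

    def test_outlier_robustness_vs_clean_lsq(self):
        rng = np.random.default_rng(11)
        inl = circle_points([3, 4], 10, 200, rng, sigma=0.3)
        out = rng.uniform([-7, -6], [13, 14], size=(50, 2))
        pts = np.vstack([inl, out])
        circ, mask = geo.fit_circle_ransac(pts, geo.RansacConfig(inlier_threshold=1.0, seed=2))
        ref = geo.fit_circle_lsq(inl)  # least squares on the known-clean subset
        assert np.linalg.norm(circ.center - ref.center) <= 0.5
        assert np.linalg.norm(circ.center - [3, 4]) <= 0.5
        assert mask.sum() >= 180

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(12)
        pts = np.vstack(
            [circle_points([0, 0], 8, 150, rng, sigma=0.3), rng.uniform(-9, 9, size=(40, 2))]
        )
        cfg = geo.RansacConfig(seed=42)
        a = geo.fit_circle_ransac(pts, cfg)
        b = geo.fit_circle_ransac(pts, cfg)
        assert np.array_equal(a[0].center, b[0].center)
        assert a[0].radius == b[0].radius
        assert np.array_equal(a[1], b[1])

    def test_center_recovery_over_seeds(self):
        # 20% outliers, 1 mm threshold: center within 0.5 mm every run
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            inl = circle_points([3, 4], 10, 160, rng, sigma=0.3)
            out = rng.uniform([-7, -6], [13, 14], size=(40, 2))
            circ, _ = geo.fit_circle_ransac(
                np.vstack([inl, out]), geo.RansacConfig(inlier_threshold=1.0, seed=seed)
            )
            assert np.linalg.norm(circ.center - [3, 4]) <= 0.5

    def test_collinear_failure(self):
        pts = np.column_stack([np.linspace(0, 10, 30), np.zeros(30)])
        with pytest.raises((geo.FitFailureError, geo.DegenerateGeometryError)):
            geo.fit_circle_ransac(pts, geo.RansacConfig(seed=0))


class TestAngleBetween:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 1, 0), (1, 0, 0), 45.0),
        ],
    )
    def test_closed_form(self, u, v, expected):
        assert geo.angle_between(u, v) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_supplement(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=(2, 3))
        a = geo.angle_between(u, v)
        assert a == pytest.approx(geo.angle_between(v, u), abs=1e-9)
        assert geo.angle_between(u, -v) == pytest.approx(180.0 - a, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            geo.angle_between((0, 0, 0), (1, 0, 0))


class TestIdw:
    def test_midpoint_symmetry(self):
        val = geo.idw_interpolate(
            [0.5, 0, 0], [[0, 0, 0], [1, 0, 0]], [0.0, 1.0], power=2, k=2
        )
        assert val == pytest.approx(0.5)

    def test_exact_match_branch(self):
        val = geo.idw_interpolate([1, 2, 3], [[0, 0, 0], [1, 2, 3]], [1.0, 7.0])
        assert val == 7.0

    def test_weighted_mean(self):
        # distances 1 and 2, values 0 and 3, p=2: (1*0 + 0.25*3) / 1.25 = 0.6
        val = geo.idw_interpolate(
            [0, 0, 0], [[1, 0, 0], [0, 2, 0]], [0.0, 3.0], power=2, k=2
        )
        assert val == pytest.approx(0.6, abs=1e-12)

    def test_symmetric_neighbors_reproduce_affine_field(self):
        rng = np.random.default_rng(3)
        coeffs = rng.normal(size=3)
        q = rng.normal(size=3)
        offsets = rng.normal(size=(5, 3))
        neighbors = np.vstack([q + offsets, q - offsets])
        values = neighbors @ coeffs + 2.0
        got = geo.idw_interpolate(q, neighbors, values, power=2, k=len(neighbors))
        # symmetric pairs at equal distance cancel the linear term
        assert got == pytest.approx(float(q @ coeffs + 2.0), abs=1e-9)

    def test_vector_values(self):
        v = geo.idw_interpolate(
            [0.5, 0, 0], [[0, 0, 0], [1, 0, 0]], [[0.0, 2.0], [1.0, 4.0]], k=2
        )
        np.testing.assert_allclose(v, [0.5, 3.0])
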