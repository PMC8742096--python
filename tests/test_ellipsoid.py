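import numpy as np
import pytest
from scipy.spatial import cKDTree

from cranioshape import Ellipsoid, EllipsoidFitter, fit_ellipsoid, foot_point, signed_distances, surface_samples
from cranioshape.errors import FitError, InsufficientDataError
from cranioshape.synth import fibonacci_cap

from conftest import ellipsoid_cloud, sphere_cloud


class TestFit:
    def test_recovers_exact_ellipsoid_parameters(self):
        pts = ellipsoid_cloud(500, (90, 70, 60), seed=1, center=(1, -2, 3))
        e = fit_ellipsoid(pts)
        np.testing.assert_allclose(e.center, [1, -2, 3], atol=1e-6)
        np.testing.assert_allclose(e.semi_axes, [90, 70, 60], atol=1e-6)

    def test_sphere_limit(self):
        e = fit_ellipsoid(sphere_cloud(500, 75.0, seed=2))
        np.testing.assert_allclose(e.semi_axes, 75.0, atol=1e-6)
        np.testing.assert_allclose(e.center, 0.0, atol=1e-6)

    def test_coplanar_cloud_rejected(self):
        rng = np.random.default_rng(3)
        flat = np.column_stack([rng.uniform(-90, 90, (200, 2)), np.zeros(200)])
        with pytest.raises(FitError):
            fit_ellipsoid(flat)

    def test_too_few_points_rejected(self):
        with pytest.raises((InsufficientDataError, ValueError)):
            fit_ellipsoid(ellipsoid_cloud(8, (90, 70, 60)))

    def test_algebraic_cost_is_local_minimum(self):
        rng = np.random.default_rng(4)
        pts = ellipsoid_cloud(400, (88, 66, 61), seed=5, center=(2, 1, -3))
        pts = pts + rng.normal(0, 0.5, pts.shape)
        e = fit_ellipsoid(pts)

        def algebraic_cost(center, axes):
            k = 1.0 - np.sum(np.asarray(center) ** 2 / np.asarray(axes) ** 2)
            quad = (1.0 / np.asarray(axes) ** 2) / k
            lin = (-2.0 * np.asarray(center) / np.asarray(axes) ** 2) / k
            resid = pts**2 @ quad + pts @ lin - 1.0
            return float(resid @ resid)

        base = algebraic_cost(e.center, e.semi_axes)
        for i in range(3):
            for scale in (0.99, 1.01):
                c = e.center.copy()
                c[i] = c[i] * scale if c[i] != 0 else 0.1
                assert algebraic_cost(c, e.semi_axes) >= base
                a = e.semi_axes.copy()
                a[i] *= scale
                assert algebraic_cost(e.center, a) >= base


class TestFootPoint:
    E = Ellipsoid(center=(0, 0, 0), semi_axes=(90, 70, 60))

    def test_on_principal_axis_outside(self):
        fp = foot_point([100, 0, 0], self.E)
        np.testing.assert_allclose(fp.foot_point, [90, 0, 0], atol=1e-8)
        assert fp.signed_distance == pytest.approx(10.0, abs=1e-8)
        assert fp.converged and not fp.ambiguous

    def test_sphere_closed_form(self):
        fp = foot_point([0, 0, 100], Ellipsoid((0, 0, 0), (60, 60, 60)))
        np.testing.assert_allclose(fp.foot_point, [0, 0, 60], atol=1e-8)
        assert fp.signed_distance == pytest.approx(40.0, abs=1e-8)

    def test_inside_point_negative_distance(self):
        fp = foot_point([0, 0, 30], Ellipsoid((0, 0, 0), (60, 60, 60)))
        assert fp.signed_distance == pytest.approx(-30.0, abs=1e-8)

    def test_center_is_ambiguous_but_deterministic(self):
        fp = foot_point([0, 0, 0], self.E)
        assert fp.ambiguous and fp.converged
        assert fp.signed_distance == pytest.approx(-60.0, abs=1e-9)  # shortest semi-axis

    def test_foot_point_satisfies_surface_equation_and_normal(self):
        rng = np.random.default_rng(6)
        for p in rng.uniform(-120, 120, (20, 3)):
            fp = foot_point(p, self.E)
            assert abs(self.E.implicit(fp.foot_point)[0]) < 1e-9
            assert np.linalg.norm(fp.normal) == pytest.approx(1.0, abs=1e-12)
            # connecting segment parallel to the surface normal
            seg = p - fp.foot_point
            if np.linalg.norm(seg) > 1e-9:
                cosang = abs(seg @ fp.normal) / np.linalg.norm(seg)
                assert cosang == pytest.approx(1.0, abs=1e-7)

    def test_points_on_surface_have_zero_distance(self):
        pts = ellipsoid_cloud(1000, (90, 70, 60), seed=7)
        d = signed_distances(pts, self.E)
        assert np.max(np.abs(d)) < 1e-8

    def test_outward_shift_increases_distance_by_shift(self):
        rng = np.random.default_rng(8)
        pts = ellipsoid_cloud(50, (90, 70, 60), seed=9) * 1.05
        for p in pts[:10]:
            fp = foot_point(p, self.E)
            delta = 3.7
            fp2 = foot_point(p + delta * fp.normal, self.E)
            assert fp2.signed_distance - fp.signed_distance == pytest.approx(delta, abs=1e-9)

    def test_brute_force_oracle_agreement(self):
        # oracle: nearest vertex of a 2-million-point parametric surface sampling
        dirs = fibonacci_cap(2_000_000, -90.0)
        surface = dirs * self.E.semi_axes
        tree = cKDTree(surface)
        rng = np.random.default_rng(10)
        u = rng.normal(size=(1000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # shell strictly off the surface: the nearest-vertex oracle is only
        # sharp when the true distance exceeds the sampling spacing
        factor = np.where(rng.random(1000) < 0.5, rng.uniform(0.85, 0.97, 1000),
                          rng.uniform(1.03, 1.15, 1000))
        shell = u * self.E.semi_axes * factor[:, None]
        oracle = tree.query(shell, workers=-1)[0]
        d = signed_distances(shell, self.E)
        np.testing.assert_allclose(np.abs(d), oracle, atol=0.05)
        # sign agrees with the implicit function
        assert np.all(np.sign(d) == np.sign(self.E.implicit(shell)))


class TestSurfaceSamples:
    E = Ellipsoid(center=(0, 0, 0), semi_axes=(90, 70, 60))

    def test_chart_quadrants(self):
        s = surface_samples(np.array([[100.0, 0, 0], [0, -80.0, 0], [0, 0, 75.0]]), self.E)
        assert s.lat[0] == pytest.approx(0, abs=1e-9)
        assert s.lon[0] == pytest.approx(0, abs=1e-9)
        assert s.distance[0] > 0
        assert s.lon[1] == pytest.approx(270.0, abs=1e-9)
        assert s.lat[2] == pytest.approx(90.0, abs=1e-6)

    def test_one_sample_per_point(self, healthy_head):
        model, truth = healthy_head
        s = surface_samples(model, truth.ellipsoid)
        assert len(s) == model.n_points
        assert np.all((s.lat >= -90) & (s.lat <= 90))
        assert np.all((s.lon >= 0) & (s.lon < 360))

    def test_estimator_transform_matches_function(self, healthy_head):
        model, _ = healthy_head
        fitter = EllipsoidFitter().fit(model.points)
        out = fitter.transform(model.points)
        s = surface_samples(model, fitter.ellipsoid_)
        np.testing.assert_allclose(out, np.column_stack([s.lat, s.lon, s.distance]))
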