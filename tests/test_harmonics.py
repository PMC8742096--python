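import numpy as np
import pytest

from cranioshape import SphericalHarmonicsRegression, basis_value, coefficient_vs_lmax, expand, expansion_rmse, reconstruct
from cranioshape.ellipsoid import SurfaceSamples
from cranioshape.errors import IllConditionedError, InsufficientDataError
from cranioshape.harmonics import degree_order_pairs, design_matrix
from cranioshape.synth import fibonacci_cap

from conftest import spread_chart


def _samples(lat, lon, d):
    return SurfaceSamples(lat=lat, lon=lon, distance=np.asarray(d, dtype=float))


class TestBasis:
    def test_y00_is_one_everywhere(self):
        lat, lon = spread_chart(50, seed=0)
        np.testing.assert_allclose(basis_value(0, 0, lat, lon), 1.0)

    def test_y2m2_quadrant_sign_pattern(self):
        signs = [np.sign(basis_value(2, -2, 0.0, lon)) for lon in (45, 135, 225, 315)]
        assert signs == [1, -1, 1, -1]

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            basis_value(2, 3, 0.0, 0.0)

    def test_orthonormality_under_quadrature(self):
        # Gauss-Legendre in z times uniform longitudes integrates products of
        # harmonics up to lmax=6 exactly: <Y_i Y_j> over the sphere = delta_ij
        # under the 4pi normalization.
        z, wz = np.polynomial.legendre.leggauss(32)
        lon = np.arange(64) * (360.0 / 64)
        Z, LON = np.meshgrid(z, lon, indexing="ij")
        W = np.repeat(wz[:, None], len(lon), axis=1) / (2.0 * len(lon))
        lat = np.degrees(np.arcsin(Z.ravel()))
        G = design_matrix(lat, LON.ravel(), 6)
        gram = (G * W.ravel()[:, None]).T @ G
        np.testing.assert_allclose(gram, np.eye(G.shape[1]), atol=1e-10)

    def test_zero_crossing_counts_of_sectoral_order(self):
        # Y_2^-2 varies as sin(2 lon): 4 longitudinal zero crossings
        lon = (np.arange(1000) + 0.5) * 0.36  # avoid grid points exactly on a zero
        vals = basis_value(2, -2, 0.0, lon)
        wrapped = np.r_[vals, vals[0]]
        crossings = np.sum(np.sign(wrapped[:-1]) * np.sign(wrapped[1:]) < 0)
        assert crossings == 4


class TestExpand:
    def test_constant_field_maps_to_degree_zero(self):
        lat, lon = spread_chart(500, seed=1)
        exp = expand(_samples(lat, lon, np.full(500, 2.0)), lmax=4)
        assert exp.coefficient(0, 0) == pytest.approx(2.0, abs=1e-9)
        others = [c for (l, m), c in zip(degree_order_pairs(4), exp.coefficients) if (l, m) != (0, 0)]
        assert np.max(np.abs(others)) < 1e-9

    def test_planted_basis_function_recovered(self):
        lat, lon = spread_chart(530, seed=2)
        d = 0.7 * basis_value(2, -2, lat, lon)
        exp = expand(_samples(lat, lon, d), lmax=4)
        assert exp.f22 == pytest.approx(0.7, abs=1e-9)
        assert exp.rmse < 1e-9
        # reconstruct interpolates the training sites of a representable field
        np.testing.assert_allclose(reconstruct(exp, lat, lon), d, atol=1e-8)

    def test_underdetermined_system_rejected(self):
        lat, lon = spread_chart(20, seed=3)
        with pytest.raises(InsufficientDataError):
            expand(_samples(lat, lon, np.zeros(20)), lmax=4)

    def test_clustered_samples_are_ill_conditioned(self):
        lat = np.full(100, 10.0) + np.random.default_rng(4).normal(0, 1e-6, 100)
        lon = np.full(100, 20.0)
        with pytest.raises(IllConditionedError):
            expand(_samples(lat, lon, np.zeros(100)), lmax=4)

    def test_linearity_of_coefficients(self):
        lat, lon = spread_chart(300, seed=5)
        rng = np.random.default_rng(6)
        d1, d2 = rng.normal(size=(2, 300))
        c = lambda d: expand(_samples(lat, lon, d), lmax=3).coefficients
        np.testing.assert_allclose(c(2.0 * d1 - 0.5 * d2), 2.0 * c(d1) - 0.5 * c(d2), atol=1e-9)

    def test_mirror_antisymmetry(self):
        lat, lon = spread_chart(400, seed=7)
        d = np.random.default_rng(8).normal(0, 1, 400)
        a = expand(_samples(lat, lon, d), lmax=4)
        b = expand(_samples(lat, (360.0 - lon) % 360.0, d), lmax=4)
        for l, m in degree_order_pairs(4):
            sign = -1.0 if m < 0 else 1.0
            assert b.coefficient(l, m) == pytest.approx(sign * a.coefficient(l, m), abs=1e-9)
        assert b.f22 == pytest.approx(-a.f22, abs=1e-9)

    def test_fitted_rmse_does_not_exceed_noise(self):
        lat, lon = spread_chart(530, seed=9)
        sigma = 0.3
        noise = np.random.default_rng(10).normal(0, sigma, 530)
        d = 0.5 * basis_value(2, -2, lat, lon) + noise
        exp = expand(_samples(lat, lon, d), lmax=4)
        assert exp.rmse <= sigma * 1.15

    def test_rmse_invariant_under_sample_permutation(self):
        lat, lon = spread_chart(200, seed=11)
        d = np.random.default_rng(12).normal(size=200)
        exp = expand(_samples(lat, lon, d), lmax=3)
        perm = np.random.default_rng(13).permutation(200)
        assert expansion_rmse(exp, _samples(lat[perm], lon[perm], d[perm])) == pytest.approx(exp.rmse)


class TestSweep:
    def test_planted_field_stable_across_lmax(self):
        lat, lon = spread_chart(530, seed=14)
        d = 0.7 * basis_value(2, -2, lat, lon)
        sweep = coefficient_vs_lmax(_samples(lat, lon, d), lmax_list=range(2, 11))
        for lm, (coef, _) in sweep.items():
            assert coef == pytest.approx(0.7, abs=1e-8), f"lmax={lm}"

    def test_training_rmse_non_increasing_in_lmax(self):
        lat, lon = spread_chart(530, seed=15)
        d = np.random.default_rng(16).normal(0, 1, 530)
        sweep = coefficient_vs_lmax(_samples(lat, lon, d), lmax_list=range(2, 11))
        rmses = [sweep[lm][1] for lm in range(2, 11)]
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))


class TestRecovery:
    @pytest.mark.parametrize("amplitude", [0.1, 0.5, 1.0])
    def test_planted_coefficient_bias_and_spread_under_noise(self, amplitude):
        # cap-distributed sites, iid 0.3 mm noise, 200 replicates
        dirs = fibonacci_cap(530, -25.0)
        lat = np.degrees(np.arcsin(dirs[:, 2]))
        lon = np.degrees(np.arctan2(dirs[:, 1], dirs[:, 0])) % 360.0
        signal = amplitude * basis_value(2, -2, lat, lon)
        rng = np.random.default_rng(17)
        est = [
            expand(_samples(lat, lon, signal + rng.normal(0, 0.3, 530)), lmax=4).f22
            for _ in range(200)
        ]
        assert abs(np.mean(est) - amplitude) < 0.05
        assert np.std(est) < 0.1


class TestEstimatorInterface:
    def test_regressor_fit_predict_round_trip(self):
        lat, lon = spread_chart(300, seed=18)
        X = np.column_stack([lat, lon])
        y = 1.3 * basis_value(3, 2, lat, lon) - 0.4
        reg = SphericalHarmonicsRegression(lmax=3).fit(X, y)
        np.testing.assert_allclose(reg.predict(X), y, atol=1e-8)
        assert reg.score(X, y) == pytest.approx(1.0, abs=1e-9)

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        reg = SphericalHarmonicsRegression(lmax=5, ridge=0.1)
        assert clone(reg).get_params() == {"lmax": 5, "ridge": 0.1}
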