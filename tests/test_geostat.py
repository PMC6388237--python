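"""Geostatistics: semivariogram estimation, model fitting, ordinary kriging."""

import numpy as np
import pytest

from wqimap import (
    EmpiricalVariogram,
    GridSpec,
    SpatialSample,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    krige_grid,
    ordinary_krige,
    project_coordinates,
    samples_from_grf,
    variogram_value,
)
from wqimap.errors import InsufficientDataError, NearSingularSystemError
from wqimap.geostat import kriging_weights

from conftest import brute_force_krige, covariance_form_krige


class TestVariogramValue:
    @pytest.mark.parametrize("family", ["spherical", "exponential", "gaussian"])
    def test_zero_at_origin(self, family):
        m = VariogramModel(family, nugget=0.5, partial_sill=2.0, range_param=1.0)
        assert variogram_value(m, 0.0) == 0.0

    def test_spherical_reaches_sill_at_range(self):
        m = VariogramModel("spherical", nugget=0.0, partial_sill=2.0, range_param=1.0)
        assert variogram_value(m, 1.0) == pytest.approx(2.0)
        assert variogram_value(m, 5.0) == pytest.approx(2.0)

    def test_pure_nugget(self):
        m = VariogramModel("exponential", nugget=0.5, partial_sill=0.0,
                           range_param=1.0)
        for h in (1e-9, 0.5, 100.0):
            assert variogram_value(m, h) == pytest.approx(0.5)

    @pytest.mark.parametrize("family", ["exponential", "gaussian"])
    def test_effective_range_convention(self, family):
        """~95% of the sill is reached at the effective range."""
        m = VariogramModel(family, nugget=0.0, partial_sill=1.0, range_param=2.0)
        assert variogram_value(m, 2.0) == pytest.approx(1.0 - np.exp(-3.0))

    @pytest.mark.parametrize("family", ["spherical", "exponential", "gaussian"])
    def test_nondecreasing(self, family):
        m = VariogramModel(family, nugget=0.1, partial_sill=1.0, range_param=0.7)
        h = np.linspace(1e-6, 3.0, 200)
        g = variogram_value(m, h)
        assert np.all(np.diff(g) >= -1e-12)

    def test_negative_lag_rejected(self):
        m = VariogramModel()
        with pytest.raises(ValueError):
            variogram_value(m, -0.1)


class TestEmpiricalVariogram:
    def test_constant_field_is_zero(self):
        rng = np.random.default_rng(0)
        s = [SpatialSample(x, y, 5.0) for x, y in rng.random((30, 2))]
        emp = empirical_variogram(s)
        assert np.all(emp.gamma_hat == 0.0)

    def test_two_samples_single_bin(self):
        s = [SpatialSample(0, 0, 0.0), SpatialSample(1, 0, 2.0)]
        emp = empirical_variogram(s, n_bins=1, max_lag=2.0)
        # gamma = (1 / (2*1)) * (2-0)^2 = 2
        assert emp.gamma_hat.tolist() == [2.0]
        assert emp.pair_counts.tolist() == [1]

    def test_iid_noise_sill_near_variance(self):
        """Pure-nugget process: semivariance ~ process variance at all lags."""
        rng = np.random.default_rng(42)
        pts = rng.random((500, 2))
        s = [SpatialSample(x, y, v) for (x, y), v in zip(pts, rng.standard_normal(500))]
        emp = empirical_variogram(s, n_bins=10)
        assert np.all(np.abs(emp.gamma_hat - 1.0) < 0.25)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            empirical_variogram([SpatialSample(0, 0, 1.0)])

    def test_bins_with_no_pairs_dropped(self):
        s = [SpatialSample(0, 0, 1.0), SpatialSample(0.01, 0, 2.0),
             SpatialSample(5, 5, 0.0)]
        emp = empirical_variogram(s, n_bins=20, max_lag=8.0)
        assert np.all(emp.pair_counts > 0)


class TestFitVariogram:
    def test_exact_curve_recovered(self):
        true = VariogramModel("spherical", nugget=0.3, partial_sill=1.7,
                              range_param=0.8)
        h = np.linspace(0.05, 1.5, 12)
        emp = EmpiricalVariogram(h, variogram_value(true, h), np.full(12, 50))
        fit = fit_variogram(emp, "spherical")
        assert fit.nugget == pytest.approx(true.nugget, abs=1e-6)
        assert fit.partial_sill == pytest.approx(true.partial_sill, abs=1e-6)
        assert fit.range_param == pytest.approx(true.range_param, abs=1e-6)

    def test_flat_target_becomes_pure_nugget(self):
        """All semivariances equal c: WLS puts everything in the nugget.
        Cross-checked by a brute-force grid search over (nugget, psill)."""
        c = 0.7
        h = np.linspace(0.1, 1.0, 8)
        emp = EmpiricalVariogram(h, np.full(8, c), np.full(8, 30))
        fit = fit_variogram(emp, "spherical")
        assert fit.nugget == pytest.approx(c, abs=1e-3)
        assert fit.partial_sill == pytest.approx(0.0, abs=1e-3)
        # brute force: best (nugget, psill, range) on a coarse grid can't
        # beat the optimizer's weighted SSE by more than numerical slack
        w = np.sqrt(emp.pair_counts / h**2)

        def sse(model):
            return float(np.sum((w * (variogram_value(model, h) - c)) ** 2))

        best_grid = min(
            sse(VariogramModel("spherical", n, p, r))
            for n in np.linspace(0, 1.4, 15)
            for p in np.linspace(0, 1.4, 15)
            for r in np.linspace(0.05, 2.0, 10)
        )
        assert sse(fit) <= best_grid + 1e-9

    def test_all_zero_semivariance_warns(self):
        h = np.linspace(0.1, 1.0, 5)
        emp = EmpiricalVariogram(h, np.zeros(5), np.full(5, 10))
        with pytest.warns(UserWarning):
            fit = fit_variogram(emp)
        assert fit.nugget == 0.0 and fit.partial_sill == 0.0

    def test_too_few_bins(self):
        emp = EmpiricalVariogram([0.1, 0.2], [0.5, 0.6], [5, 5])
        with pytest.raises(InsufficientDataError):
            fit_variogram(emp)

    def test_grf_parameter_recovery_median(self):
        """Round trip: simulate from a known model, fit, recover within 25%
        relative error in the median over seeds (small-n smoke version)."""
        true = VariogramModel("spherical", nugget=0.25, partial_sill=0.75,
                              range_param=0.3)
        errs = []
        for seed in range(5):
            s = samples_from_grf(400, true, seed=seed)
            fit = fit_variogram(empirical_variogram(s))
            errs.append(abs(fit.sill - true.sill) / true.sill)
        assert float(np.median(errs)) < 0.25


class TestOrdinaryKrige:
    def test_exactness_at_sample_locations(self, square_samples, spherical_model):
        preds = ordinary_krige(
            square_samples, spherical_model,
            [(s.x, s.y) for s in square_samples],
        )
        for p, s in zip(preds, square_samples):
            assert p.predicted == pytest.approx(s.value, abs=1e-8)
            assert p.kriging_variance == pytest.approx(0.0, abs=1e-8)

    def test_pure_nugget_predicts_mean(self):
        """Hand-solved: with a pure-nugget variogram all weights are 1/n,
        so every prediction is the arithmetic mean."""
        s = [SpatialSample(0, 0, 1.0), SpatialSample(1, 0, 2.0),
             SpatialSample(0, 1, 6.0)]
        m = VariogramModel("exponential", nugget=0.8, partial_sill=0.0,
                           range_param=1.0)
        p = ordinary_krige(s, m, [(0.3, 0.4)])[0]
        assert p.predicted == pytest.approx(3.0, abs=1e-10)
        w, _ = kriging_weights(s, m, (0.3, 0.4))
        assert np.allclose(w, 1.0 / 3.0, atol=1e-10)

    def test_weights_sum_to_one(self, square_samples, spherical_model):
        rng = np.random.default_rng(7)
        for t in rng.random((10, 2)) * 2 - 0.5:
            w, _ = kriging_weights(square_samples, spherical_model, tuple(t))
            assert np.sum(w) == pytest.approx(1.0, abs=1e-10)

    def test_brute_force_oracle_small_systems(self):
        """<= 10-point systems match an independent naive-loop solve."""
        rng = np.random.default_rng(3)
        for n in (3, 5, 10):
            s = [SpatialSample(x, y, v)
                 for (x, y), v in zip(rng.random((n, 2)),
                                      rng.normal(10, 2, n))]
            m = VariogramModel("exponential", nugget=0.1, partial_sill=1.5,
                               range_param=0.6)
            targets = rng.random((4, 2))
            preds = ordinary_krige(s, m, targets)
            for p, t in zip(preds, targets):
                ref_pred, ref_var = brute_force_krige(s, m, t)
                assert p.predicted == pytest.approx(ref_pred, abs=1e-10)
                assert p.kriging_variance == pytest.approx(ref_var, abs=1e-10)

    def test_value_shift_equivariance(self, square_samples, spherical_model):
        shifted = [SpatialSample(s.x, s.y, s.value + 11.5) for s in square_samples]
        t = [(0.25, 0.7)]
        p0 = ordinary_krige(square_samples, spherical_model, t)[0]
        p1 = ordinary_krige(shifted, spherical_model, t)[0]
        assert p1.predicted == pytest.approx(p0.predicted + 11.5, abs=1e-9)
        assert p1.kriging_variance == pytest.approx(p0.kriging_variance, abs=1e-9)

    def test_rigid_motion_invariance(self, square_samples, spherical_model):
        """Rotating + translating all coordinates leaves predictions unchanged
        (isotropic variogram depends only on distances)."""
        theta = 0.7
        c, s_ = np.cos(theta), np.sin(theta)

        def move(x, y):
            return (c * x - s_ * y + 3.0, s_ * x + c * y - 1.0)

        moved = [SpatialSample(*move(s.x, s.y), s.value) for s in square_samples]
        t0 = (0.3, 0.6)
        p0 = ordinary_krige(square_samples, spherical_model, [t0])[0]
        p1 = ordinary_krige(moved, spherical_model, [move(*t0)])[0]
        assert p1.predicted == pytest.approx(p0.predicted, abs=1e-9)
        assert p1.kriging_variance == pytest.approx(p0.kriging_variance, abs=1e-9)

    def test_nugget_smooths_toward_mean(self):
        """With a nugget the predictor is discontinuous at data points:
        just off a sample location the prediction is pulled from the
        sample value toward the local mean."""
        s = [SpatialSample(0, 0, 0.0), SpatialSample(1, 0, 0.0),
             SpatialSample(0.5, 0.5, 10.0), SpatialSample(0, 1, 0.0),
             SpatialSample(1, 1, 0.0)]
        exact = VariogramModel("spherical", nugget=0.0, partial_sill=1.0,
                               range_param=1.0)
        noisy = VariogramModel("spherical", nugget=0.5, partial_sill=0.5,
                               range_param=1.0)
        target = (0.5 + 1e-9, 0.5)
        p_exact = ordinary_krige(s, exact, [target])[0].predicted
        p_noisy = ordinary_krige(s, noisy, [target])[0].predicted
        assert p_exact == pytest.approx(10.0, abs=1e-6)
        assert p_noisy < p_exact - 1.0

    def test_duplicate_locations_raise(self):
        s = [SpatialSample(0, 0, 1.0), SpatialSample(0, 0, 2.0),
             SpatialSample(1, 1, 3.0)]
        m = VariogramModel("spherical", nugget=0.0, partial_sill=1.0,
                           range_param=1.0)
        with pytest.raises(NearSingularSystemError, match="duplicate"):
            ordinary_krige(s, m, [(0.5, 0.5)])

    def test_empty_targets(self, square_samples, spherical_model):
        assert ordinary_krige(square_samples, spherical_model, []) == []


class TestKrigeGrid:
    def test_grid_reproduces_samples_at_cell_centers(self):
        # 2x2 grid over (0,2)x(0,2): centers (0.5,0.5)...(1.5,1.5)
        s = [SpatialSample(0.5, 0.5, 1.0), SpatialSample(1.5, 0.5, 2.0),
             SpatialSample(0.5, 1.5, 3.0), SpatialSample(1.5, 1.5, 4.0)]
        m = VariogramModel("spherical", nugget=0.0, partial_sill=1.0,
                           range_param=2.0)
        g = krige_grid(s, m, GridSpec(0, 2, 0, 2, 2, 2))
        assert g.predicted == pytest.approx(np.array([[1.0, 2.0], [3.0, 4.0]]),
                                            abs=1e-8)

    def test_constant_field_constant_grid(self):
        rng = np.random.default_rng(5)
        s = [SpatialSample(x, y, 7.0) for x, y in rng.random((12, 2))]
        m = VariogramModel("exponential", nugget=0.2, partial_sill=0.5,
                           range_param=0.5)
        g = krige_grid(s, m, GridSpec(0, 1, 0, 1, 5, 5))
        assert np.allclose(g.predicted, 7.0, atol=1e-9)

    def test_matches_covariance_form_oracle_on_grid(self):
        """20x20 grid from 50 GRF samples: semivariance-form implementation
        vs an independent covariance-form solve, to 1e-6."""
        true = VariogramModel("spherical", nugget=0.1, partial_sill=1.0,
                              range_param=0.4)
        s = samples_from_grf(50, true, mean=8.0, seed=21)
        grid = GridSpec(0, 1, 0, 1, 20, 20)
        g = krige_grid(s, true, grid)
        ref_pred, ref_var = covariance_form_krige(s, true, grid.targets())
        assert np.allclose(g.predicted.ravel(), ref_pred, atol=1e-6)
        assert np.allclose(g.variance.ravel(), ref_var, atol=1e-6)


class TestProjection:
    def test_raw_degrees_identity(self):
        lon, lat = np.array([117.0, 118.0]), np.array([36.0, 37.0])
        x, y = project_coordinates(lon, lat, project=False)
        assert np.array_equal(x, lon) and np.array_equal(y, lat)

    def test_equirectangular_scale(self):
        # one degree of latitude ~ 111 km everywhere
        lon, lat = np.array([117.0, 117.0]), np.array([36.0, 37.0])
        x, y = project_coordinates(lon, lat)
        assert abs(y[1] - y[0]) == pytest.approx(111.2, abs=1.0)
        # a degree of longitude is compressed by cos(latitude)
        lon2, lat2 = np.array([117.0, 118.0]), np.array([36.5, 36.5])
        x2, _ = project_coordinates(lon2, lat2)
        assert abs(x2[1] - x2[0]) == pytest.approx(111.2 * np.cos(np.radians(36.5)),
                                                   abs=1.0)
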