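"""Isotope standardization, kriging oracle, and isoscape fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from otogeo.isotopes import (NBS19_D13C_VPDB, NBS19_D18O_VPDB, delta_vpdb,
                             smow_to_vpdb, vpdb_to_smow)
from otogeo.isoscape import (ExponentialKriging, IsoscapeModel, fit_isoscape,
                             interpolate_env)
from otogeo.types import DepthStratum, haversine_km


class TestStandardization:
    def test_sample_equal_to_standard_returns_nominal_values(self):
        R = 0.0112372
        assert delta_vpdb(R, R, NBS19_D13C_VPDB) == pytest.approx(1.95, abs=1e-12)
        assert delta_vpdb(R, R, NBS19_D18O_VPDB) == pytest.approx(-2.20, abs=1e-12)

    def test_zero_nominal_and_equal_ratios_give_zero(self):
        assert delta_vpdb(1.0, 1.0, 0.0) == 0.0

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            delta_vpdb(-1.0, 1.0, 0.0)

    def test_smow_zero_maps_to_printed_intercept(self):
        assert smow_to_vpdb(0.0) == pytest.approx(-29.94)

    def test_smow_root_of_affine_map(self):
        assert smow_to_vpdb(29.94 / 0.97006) == pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(-50, 50), b=st.floats(-50, 50))
    def test_affine_identity(self, a, b):
        f = smow_to_vpdb
        assert f(a) + f(b) - f(0.0) == pytest.approx(f(a + b), abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(x=st.floats(-60, 60))
    def test_scale_conversion_round_trips(self, x):
        assert vpdb_to_smow(smow_to_vpdb(x)) == pytest.approx(x, abs=1e-9)


class TestKrigingOracle:
    def test_three_point_closed_form_gp_posterior(self):
        # hand-specified exponential covariance, zero-mean simple kriging
        X = np.array([[-44.0, -60.0], [-43.0, -60.5], [-42.0, -59.5]])
        y = np.array([0.3, -0.1, 0.2])
        sill, rng_km, nugget = 0.5, 150.0, 0.05
        krig = ExponentialKriging(range_km=rng_km, sill=sill, nugget=nugget,
                                  mean="zero").fit(X, y)
        Xs = np.array([[-43.5, -60.2], [-41.0, -59.0]])

        def cov(A, B, diag_nugget):
            H = haversine_km(A[:, 0][:, None], A[:, 1][:, None],
                             B[:, 0][None, :], B[:, 1][None, :])
            K = sill * np.exp(-H / rng_km)
            if diag_nugget:
                K = K + nugget * np.eye(len(A))
            return K

        K = cov(X, X, True)
        ks = cov(Xs, X, False)
        mean_ref = ks @ np.linalg.solve(K, y)
        var_ref = sill + nugget - np.sum(ks * np.linalg.solve(K, ks.T).T, axis=1)
        mean, sd = krig.predict(Xs, return_std=True)
        assert np.allclose(mean, mean_ref, atol=1e-8)
        assert np.allclose(sd, np.sqrt(var_ref), atol=1e-8)

    def test_exact_interpolation_without_nugget(self, rng):
        X = rng.uniform([-48, -64], [-36, -58], size=(25, 2))
        y = rng.normal(size=25)
        krig = ExponentialKriging(range_km=200.0, sill=1.0, nugget=0.0,
                                  mean="zero").fit(X, y)
        assert np.allclose(krig.predict(X), y, atol=1e-6)

    def test_variance_at_least_nugget_and_grows_with_distance(self, rng):
        X = rng.uniform([-48, -64], [-40, -58], size=(30, 2))
        y = rng.normal(size=30)
        krig = ExponentialKriging(range_km=100.0, sill=1.0, nugget=0.1,
                                  mean="zero").fit(X, y)
        # walk east into an empty region
        ray = np.column_stack([np.linspace(-39.5, -20.0, 12), np.full(12, -61.0)])
        _, sd = krig.predict(ray, return_std=True)
        assert np.all(sd**2 >= 0.1 - 1e-9)
        assert np.all(np.diff(sd) >= -1e-9)

    def test_ml_recovers_plausible_parameters(self, rng):
        # draw from a known GP and check the ML estimates are in range
        X = rng.uniform([-48, -64], [-36, -58], size=(120, 2))
        H = haversine_km(X[:, 0][:, None], X[:, 1][:, None],
                         X[:, 0][None, :], X[:, 1][None, :])
        K = 1.0 * np.exp(-H / 100.0) + 0.2 * np.eye(120)
        y = np.linalg.cholesky(K) @ rng.standard_normal(120)
        krig = ExponentialKriging(mean="zero", random_state=0).fit(X, y)
        assert 30.0 < krig.range_km_ < 400.0
        assert 0.2 < krig.sill_ < 4.0
        assert 0.02 < krig.nugget_ < 1.0


class TestInterpolateEnv:
    STRATA = [DepthStratum(0, 50), DepthStratum(50, 100)]

    def test_recovers_plane_exactly(self, rng):
        lon = np.arange(-47.5, -36, 1.0)
        lat = np.arange(-63.5, -58, 1.0)
        obs = pd.DataFrame({
            "lon": rng.uniform(-48, -36, 80),
            "lat": rng.uniform(-64, -58, 80),
            "depth": rng.uniform(0, 50, 80),
        })
        obs["temperature"] = 2.0 + 0.3 * obs.lon + 0.1 * obs.lat
        field = interpolate_env(obs, "temperature", lon, lat, [self.STRATA[0]])
        LON, LAT = np.meshgrid(lon, lat)
        assert np.allclose(field.values[0], 2.0 + 0.3 * LON + 0.1 * LAT, atol=1e-6)

    def test_single_observation_gives_constant_field(self):
        obs = pd.DataFrame({"lon": [-44.0], "lat": [-60.0], "depth": [10.0],
                            "temperature": [1.5]})
        with pytest.warns(UserWarning, match="single observation"):
            field = interpolate_env(obs, "temperature", np.array([-44.0, -43.0]),
                                    np.array([-60.0]), [self.STRATA[0]])
        assert np.all(field.values[0] == 1.5)

    def test_empty_stratum_flagged_missing(self, rng):
        obs = pd.DataFrame({"lon": rng.uniform(-48, -36, 30),
                            "lat": rng.uniform(-64, -58, 30),
                            "depth": rng.uniform(0, 50, 30)})
        obs["temperature"] = 1.0
        with pytest.warns(UserWarning, match="no observations"):
            field = interpolate_env(obs, "temperature", np.array([-44.0]),
                                    np.array([-60.0]), self.STRATA)
        assert np.all(np.isnan(field.values[1]))

    def test_loo_rmse_below_noise_ceiling(self, rng):
        noise_sd = 0.2
        obs = pd.DataFrame({"lon": rng.uniform(-48, -36, 120),
                            "lat": rng.uniform(-64, -58, 120),
                            "depth": rng.uniform(0, 50, 120)})
        obs["temperature"] = (np.sin(obs.lon / 3.0) + 0.2 * obs.lat
                              + rng.normal(0, noise_sd, 120))
        field = interpolate_env(obs, "temperature", np.array([-44.0]),
                                np.array([-60.0]), [self.STRATA[0]],
                                bandwidth_km=150.0)
        assert field.loo_rmse[0] < 1.5 * noise_sd


class TestIsoscapeModel:
    def test_fit_and_grid_prediction(self, small_sim):
        env = small_sim.environment
        iso = fit_isoscape(env.water_obs, env.temperature, env.salinity)
        assert 0.3 < iso.deviance_explained < 0.95
        assert np.all(np.isfinite(iso.mean))
        assert np.all(iso.sd >= 0)
        # predicted field should correlate with the realized truth
        r = np.corrcoef(iso.mean.ravel(), env.water_true.values.ravel())[0, 1]
        assert r > 0.8

    def test_smow_flagged_rows_converted_on_entry(self, small_sim):
        env = small_sim.environment
        obs_v = env.water_obs
        obs_s = obs_v.copy()
        obs_s["d18o_water"] = vpdb_to_smow(obs_v["d18o_water"])
        obs_s["scale"] = "SMOW"
        iso_v = fit_isoscape(obs_v, env.temperature, env.salinity)
        iso_s = fit_isoscape(obs_s, env.temperature, env.salinity)
        assert np.allclose(iso_v.mean, iso_s.mean, atol=1e-6)

    def test_too_few_observations_rejected(self, small_sim):
        env = small_sim.environment
        with pytest.raises(ValueError, match=">= 30"):
            IsoscapeModel().fit(env.water_obs.head(10))

    def test_year_window_filters_observations(self, small_sim):
        env = small_sim.environment
        model = IsoscapeModel(year_window=(1989, 1995))
        model.fit(env.water_obs)
        assert model.obs_["year"].between(1989, 1995).all()
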