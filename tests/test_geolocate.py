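"""Fractionation predictions, occurrence probabilities and map arithmetic."""

import numpy as np
import pytest
from scipy.stats import norm

from otogeo.geolocate import (area_summary, bias_test, capture_site_expectation,
                              expected_distribution, expected_distribution_grid,
                              occurrence_probability, synoptic_map,
                              top_percentile_region)
from otogeo.isoscape import Isoscape
from otogeo.isotopes import THORROLD, FractionationEquation, predict_oto
from otogeo.types import AreaPolygon, DepthStratum, EnvField, FishRecord


def _iso(values, sd=0.0, lon=None, lat=None, strata=None):
    values = np.asarray(values, dtype=float)
    n_s, n_la, n_lo = values.shape
    lon = np.arange(n_lo, dtype=float) if lon is None else np.asarray(lon, float)
    lat = np.arange(n_la, dtype=float) - 60.0 if lat is None else np.asarray(lat, float)
    strata = strata or [DepthStratum(100.0 * k, 100.0 * (k + 1)) for k in range(n_s)]
    return Isoscape(lon, lat, strata, values, np.full_like(values, float(sd)))


def _temp(iso, value=0.0, sd=0.0):
    vals = np.full_like(iso.mean, float(value))
    return EnvField("temperature", iso.lon, iso.lat, iso.strata, vals,
                    variance=np.full_like(vals, float(sd) ** 2))


class TestPredictOto:
    def test_printed_equation_constants(self):
        assert predict_oto(THORROLD, 0.0, 0.0) == pytest.approx(4.64)
        assert predict_oto(THORROLD, 10.0, 0.0) == pytest.approx(2.54)

    def test_unit_water_coefficient(self):
        base = predict_oto(THORROLD, 5.0, 0.0)
        assert predict_oto(THORROLD, 5.0, 1.0) == pytest.approx(base + 1.0)


class TestCaptureSite:
    def test_uniform_field_returns_constant(self):
        iso = _iso(np.full((2, 4, 4), -0.4))
        t, w = capture_site_expectation(iso, _temp(iso, 1.5), 1.0, -59.0, 100.0)
        assert (t, w) == (1.5, pytest.approx(-0.4))

    def test_tiny_radius_uses_nearest_cell(self):
        vals = np.arange(16, dtype=float).reshape(1, 4, 4)
        iso = _iso(vals, strata=[DepthStratum(0, 200)])
        t, w = capture_site_expectation(iso, _temp(iso), float(iso.lon[2]),
                                        float(iso.lat[1]), 100.0, radius_km=1.0)
        assert w == vals[0, 1, 2]

    def test_hand_built_three_cell_mean(self):
        # 1x3 grid: all three centres fall inside a generous radius
        vals = np.array([[[1.0, 2.0, 3.0]]])
        iso = _iso(vals, lon=np.array([-44.0, -43.5, -43.0]), lat=np.array([-60.0]),
                   strata=[DepthStratum(0, 200)])
        _, w = capture_site_expectation(iso, _temp(iso), -43.5, -60.0, 100.0,
                                        radius_km=100.0)
        assert w == pytest.approx(2.0)

    def test_no_overlapping_stratum_raises(self):
        iso = _iso(np.zeros((1, 2, 2)), strata=[DepthStratum(0, 100)])
        with pytest.raises(ValueError, match="strata"):
            capture_site_expectation(iso, _temp(iso), 0.5, -59.5, 900.0)


def _fish(fid, lon, lat):
    import datetime as dt

    return FishRecord(fish_id=fid, total_length=140.0, capture_date=dt.date(2018, 2, 1),
                      capture_lon=lon, capture_lat=lat, capture_event_id="E1")


class TestBiasTest:
    def _setup(self, rng):
        iso = _iso(rng.normal(-0.5, 0.1, size=(2, 5, 5)),
                   lon=np.linspace(-45, -41, 5), lat=np.linspace(-62, -58, 5))
        temp = _temp(iso, 1.0)
        fish = [_fish(f"f{i}", -43.0 + 0.2 * i, -60.0) for i in range(6)]
        edges = {}
        for f in fish:
            t, w = capture_site_expectation(iso, temp, f.capture_lon, f.capture_lat, 100.0)
            edges[f.fish_id] = predict_oto(THORROLD, t, w)
        return iso, temp, fish, edges

    def test_generating_equation_has_zero_bias(self, rng):
        iso, temp, fish, edges = self._setup(rng)
        report = bias_test([THORROLD], edges, fish, iso, temp)
        assert report.rows.loc[0, "mean_bias"] == pytest.approx(0.0, abs=1e-9)

    def test_intercept_shift_propagates_exactly(self, rng):
        iso, temp, fish, edges = self._setup(rng)
        shifted = FractionationEquation("shifted", THORROLD.intercept + 0.5,
                                        THORROLD.temp_slope)
        report = bias_test([THORROLD, shifted], edges, fish, iso, temp)
        rows = report.rows.set_index("equation")
        assert rows.loc["shifted", "mean_bias"] == pytest.approx(
            rows.loc["thorrold", "mean_bias"] - 0.5, abs=1e-9)

    def test_ranking_orders_by_absolute_bias(self, rng):
        iso, temp, fish, edges = self._setup(rng)
        worse = FractionationEquation("worse", THORROLD.intercept - 1.5, THORROLD.temp_slope)
        report = bias_test([worse, THORROLD], edges, fish, iso, temp)
        assert report.ranked()["equation"].tolist() == ["thorrold", "worse"]

    def test_too_few_fish_rejected(self, rng):
        iso, temp, fish, edges = self._setup(rng)
        with pytest.raises(ValueError, match=">= 5"):
            bias_test([THORROLD], edges, fish[:3], iso, temp)


class TestExpectedDistribution:
    def test_degenerate_sds_give_constant_draws(self):
        iso = _iso(np.full((1, 2, 2), -0.5), sd=0.0)
        eq = FractionationEquation("det", 4.64, -0.21, residual_sd=0.0)
        dist = expected_distribution(iso, eq, _temp(iso, 2.0), (0, 0), 0,
                                     n_mc=500, seed=0)
        assert np.all(dist.mc_samples == predict_oto(eq, 2.0, -0.5))

    def test_water_sd_propagates_to_draw_spread(self):
        iso = _iso(np.full((1, 2, 2), -0.5), sd=0.3)
        eq = FractionationEquation("det", 4.64, -0.21, residual_sd=0.0)
        dist = expected_distribution(iso, eq, _temp(iso, 2.0), (0, 0), 0,
                                     n_mc=20000, seed=1)
        assert dist.sd == pytest.approx(0.3, rel=0.05)

    def test_same_seed_identical_draws(self):
        iso = _iso(np.full((1, 2, 2), -0.5), sd=0.2)
        a = expected_distribution(iso, THORROLD, _temp(iso, 1.0, sd=0.3), (0, 1), 0,
                                  n_mc=1000, seed=3)
        b = expected_distribution(iso, THORROLD, _temp(iso, 1.0, sd=0.3), (0, 1), 0,
                                  n_mc=1000, seed=3)
        assert np.array_equal(a.mc_samples, b.mc_samples)

    def test_grid_draws_match_configured_count(self):
        iso = _iso(np.zeros((2, 3, 4)), sd=0.1)
        draws = expected_distribution_grid(iso, THORROLD, _temp(iso, 1.0), n_mc=256, seed=0)
        assert draws.shape == (2, 3, 4, 256)
        assert np.all(np.isfinite(draws))


class TestOccurrenceProbability:
    def test_median_observation_scores_one(self):
        draws = np.linspace(0, 1, 1001)
        assert occurrence_probability(0.5, draws) == pytest.approx(1.0, abs=2e-3)

    def test_far_outside_scores_zero(self):
        draws = np.random.default_rng(0).normal(4.0, 0.3, 2000)
        assert occurrence_probability(50.0, draws) == 0.0

    def test_matches_analytic_normal_tail(self):
        draws = np.random.default_rng(1).normal(4.0, 0.3, 200000)
        p = occurrence_probability(4.3, draws)
        assert p == pytest.approx(2 * (1 - norm.cdf(1.0)), abs=0.01)

    def test_invariant_to_monotone_relabelling(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=5000)
        x = 0.7
        p1 = occurrence_probability(x, draws)
        p2 = occurrence_probability(np.exp(x), np.exp(draws))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_few_draws_warn(self):
        with pytest.warns(UserWarning, match="1000 draws"):
            occurrence_probability(0.0, np.random.default_rng(0).normal(size=100))


class TestSynopticAndAreas:
    def _map_from(self, per_fish, n_lo=4, n_la=1, n_s=2):
        iso = _iso(np.zeros((n_s, n_la, n_lo)))
        return synoptic_map(per_fish, iso, n_mc=1000)

    def test_single_fish_map_is_identity(self):
        p = np.random.default_rng(0).uniform(size=(2, 1, 4))
        omap = self._map_from({"f1": p})
        assert np.allclose(omap.mean_by_stratum, p)
        assert np.allclose(omap.mean_across, p.mean(axis=0))

    def test_two_fish_mean_and_loglik(self):
        a = np.full((1, 1, 1), 0.2)
        b = np.full((1, 1, 1), 0.4)
        omap = self._map_from({"f1": a, "f2": b}, n_lo=1, n_s=1)
        assert omap.mean_across[0, 0] == pytest.approx(0.3)
        assert omap.loglik[0, 0] == pytest.approx(np.log(0.2) + np.log(0.4))

    def test_uniform_maps_give_constant_output(self):
        p = np.full((2, 1, 4), 0.37)
        omap = self._map_from({"f1": p, "f2": p})
        assert np.ptp(omap.mean_across) == 0.0
        assert np.ptp(omap.loglik) == 0.0

    def test_zero_probability_floored_at_mc_resolution(self):
        p = np.zeros((1, 1, 1))
        omap = self._map_from({"f1": p}, n_lo=1, n_s=1)
        assert omap.loglik[0, 0] == pytest.approx(np.log(1 / 2000))

    def test_area_summary_whole_domain_equals_global_mean(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=(2, 3, 4))
        iso = _iso(np.zeros((2, 3, 4)), lon=np.linspace(-45, -42, 4),
                   lat=np.linspace(-61, -59, 3),
                   strata=[DepthStratum(0, 100), DepthStratum(100, 200)])
        omap = synoptic_map({"f1": p}, iso, n_mc=1000)
        whole = AreaPolygon("all", [(-46, -62), (-41, -62), (-41, -58), (-46, -58),
                                    (-46, -62)])
        row = area_summary(omap, [whole], depth_range=(0, 200)).iloc[0]
        assert row.mean_probability == pytest.approx(p.mean(axis=0).mean())
        assert row.n_cells == 12

    def test_disjoint_polygons_hand_means(self):
        p = np.array([[[0.1, 0.2, 0.6, 0.8]]])
        iso = _iso(np.zeros((1, 1, 4)), lon=np.array([-45.0, -44.0, -43.0, -42.0]),
                   lat=np.array([-60.0]), strata=[DepthStratum(0, 200)])
        omap = synoptic_map({"f1": p}, iso, n_mc=1000)
        west = AreaPolygon("W", [(-45.5, -61), (-43.5, -61), (-43.5, -59), (-45.5, -59),
                                 (-45.5, -61)])
        east = AreaPolygon("E", [(-43.5, -61), (-41.5, -61), (-41.5, -59), (-43.5, -59),
                                 (-43.5, -61)])
        res = area_summary(omap, [west, east], depth_range=(0, 200)).set_index("area")
        assert res.loc["W", "mean_probability"] == pytest.approx(0.15)
        assert res.loc["E", "mean_probability"] == pytest.approx(0.7)


class TestTopPercentile:
    def _omap(self, per_fish, n_lo):
        iso = _iso(np.zeros((1, 1, n_lo)))
        return synoptic_map(per_fish, iso, n_mc=1000)

    def test_uniform_map_ties_include_all_cells(self):
        omap = self._omap({"f1": np.full((1, 1, 10), 0.5)}, 10)
        cells = top_percentile_region(omap, q=0.95)[0]
        assert cells.all()

    def test_single_hot_cell_in_top_set(self):
        p = np.linspace(0.1, 0.2, 100).reshape(1, 1, 100)
        p[0, 0, 42] = 0.9
        omap = self._omap({"f1": p}, 100)
        cells = top_percentile_region(omap, q=0.95)[0]
        assert cells[0, 42]
        assert cells.sum() <= 5

    def test_zero_quantile_returns_everything(self):
        omap = self._omap({"f1": np.random.default_rng(0).uniform(size=(1, 1, 20))}, 20)
        assert top_percentile_region(omap, q=0.0)[0].all()

    def test_clusters_use_their_own_members(self):
        hot_w = np.array([[[0.9, 0.1, 0.1, 0.1]]])
        hot_e = np.array([[[0.1, 0.1, 0.1, 0.9]]])
        omap = self._omap({"f1": hot_w, "f2": hot_e}, 4)
        tops = top_percentile_region(omap, labels={"f1": 0, "f2": 1}, q=0.75)
        assert tops[0][0, 0] and not tops[0][0, 3]
        assert tops[1][0, 3] and not tops[1][0, 0]
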