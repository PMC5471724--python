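"""Covariate construction: weather aggregates, GDD, lags, distances,
ecoregion lookup, and attachment."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, Polygon, box

from movescale import covariates as cov
from movescale.homerange import project_aeqd


class TestSVPD:
    def test_saturated_air_zero_deficit(self):
        assert cov.svpd_mmhg(20.0, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_tetens_at_25C_half_rh(self):
        svp25 = 610.78 * np.exp(17.27 * 25 / (25 + 237.3)) / 133.322
        assert svp25 == pytest.approx(23.76, abs=0.05)
        assert cov.svpd_mmhg(25.0, 50.0) == pytest.approx(0.5 * svp25, rel=1e-12)
        assert cov.svpd_mmhg(25.0, 50.0) == pytest.approx(11.88, abs=0.05)

    def test_monotone_in_temperature_at_fixed_rh(self):
        temps = np.linspace(0, 40, 50)
        d = cov.svpd_mmhg(temps, 60.0)
        assert (np.diff(d) > 0).all()


class TestGDD:
    @pytest.mark.parametrize("tmax,tmin,expected", [(25, 15, 10), (12, 4, 0),
                                                    (20, 0, 0)])
    def test_values(self, tmax, tmin, expected):
        assert cov.gdd(tmax, tmin) == pytest.approx(expected)

    def test_month_of_identical_days_sums(self):
        total = sum(cov.gdd(25, 15) for _ in range(30))
        assert total == pytest.approx(300)

    def test_tmax_below_tmin_rejected(self):
        with pytest.raises(ValueError):
            cov.gdd(10, 20)


def _hourly_weather(temps=None, rh=100.0, precip=0.0, start="2010-01-01",
                    n_hours=48):
    times = pd.date_range(start, periods=n_hours, freq="h")
    return pd.DataFrame({
        "study_id": "s1",
        "timestamp": times,
        "temp_c": 20.0 if temps is None else temps,
        "pressure_pa": 101325.0,
        "precip_mm": precip,
        "wind_ms": 3.0,
        "rh_pct": rh,
    })


class TestDailyAggregate:
    def test_constant_saturated_air(self):
        dw = cov.daily_weather_table(_hourly_weather())
        full = dw.dropna()
        assert (full["svpd_mmhg"].abs() < 1e-12).all()
        assert (full["tmean_c"] == 20.0).all()

    def test_precip_totalled_over_window(self):
        dw = cov.daily_weather_table(_hourly_weather(precip=0.5))
        full = dw[dw["precip_mm"].notna()]
        # 14-hour biological-day window at 0.5 mm/h
        assert full["precip_mm"].max() == pytest.approx(7.0)

    def test_coverage_gap_yields_missing(self):
        w = _hourly_weather()
        w = w[w["timestamp"].dt.hour % 2 == 0]  # half the hours missing
        dw = cov.daily_weather_table(w)
        assert dw["tmean_c"].isna().all()


class TestMonthlyLags:
    def _series(self, values):
        months = pd.period_range("2009-01", periods=len(values), freq="M")
        return pd.DataFrame({"study_id": "s1", "month": months,
                             "tmean_c": values,
                             "precip_mm": np.asarray(values) * 10.0})

    def test_lag_one_and_twelve(self):
        lags = cov.monthly_lags(self._series(np.arange(1.0, 25.0)))
        row = lags[lags["month"] == pd.Period("2010-01")].iloc[0]  # month 13
        assert row["lag1_tmean_c"] == 12.0
        assert row["lag12_tmean_c"] == 1.0

    def test_insufficient_history_missing(self):
        lags = cov.monthly_lags(self._series(np.arange(1.0, 25.0)))
        first = lags[lags["month"] == pd.Period("2009-01")].iloc[0]
        assert np.isnan(first["lag1_tmean_c"])

    def test_matches_brute_force_shift(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        lags = cov.monthly_lags(self._series(vals))
        for k in (1, 5, 12):
            got = lags[f"lag{k}_tmean_c"].to_numpy()
            want = np.concatenate([np.full(k, np.nan), vals[:-k]])
            np.testing.assert_allclose(got, want, equal_nan=True)

    def test_lag_commutes_with_series_shift(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        l1 = cov.monthly_lags(self._series(vals))
        l2 = cov.monthly_lags(self._series(np.roll(vals, 0) + 3.0))
        np.testing.assert_allclose(
            l2["lag3_tmean_c"].to_numpy(), l1["lag3_tmean_c"].to_numpy() + 3.0,
            equal_nan=True,
        )


from movescale.homerange import unproject_aeqd


def km_geom_to_lonlat(coords, lat0=30.0, lon0=-95.0):
    """Exact inverse of the local equal-area plane used for distances."""
    xy = np.asarray(coords, dtype=float)
    lon, lat = unproject_aeqd(xy[:, 0], xy[:, 1], lon0, lat0)
    return list(zip(np.atleast_1d(lon), np.atleast_1d(lat)))


class TestDistances:
    def test_point_to_segment_one_km(self):
        seg = LineString(km_geom_to_lonlat([(-1, 0), (1, 0)]))
        lonlat = km_geom_to_lonlat([(0, 1)])[0]
        d = cov.distance_to_feature([lonlat[0]], [lonlat[1]], [seg],
                                    lon0=-95.0, lat0=30.0)
        assert d[0] == pytest.approx(1.0, rel=1e-6)

    def test_beyond_endpoint_distance_to_endpoint(self):
        seg = LineString(km_geom_to_lonlat([(-1, 0), (1, 0)]))
        lonlat = km_geom_to_lonlat([(4, 4)])[0]
        d = cov.distance_to_feature([lonlat[0]], [lonlat[1]], [seg],
                                    lon0=-95.0, lat0=30.0)
        assert d[0] == pytest.approx(np.hypot(3, 4), rel=1e-3)

    def test_inside_polygon_zero(self):
        poly = Polygon(km_geom_to_lonlat([(-1, -1), (1, -1), (1, 1), (-1, 1)]))
        d = cov.distance_to_feature([-95.0], [30.0], [poly],
                                    lon0=-95.0, lat0=30.0)
        assert d[0] == 0.0

    def test_empty_class_missing(self):
        d = cov.distance_to_feature([-95.0], [30.0], [])
        assert np.isnan(d[0])

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(5)
        a, b = np.array([-2.0, -1.0]), np.array([3.0, 2.0])
        seg = LineString(km_geom_to_lonlat([tuple(a), tuple(b)]))
        p = rng.uniform(-3, 3, 2)
        lonlat = km_geom_to_lonlat([tuple(p)])[0]
        d = cov.distance_to_feature([lonlat[0]], [lonlat[1]], [seg],
                                    lon0=-95.0, lat0=30.0)[0]
        ts = np.linspace(0, 1, 100_000)
        samples = a[None, :] + ts[:, None] * (b - a)[None, :]
        oracle = np.min(np.hypot(*(samples - p).T))
        assert abs(d - oracle) < 1e-4

    def test_translation_consistent(self):
        seg0 = [(-1.0, 0.0), (1.0, 0.5)]
        p0 = (0.3, 1.2)
        dists = []
        for shift in [(0.0, 0.0), (4.0, -2.0)]:
            seg = LineString(km_geom_to_lonlat(
                [(x + shift[0], y + shift[1]) for x, y in seg0]
            ))
            lonlat = km_geom_to_lonlat([(p0[0] + shift[0], p0[1] + shift[1])])[0]
            dists.append(cov.distance_to_feature(
                [lonlat[0]], [lonlat[1]], [seg], lon0=-95.0, lat0=30.0
            )[0])
        assert dists[0] == pytest.approx(dists[1], abs=1e-6)


class TestEcoregionLookup:
    def test_inside_and_outside(self):
        polys = [("A", box(0, 0, 1, 1)), ("B", box(1, 0, 2, 1))]
        labels = cov.ecoregion_lookup([0.5, 2.5], [0.5, 0.5], polys)
        assert labels == ["A", None]

    def test_boundary_goes_to_first_polygon(self):
        polys = [("A", box(0, 0, 1, 1)), ("B", box(1, 0, 2, 1))]
        assert cov.ecoregion_lookup([1.0], [0.5], polys) == ["A"]

    def test_matches_shapely_oracle_on_random_points(self):
        rng = np.random.default_rng(2)
        polys = [
            ("A", Polygon([(0, 0), (2, 0.3), (1.7, 2.1), (0.2, 1.8)])),
            ("B", Polygon([(2, 0.3), (4, 0), (4.2, 2), (1.7, 2.1)])),
        ]
        lon = rng.uniform(-0.5, 4.5, 1000)
        lat = rng.uniform(-0.5, 2.5, 1000)
        got = cov.ecoregion_lookup(lon, lat, polys)
        for g, x, y in zip(got, lon, lat):
            p = Point(x, y)
            oracle = None
            for label, poly in polys:
                if poly.covers(p):
                    oracle = label
                    break
            assert g == oracle


class TestAttach:
    def test_constant_weather_shared_covariates(self, daily_small, sim_small):
        wx = sim_small.weather.copy()
        for c in ["temp_c", "pressure_pa", "wind_ms", "rh_pct"]:
            wx[c] = {"temp_c": 20.0, "pressure_pa": 101325.0,
                     "wind_ms": 3.0, "rh_pct": 70.0}[c]
        wx["precip_mm"] = 0.0
        sub = daily_small[daily_small["study_id"] == "study01"].head(50)
        table, _ = cov.attach(sub, wx, None, "daily")
        for c in ["tmean_c", "pressure_pa", "svpd_mmhg"]:
            assert table[c].nunique() == 1

    def test_sex_age_concatenation(self, daily_small, sim_small):
        table, _ = cov.attach(daily_small.head(100), sim_small.weather, None, "daily")
        assert set(table["sex_age"]).issubset({
            f"{a}-{s}" for a in ("adult", "subadult", "juvenile", "unknown")
            for s in ("M", "F", "unknown")
        })

    def test_monthly_tmean_is_mean_of_daily_means(self, sim_small, screened_small,
                                                  daily_small):
        from movescale import metrics

        monthly = metrics.aggregate(daily_small, "monthly",
                                    screened_small.month_eligibility)
        dw = cov.daily_weather_table(sim_small.weather)
        table, _ = cov.attach(monthly, sim_small.weather, None, "monthly",
                              daily_weather=dw)
        row = table.iloc[0]
        dws = dw[(dw["study_id"] == row["study_id"])
                 & (pd.to_datetime(dw["bio_day"]).dt.to_period("M")
                    == pd.Period(f"{int(row['year'])}-{int(row['month']):02d}"))]
        assert row["tmean_c"] == pytest.approx(dws["tmean_c"].mean())

    def test_manifest_reports_categories_and_missing(self, daily_small, sim_small):
        table, man = cov.attach(daily_small, sim_small.weather,
                                sim_small.landscape, "daily")
        assert set(man["categories"]) == {
            "individual", "meteorological", "temporal", "geographic", "landscape"
        }
        assert man["missing"]["ecoregion"] == 0
        assert (table[cov.LANDSCAPE_COLUMNS] >= 0).all().all()
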