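"""Home ranges: MCP geometry, variograms, OU fits, sAKDE."""

import numpy as np
import pandas as pd
import pytest

from movescale import synthetic
from movescale.homerange import (
    InsufficientDataError,
    convex_hull,
    empirical_variogram,
    fit_ou,
    mcp_area,
    polygon_area,
    project_aeqd,
    sakde_area,
)

KM_PER_DEG = 6371.0088 * np.pi / 180.0  # spherical, ~111.195


def km_points_to_lonlat(xy, lat0=0.0, lon0=0.0):
    xy = np.asarray(xy, dtype=float)
    lat = lat0 + xy[:, 1] / KM_PER_DEG
    lon = lon0 + xy[:, 0] / (KM_PER_DEG * np.cos(np.radians(lat0)))
    return lon, lat


def gift_wrap_hull(points):
    """Independent convex-hull oracle (Jarvis march)."""
    pts = np.unique(np.asarray(points, float), axis=0)
    n = len(pts)
    start = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % n
        for r in range(n):
            u, v = pts[q] - pts[p], pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[r] - pts[p]) >
                             np.linalg.norm(pts[q] - pts[p])):
                q = r
        if q == start:
            break
        hull.append(q)
        if len(hull) > n:  # pragma: no cover
            raise RuntimeError("gift wrapping failed")
    return pts[hull]


class TestMCP:
    def test_unit_square_full_percent(self):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        lon, lat = km_points_to_lonlat(corners)
        res = mcp_area(lon, lat, percent=100)
        assert res.area_km2 == pytest.approx(1.0, rel=1e-4)

    def test_outlier_trimmed_at_95_percent(self):
        rng = np.random.default_rng(1)
        cluster = rng.uniform(0, 1, (19, 2))
        pts = np.vstack([cluster, [50.0, 50.0]])
        lon, lat = km_points_to_lonlat(pts)
        t = pd.date_range("2010-01-01", periods=20, freq="h")
        res = mcp_area(lon, lat, percent=95, timestamps=t)
        assert res.n_retained == 19
        assert 19 not in set(res.kept_index)  # the far outlier is trimmed
        assert res.area_km2 < 2.0

    def test_matches_gift_wrapping_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.normal(0, 2, (200, 2))
            lon, lat = km_points_to_lonlat(pts, lat0=30.0, lon0=-95.0)
            res = mcp_area(lon, lat, percent=100)
            x, y = project_aeqd(lon, lat, np.mean(lon), np.mean(lat))
            oracle = polygon_area(gift_wrap_hull(np.column_stack([x, y])))
            assert res.area_km2 == pytest.approx(oracle, rel=1e-9)

    def test_area_nondecreasing_in_percent(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (100, 2))
        lon, lat = km_points_to_lonlat(pts)
        areas = [mcp_area(lon, lat, percent=p).area_km2
                 for p in (50, 70, 90, 95, 100)]
        assert all(a <= b + 1e-12 for a, b in zip(areas, areas[1:]))

    def test_identical_points_degenerate(self):
        lon = np.full(6, -95.0)
        lat = np.full(6, 30.0)
        res = mcp_area(lon, lat)
        assert res.area_km2 == 0.0 and res.degenerate

    def test_too_few_points_raise(self):
        with pytest.raises(InsufficientDataError):
            mcp_area([0, 1, 2], [0, 1, 2])

    def test_point_order_invariant(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, (50, 2))
        lon, lat = km_points_to_lonlat(pts)
        a1 = mcp_area(lon, lat, percent=100).area_km2
        perm = rng.permutation(50)
        a2 = mcp_area(lon[perm], lat[perm], percent=100).area_km2
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_hull_oracle_small_instances(self):
        rng = np.random.default_rng(11)
        for n in (5, 8, 13):
            pts = rng.uniform(-1, 1, (n, 2))
            assert polygon_area(convex_hull(pts)) == pytest.approx(
                polygon_area(gift_wrap_hull(pts)), rel=1e-12
            )


class TestVariogram:
    def test_iid_positions_flat_at_per_axis_variance(self):
        rng = np.random.default_rng(4)
        n = 4000
        t = np.arange(n, dtype=float)
        s = 1.3
        x = rng.normal(0, s, n)
        y = rng.normal(0, s, n)
        vg = empirical_variogram(t, x, y, lag_bins_h=np.arange(0, 21, 2.0))
        # E||dr||^2/4 = s^2 for independent 2-D gaussians
        assert np.nanmax(np.abs(vg["gamma_km2"] - s**2)) < 0.15 * s**2

    def test_single_pair_bin_value(self):
        vg = empirical_variogram([0.0, 5.0], [0.0, 3.0], [0.0, 4.0],
                                 lag_bins_h=np.array([4.0, 6.0]))
        assert vg["gamma_km2"].iloc[0] == pytest.approx(25.0 / 4.0)
        assert vg["n_pairs"].iloc[0] == 1

    def test_empty_bins_reported_missing(self):
        vg = empirical_variogram([0.0, 1.0], [0, 1], [0, 0],
                                 lag_bins_h=np.array([0.0, 0.5, 1.5]))
        assert np.isnan(vg["gamma_km2"].iloc[0])
        assert vg["n_pairs"].iloc[0] == 0

    def test_exact_ou_track_matches_closed_form(self):
        """Binned semivariance of an exact-OU track tracks
        sigma^2 (1 - exp(-l/tau))."""
        rng = np.random.default_rng(6)
        tau, sigma = 12.0, 0.8
        n = 20000
        rho = np.exp(-1.0 / tau)
        eps = rng.standard_normal((n, 2)) * sigma * np.sqrt(1 - rho**2)
        pos = np.zeros((n, 2))
        for i in range(1, n):
            pos[i] = rho * pos[i - 1] + eps[i]
        t = np.arange(n, dtype=float)
        vg = empirical_variogram(t, pos[:, 0], pos[:, 1],
                                 lag_bins_h=np.arange(0, 49, 4.0))
        expected = sigma**2 * (1 - np.exp(-vg["lag_h"] / tau))
        rel = np.abs(vg["gamma_km2"] - expected) / sigma**2
        assert np.nanmax(rel) < 0.15


class TestOUFit:
    def test_noise_free_inversion(self):
        tau, s2 = 12.0, 0.5
        lag = np.arange(1.0, 61.0, 2.0)
        vg = pd.DataFrame({
            "lag_h": lag,
            "gamma_km2": s2 * (1 - np.exp(-lag / tau)),
            "n_pairs": 100,
        })
        fit = fit_ou(vg)
        assert fit.tau_h == pytest.approx(tau, abs=1e-4)
        assert fit.sigma2_km2 == pytest.approx(s2, rel=1e-6)
        assert fit.converged

    def test_recovery_from_exact_ou_tracks(self):
        taus = []
        true_tau = 12.0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            rho = np.exp(-1.0 / true_tau)
            n = 1500
            eps = rng.standard_normal((n, 2)) * 0.7 * np.sqrt(1 - rho**2)
            pos = np.zeros((n, 2))
            for i in range(1, n):
                pos[i] = rho * pos[i - 1] + eps[i]
            vg = empirical_variogram(np.arange(n, dtype=float),
                                     pos[:, 0], pos[:, 1],
                                     lag_bins_h=np.arange(0, 73, 4.0))
            taus.append(fit_ou(vg).tau_h)
        assert abs(np.median(taus) - true_tau) / true_tau < 0.25

    def test_flat_variogram_hits_lower_bound_with_independence_flag(self):
        lag = np.arange(1.0, 41.0, 2.0)
        vg = pd.DataFrame({"lag_h": lag, "gamma_km2": 1.0, "n_pairs": 50})
        fit = fit_ou(vg)
        assert fit.independent

    def test_too_few_bins_raise(self):
        vg = pd.DataFrame({"lag_h": [1, 2, 3], "gamma_km2": [1, 1, 1],
                           "n_pairs": [5, 5, 5]})
        with pytest.raises(InsufficientDataError):
            fit_ou(vg)


class TestSAKDE:
    def test_gaussian_95_area_matches_closed_form(self):
        rng = np.random.default_rng(8)
        n = 10_000
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        res = sakde_area(x, y, tau_h=0.0, duration_h=n, percent=95)
        # 95% HDR of a standard bivariate normal: pi * chi2_2(0.95) ~ 18.8
        expected = np.pi * 5.991
        assert abs(res.area_km2 - expected) / expected < 0.05

    def test_inflated_tau_strictly_larger_area(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0, 1, 2000)
        a_small = sakde_area(x, y, tau_h=1.0, duration_h=2000.0).area_km2
        a_big = sakde_area(x, y, tau_h=100.0, duration_h=2000.0).area_km2
        assert a_big > a_small

    def test_grid_refinement_changes_area_under_one_percent(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 3000)
        y = rng.normal(0, 1, 3000)
        a1 = sakde_area(x, y, 0.0, 3000.0, grid_n=160).area_km2
        a2 = sakde_area(x, y, 0.0, 3000.0, grid_n=320).area_km2
        assert abs(a2 - a1) / a1 < 0.01

    def test_tau_at_duration_flagged_unreliable(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        res = sakde_area(x, y, tau_h=600.0, duration_h=500.0)
        assert res.unreliable
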