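"""Predictor construction: the five covariate categories at each scale.

* individual — sex_age (age class and sex concatenated, e.g. "adult-M") and
  the management indicator;
* meteorological — max/min/mean temperature (degC), mean relative humidity
  (%), mean saturation vapour-pressure deficit (mm Hg, Tetens formula),
  total precipitation (mm), mean surface pressure (Pa), mean wind speed
  (m/s), and growing degree days with respect to a 10 degC base, aggregated
  over the 18:00–08:00 biological-day window so that covariates align with
  the nocturnal movement responses;
* temporal — month (entering models as a cyclic term), year, and monthly
  mean-temperature / total-precipitation lags of 1..12 months (proxies for
  biotic productivity);
* geographic — the level-III ecoregion of the record's centroid;
* landscape — distances (km) from the record's centroid to the nearest
  water body, stream, agricultural field, forest patch, and major / medium /
  minor road.

Monthly meteorology is the mean of the daily values (precipitation summed);
all covariates are attached at the record's home-range centroid (mean
lat/lon of its fixes).  Weather is taken from the study's series (nearest
series, no spatial interpolation), which keeps the synthetic path exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import Point
from shapely.ops import transform as shapely_transform

from .homerange import project_aeqd
from .telemetry import assign_biological_day

__all__ = [
    "svp_mmhg",
    "svpd_mmhg",
    "gdd",
    "daily_weather_table",
    "monthly_weather_series",
    "monthly_lags",
    "distance_to_feature",
    "ecoregion_lookup",
    "attach",
    "CATEGORY_COLUMNS",
]

MMHG_PER_PA = 1.0 / 133.322

MET_COLUMNS = [
    "tmax_c", "tmin_c", "tmean_c", "rh_pct", "svpd_mmhg",
    "precip_mm", "pressure_pa", "wind_ms", "gdd",
]
LANDSCAPE_CLASSES = [
    ("water", None), ("stream", None), ("agriculture", None), ("forest", None),
    ("road", "major"), ("road", "medium"), ("road", "minor"),
]
LANDSCAPE_COLUMNS = [
    "dist_water_km", "dist_stream_km", "dist_agriculture_km",
    "dist_forest_km", "dist_road_major_km", "dist_road_medium_km",
    "dist_road_minor_km",
]

CATEGORY_COLUMNS = {
    "individual": ["sex_age", "managed"],
    "meteorological": MET_COLUMNS,
    "temporal": ["month", "year"],  # + lag columns at the monthly scale
    "geographic": ["ecoregion"],
    "landscape": LANDSCAPE_COLUMNS,
}


def svp_mmhg(temp_c) -> np.ndarray | float:
    """Saturation vapour pressure (Tetens), in mm Hg."""
    t = np.asarray(temp_c, dtype=float)
    svp_pa = 610.78 * np.exp(17.27 * t / (t + 237.3))
    out = svp_pa * MMHG_PER_PA
    return out if out.ndim else float(out)


def svpd_mmhg(temp_c, rh_pct) -> np.ndarray | float:
    """Saturation vapour-pressure deficit: zero exactly at RH=100%."""
    rh = np.asarray(rh_pct, dtype=float)
    out = (1.0 - rh / 100.0) * np.asarray(svp_mmhg(temp_c))
    return out if out.ndim else float(out)


def gdd(tmax_c, tmin_c, base_c: float = 10.0) -> np.ndarray | float:
    """Growing degree days: max(0, (tmax+tmin)/2 - base)."""
    tmax = np.asarray(tmax_c, dtype=float)
    tmin = np.asarray(tmin_c, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("gdd requires tmax >= tmin")
    out = np.maximum(0.0, (tmax + tmin) / 2.0 - base_c)
    return out if out.ndim else float(out)


def daily_weather_table(
    weather: pd.DataFrame,
    night_start_hour: int = 18,
    night_end_hour: int = 8,
    max_gap_fraction: float = 0.2,
) -> pd.DataFrame:
    """Aggregate hourly weather to biological-day values per study.

    The window is [day 18:00, day+1 08:00).  Days whose hourly coverage has
    a gap exceeding ``max_gap_fraction`` of the window are reported with
    missing values rather than imputed.
    """
    w = assign_biological_day(weather, night_start_hour, night_end_hour)
    w = w[~w["diurnal"]].copy()
    window_hours = (24 - night_start_hour) + night_end_hour
    rows = []
    for (sid, day), g in w.groupby(["study_id", "bio_day"]):
        if len(g) < (1.0 - max_gap_fraction) * window_hours:
            rec = {c: np.nan for c in MET_COLUMNS}
        else:
            t = g["temp_c"].to_numpy()
            rec = {
                "tmax_c": float(t.max()),
                "tmin_c": float(t.min()),
                "tmean_c": float(t.mean()),
                "rh_pct": float(g["rh_pct"].mean()),
                "svpd_mmhg": float(np.mean(svpd_mmhg(t, g["rh_pct"].to_numpy()))),
                "precip_mm": float(g["precip_mm"].sum()),
                "pressure_pa": float(g["pressure_pa"].mean()),
                "wind_ms": float(g["wind_ms"].mean()),
            }
            rec["gdd"] = gdd(rec["tmax_c"], rec["tmin_c"])
        rec["study_id"] = sid
        rec["bio_day"] = day
        rows.append(rec)
    return pd.DataFrame(rows)


def monthly_weather_series(weather: pd.DataFrame) -> pd.DataFrame:
    """Calendar-month mean temperature and total precipitation per study
    (the lag-series inputs), from the full hourly history including burn-in."""
    w = weather.copy()
    w["date"] = pd.to_datetime(w["timestamp"]).dt.normalize()
    daily = (
        w.groupby(["study_id", "date"])
        .agg(tmean_c=("temp_c", "mean"), precip_mm=("precip_mm", "sum"))
        .reset_index()
    )
    daily["month"] = daily["date"].dt.to_period("M")
    return (
        daily.groupby(["study_id", "month"])
        .agg(tmean_c=("tmean_c", "mean"), precip_mm=("precip_mm", "sum"))
        .reset_index()
    )


def monthly_lags(
    series: pd.DataFrame,
    columns: tuple[str, ...] = ("tmean_c", "precip_mm"),
    max_lag: int = 12,
) -> pd.DataFrame:
    """Wide lag columns: ``lag{k}_{col}`` holds the value k months before the
    row's month.  Insufficient history yields missing values."""
    parts = []
    for sid, g in series.groupby("study_id"):
        g = g.sort_values("month").set_index("month")
        out = pd.DataFrame(index=g.index)
        out["study_id"] = sid
        for col in columns:
            for k in range(1, max_lag + 1):
                out[f"lag{k}_{col}"] = g[col].reindex(g.index - k).to_numpy()
        parts.append(out.reset_index())
    return pd.concat(parts, ignore_index=True)


def _project_geom(geom, lon0: float, lat0: float):
    return shapely_transform(
        lambda gx, gy: project_aeqd(np.asarray(gx), np.asarray(gy), lon0, lat0), geom
    )


def distance_to_feature(
    lon,
    lat,
    geoms: list,
    lon0: float | None = None,
    lat0: float | None = None,
) -> np.ndarray:
    """Minimum distance (km) from each centroid to any geometry of a class.

    Geometries are given in lon/lat; both points and geometry vertices are
    projected into a shared local equal-area plane before measuring, so
    polyline distances reduce to planar point-to-segment and polygon
    distances are 0 inside.  An empty class returns NaN for every point.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if not geoms:
        return np.full(len(lon), np.nan)
    if lon0 is None:
        lon0 = float(lon.mean())
    if lat0 is None:
        lat0 = float(lat.mean())
    x, y = project_aeqd(lon, lat, lon0, lat0)
    pts = [Point(xi, yi) for xi, yi in zip(x, y)]
    proj = [_project_geom(g, lon0, lat0) for g in geoms]
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        out[i] = min(p.distance(g) for g in proj)
    return out


def _point_in_ring(px: float, py: float, ring: np.ndarray) -> bool:
    """Ray casting (horizontal ray towards +x); boundary treated as inside."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        # on-segment check (boundary -> inside)
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
            return True
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if xint > px:
                inside = not inside
    return inside


def ecoregion_lookup(lon, lat, polygons: list[tuple[str, object]]) -> list:
    """Label of the containing ecoregion polygon for each centroid.

    ``polygons`` is a list of (label, shapely Polygon) in file order;
    point-in-polygon by ray casting on lon/lat coordinates, boundary points
    assigned to the first polygon in file order.  Points outside every
    polygon get None.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    rings = [(label, np.asarray(poly.exterior.coords)[:-1]) for label, poly in polygons]
    out = []
    for px, py in zip(lon, lat):
        found = None
        for label, ring in rings:
            if _point_in_ring(px, py, ring):
                found = label
                break
        out.append(found)
    return out


def _landscape_distances(
    records: pd.DataFrame, landscape: pd.DataFrame
) -> pd.DataFrame:
    """Per-record distance columns, computed study-by-study in each study's
    local projection (translation-consistent)."""
    land = landscape.copy()
    if "geometry" not in land.columns:
        land["geometry"] = [shapely_wkt.loads(w) for w in land["wkt"]]
    out = pd.DataFrame(index=records.index, columns=LANDSCAPE_COLUMNS, dtype=float)
    for sid, recs in records.groupby("study_id"):
        feats = land[land["study_id"] == sid]
        lon0 = float(recs["cen_lon"].mean())
        lat0 = float(recs["cen_lat"].mean())
        for (cls, detail), col in zip(LANDSCAPE_CLASSES, LANDSCAPE_COLUMNS):
            sel = feats["feature_class"] == cls
            if detail is not None:
                sel &= feats["class_detail"] == detail
            geoms = list(feats.loc[sel, "geometry"])
            out.loc[recs.index, col] = distance_to_feature(
                recs["cen_lon"], recs["cen_lat"], geoms, lon0, lat0
            )
    return out


def attach(
    records: pd.DataFrame,
    weather: pd.DataFrame,
    landscape: pd.DataFrame | None,
    scale: str,
    daily_weather: pd.DataFrame | None = None,
    max_lag: int = 12,
) -> tuple[pd.DataFrame, dict]:
    """Build the covariate table for one scale's modelling records.

    ``records`` is the metrics (or home-range) table for the scale, with
    ``study_id``, centroid columns, and ``bio_day`` (daily) or ``month``
    (monthly).  Returns (covariate table, manifest mapping column ->
    category).  Missing values propagate; a per-column missingness count is
    included in the manifest under "missing".
    """
    if scale not in {"daily", "monthly", "overall"}:
        raise ValueError(f"unknown scale {scale!r}")
    out = records.copy()
    if daily_weather is None:
        daily_weather = daily_weather_table(weather)

    # individual
    out["sex_age"] = out["age_class"].astype(str) + "-" + out["sex"].astype(str)
    out["managed"] = out["managed"].astype(int)

    # meteorological + temporal
    if scale == "daily":
        out = out.merge(daily_weather, on=["study_id", "bio_day"], how="left")
        bd = pd.to_datetime(out["bio_day"])
        out["month"] = bd.dt.month.astype(float)
        out["year"] = bd.dt.year.astype(float)
    else:
        dw = daily_weather.copy()
        dw["month"] = pd.to_datetime(dw["bio_day"]).dt.to_period("M")
        agg = {c: "mean" for c in MET_COLUMNS}
        agg["precip_mm"] = "sum"
        met_m = dw.groupby(["study_id", "month"]).agg(agg).reset_index()
        if scale == "monthly":
            out = out.merge(met_m, on=["study_id", "month"], how="left")
            lags = monthly_lags(monthly_weather_series(weather), max_lag=max_lag)
            out = out.merge(lags, on=["study_id", "month"], how="left")
            out["year"] = out["month"].dt.year.astype(float)
            out["month"] = out["month"].dt.month.astype(float)
        else:  # overall: average the study's eligible-period daily values
            met_o = dw.groupby("study_id")[MET_COLUMNS].mean().reset_index()
            out = out.merge(met_o, on="study_id", how="left")
            yr = (
                weather.assign(year=pd.to_datetime(weather["timestamp"]).dt.year)
                .groupby("study_id")["year"].mean().reset_index()
            )
            out = out.merge(yr, on="study_id", how="left")

    # geographic + landscape
    if landscape is not None and len(landscape):
        land = landscape.copy()
        if "geometry" not in land.columns:
            land["geometry"] = [shapely_wkt.loads(w) for w in land["wkt"]]
        eco = land[land["feature_class"] == "ecoregion"]
        polys = list(zip(eco["label"], eco["geometry"]))
        out["ecoregion"] = ecoregion_lookup(out["cen_lon"], out["cen_lat"], polys)
        dists = _landscape_distances(out, land)
        for c in LANDSCAPE_COLUMNS:
            out[c] = dists[c].to_numpy()
    else:
        out["ecoregion"] = None
        for c in LANDSCAPE_COLUMNS:
            out[c] = np.nan

    manifest: dict = {"scale": scale, "categories": {}, "missing": {}}
    for cat, cols in CATEGORY_COLUMNS.items():
        cols = list(cols)
        if cat == "temporal":
            if scale == "monthly":
                cols = cols + [c for c in out.columns if c.startswith("lag")]
            elif scale == "overall":
                cols = ["year"]
        cols = [c for c in cols if c in out.columns]
        manifest["categories"][cat] = cols
        for c in cols:
            manifest["missing"][c] = int(out[c].isna().sum())
    return out, manifest
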