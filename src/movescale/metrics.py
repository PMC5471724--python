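"""Daily movement metrics (MxD, MHD) and their monthly/overall aggregation.

MxD is the maximum great-circle distance between any two fixes within one
biological day — the farthest an animal ranged that night.  MHD is the mean
of distances between fix pairs approximately one hour apart (the pairing
rule below), a short-term movement-rate proxy.  Daily values are averaged
per animal at the monthly scale (only months with enough monitored days)
and at the overall scale (all daily values combined, not a mean of monthly
means).  Each record carries a weight — the mean number of fixes per day —
and the centroid (mean lat/lon) of its contributing fixes, which downstream
models use for precision weighting and covariate attachment.

Pairing rule for MHD: for each fix (origin), among subsequent fixes whose
time separation falls in [50, 70] minutes, take the one closest to 60
minutes (ties -> the earlier fix).  A fix may serve as origin of one pair
and target of others, so overlapping pairs are allowed: fixes every 30
minutes from 8:00 to 10:30 give exactly four pairs (origins 8:00, 8:30,
9:00, 9:30).  The window is configurable; no rate normalisation by the
exact time separation is applied (distances are averaged as-is).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "geo_distance",
    "daily_mxd",
    "hour_pairs",
    "daily_mhd",
    "build_daily_records",
    "aggregate",
]

EARTH_RADIUS_KM = 6371.0088


def geo_distance(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle (haversine) distance in km; accepts arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.ndim else float(d)


class UndefinedMetricError(ValueError):
    """Raised when a metric's preconditions (e.g. >= 2 fixes) fail."""


def _pairwise_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    return geo_distance(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def daily_mxd(lon, lat, times) -> tuple[float, float]:
    """Maximum pairwise distance among a day's fixes.

    Returns ``(mxd_km, dt_hours)`` where ``dt_hours`` is the time separation
    of the arg-max pair (used for the >3 h diagnostic).  Requires >= 2 fixes.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if len(lon) < 2:
        raise UndefinedMetricError("daily_mxd requires at least 2 fixes")
    d = _pairwise_km(lon, lat)
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    t = pd.to_datetime(pd.Series(times)).to_numpy()
    dt_h = abs((t[j] - t[i]) / np.timedelta64(1, "s")) / 3600.0
    return float(d[i, j]), float(dt_h)


def hour_pairs(
    times,
    target_min: float = 60.0,
    window_min: tuple[float, float] = (50.0, 70.0),
) -> list[tuple[int, int]]:
    """Index pairs approximately one hour apart (see module docstring).

    ``times`` must be sorted ascending.  Returns a (possibly empty) list of
    (origin, target) index pairs.
    """
    t = pd.to_datetime(pd.Series(times)).to_numpy()
    n = len(t)
    lo, hi = window_min
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        best_j = -1
        best_err = np.inf
        for j in range(i + 1, n):
            dt = (t[j] - t[i]) / np.timedelta64(1, "m")
            if dt > hi:
                break
            if dt < lo:
                continue
            err = abs(dt - target_min)
            if err < best_err:  # strict: ties keep the earlier fix
                best_err = err
                best_j = j
        if best_j >= 0:
            pairs.append((i, best_j))
    return pairs


def daily_mhd(
    lon, lat, times,
    target_min: float = 60.0,
    window_min: tuple[float, float] = (50.0, 70.0),
) -> tuple[float, int] | tuple[None, int]:
    """Mean distance over the day's hour-apart pairs.

    Returns ``(mhd_km, n_pairs)``; ``(None, 0)`` when no pair exists — that
    day still contributes to MxD but not MHD.
    """
    pairs = hour_pairs(times, target_min, window_min)
    if not pairs:
        return None, 0
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    d = geo_distance(lon[i], lat[i], lon[j], lat[j])
    return float(np.mean(d)), len(pairs)


def build_daily_records(
    fixes: pd.DataFrame,
    target_min: float = 60.0,
    window_min: tuple[float, float] = (50.0, 70.0),
) -> pd.DataFrame:
    """One row per animal × biological day with MxD, MHD, weight, centroid.

    Expects screened fixes (``bio_day`` assigned, >= 2 fixes per retained
    day).
    """
    rows = []
    for (aid, day), g in fixes.groupby(["animal_id", "bio_day"], sort=True):
        lon = g["lon"].to_numpy()
        lat = g["lat"].to_numpy()
        t = g["timestamp"]
        if len(g) < 2:
            continue
        mxd, dt_h = daily_mxd(lon, lat, t)
        mhd, n_pairs = daily_mhd(lon, lat, t, target_min, window_min)
        rows.append(
            {
                "study_id": g["study_id"].iloc[0],
                "animal_id": aid,
                "bio_day": day,
                "n_fixes": len(g),
                "mxd_km": mxd,
                "mxd_dt_h": dt_h,
                "mhd_km": np.nan if mhd is None else mhd,
                "n_pairs": n_pairs,
                "cen_lon": float(lon.mean()),
                "cen_lat": float(lat.mean()),
                "sex": g["sex"].iloc[0] if "sex" in g else "unknown",
                "age_class": g["age_class"].iloc[0] if "age_class" in g else "unknown",
                "managed": int(g["managed"].iloc[0]) if "managed" in g else 0,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["animal_id", "bio_day"]).reset_index(drop=True)
    return df


@dataclass
class _AggSpec:
    keys: list[str]


def aggregate(
    daily: pd.DataFrame,
    scale: str,
    month_eligibility: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate daily records to the monthly or overall scale.

    Unweighted mean of the daily values per animal(-month); the record
    weight is the mean number of fixes per day; the centroid is the mean
    lat/lon over contributing fixes (daily centroids weighted by their fix
    counts).  MHD aggregates only over MHD-defined days.  At the monthly
    scale only months flagged eligible (>= 15 monitored days) appear.
    """
    if scale not in {"monthly", "overall"}:
        raise ValueError(f"unknown scale {scale!r}")
    if len(daily) == 0:
        return pd.DataFrame()
    df = daily.copy()
    df["month"] = pd.to_datetime(df["bio_day"]).dt.to_period("M")
    if scale == "monthly":
        if month_eligibility is not None and len(month_eligibility):
            elig = month_eligibility[month_eligibility["eligible"]]
            key = pd.MultiIndex.from_frame(df[["animal_id", "month"]])
            ok = key.isin(pd.MultiIndex.from_frame(elig[["animal_id", "month"]]))
            df = df.loc[ok]
        keys = ["animal_id", "month"]
    else:
        keys = ["animal_id"]
    if len(df) == 0:
        return pd.DataFrame()

    def agg_group(g: pd.DataFrame) -> pd.Series:
        wsum = g["n_fixes"].sum()
        mhd_days = g["mhd_km"].notna()
        return pd.Series(
            {
                "study_id": g["study_id"].iloc[0],
                "mxd_km": g["mxd_km"].mean(),
                "mhd_km": g.loc[mhd_days, "mhd_km"].mean() if mhd_days.any() else np.nan,
                "n_days": len(g),
                "n_mhd_days": int(mhd_days.sum()),
                "weight": wsum / len(g),
                "cen_lon": (g["cen_lon"] * g["n_fixes"]).sum() / wsum,
                "cen_lat": (g["cen_lat"] * g["n_fixes"]).sum() / wsum,
                "sex": g["sex"].iloc[0],
                "age_class": g["age_class"].iloc[0],
                "managed": int(g["managed"].max()),
            }
        )

    out = df.groupby(keys, sort=True).apply(agg_group, include_groups=False).reset_index()
    return out
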