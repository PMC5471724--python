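"""Telemetry ingest, quality screening, and the nocturnal biological day.

Wild pig activity in the study region is primarily nocturnal, so the
analysis "day" is the 18:00–08:00 window: a fix at or after 18:00 belongs to
that calendar date's biological day, a fix before 08:00 belongs to the
previous date's, and fixes between 08:00 and 18:00 are labelled diurnal and
excluded from all analyses.

Screening applies, in order:

1. drop fixes with DOP > 10 (10.0 itself is kept — "greater than" read
   strictly);
2. drop diurnal fixes;
3. drop biological days with fewer than 2 fixes;
4. drop animals with fewer than 20 retained biological days;
5. flag animal-months with fewer than 15 retained days as ineligible for
   monthly aggregation.

"Monitored for at least 20 days" is counted in retained biological days,
the same unit as the 15-day monthly rule; calendar-span counting is
available via ``ScreenThresholds.min_days_unit="span"``.  Every rule's
removal count is recorded in an audit report rather than silently applied.
Timestamps are treated as local study clock time with no DST arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ScreenThresholds",
    "ReadReport",
    "ScreenResult",
    "REQUIRED_COLUMNS",
    "read_fixes",
    "assign_biological_day",
    "screen",
]

REQUIRED_COLUMNS = [
    "study_id", "animal_id", "timestamp", "lon", "lat", "dop",
]
OPTIONAL_COLUMNS = ["sex", "age_class", "managed"]


class SchemaError(ValueError):
    """Input file does not match the telemetry CSV schema."""


@dataclass
class ScreenThresholds:
    dop_max: float = 10.0
    min_fixes_per_day: int = 2
    min_days: int = 20
    min_days_per_month: int = 15
    night_start_hour: int = 18
    night_end_hour: int = 8
    #: "retained" (retained biological days) or "span" (calendar span)
    min_days_unit: str = "retained"


@dataclass
class ReadReport:
    n_rows: int = 0
    n_parsed: int = 0
    n_bad_timestamp: int = 0
    n_bad_coordinates: int = 0
    n_duplicates: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ScreenResult:
    fixes: pd.DataFrame
    audit: dict = field(default_factory=dict)
    #: per (animal_id, month) eligibility for monthly aggregation
    month_eligibility: pd.DataFrame | None = None


def read_fixes(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Parse a telemetry CSV.

    Rows with unparseable coordinates or timestamps, coordinates outside
    valid ranges, or negative DOP are counted in the report and dropped;
    exact-duplicate rows are removed and counted.  A missing required column
    raises :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(path, dtype={"study_id": str, "animal_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    report = ReadReport(n_rows=len(df))

    ndup = int(df.duplicated().sum())
    df = df.drop_duplicates()
    report.n_duplicates = ndup

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    report.n_bad_timestamp = int(bad_ts.sum())

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    dop = pd.to_numeric(df["dop"], errors="coerce")
    bad_coord = (
        lon.isna() | lat.isna() | dop.isna()
        | (lat < -90) | (lat > 90) | (lon < -180) | (lon > 180) | (dop < 0)
    )
    report.n_bad_coordinates = int((bad_coord & ~bad_ts).sum())

    keep = ~(bad_ts | bad_coord)
    out = df.loc[keep].copy()
    out["timestamp"] = ts[keep]
    out["lon"] = lon[keep]
    out["lat"] = lat[keep]
    out["dop"] = dop[keep]
    for col in OPTIONAL_COLUMNS:
        if col not in out.columns:
            out[col] = "unknown" if col != "managed" else 0
    # within-animal timestamp duplicates violate the strictly-increasing
    # invariant: keep the first occurrence
    before = len(out)
    out = out.sort_values(["animal_id", "timestamp"], kind="stable")
    out = out.drop_duplicates(subset=["animal_id", "timestamp"], keep="first")
    report.n_duplicates += before - len(out)
    report.n_parsed = len(out)
    return out.reset_index(drop=True), report


def assign_biological_day(
    fixes: pd.DataFrame,
    night_start_hour: int = 18,
    night_end_hour: int = 8,
) -> pd.DataFrame:
    """Attach ``bio_day`` (date) and ``diurnal`` (bool) columns.

    Times >= night_start get their own calendar date; times < night_end get
    the previous date; everything in between is diurnal (bio_day = NaT).
    """
    ts = pd.to_datetime(fixes["timestamp"])
    hour = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    date = ts.dt.normalize()
    out = fixes.copy()
    evening = hour >= night_start_hour
    morning = hour < night_end_hour
    bio = pd.Series(pd.NaT, index=fixes.index, dtype="datetime64[ns]")
    bio[evening] = date[evening]
    bio[morning] = date[morning] - pd.Timedelta(days=1)
    out["bio_day"] = bio
    out["diurnal"] = ~(evening | morning)
    return out


def screen(
    fixes: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
) -> ScreenResult:
    """Apply the screening rules in order, with a per-rule audit.

    Empty input yields an empty result with a zeroed audit.  Screening is
    idempotent and insensitive to input row order (output is sorted by
    animal and timestamp).
    """
    th = thresholds or ScreenThresholds()
    audit: dict = {
        "input_fixes": int(len(fixes)),
        "removed_dop": 0,
        "removed_diurnal": 0,
        "removed_sparse_days": 0,
        "removed_short_animals": 0,
        "animals_removed": 0,
        "retained_fixes": 0,
        "retained_animals": 0,
        "ineligible_months": 0,
    }
    empty_elig = pd.DataFrame(
        columns=["animal_id", "month", "n_days", "eligible"]
    )
    if len(fixes) == 0:
        return ScreenResult(fixes=fixes.copy(), audit=audit,
                            month_eligibility=empty_elig)

    df = fixes.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)

    # 1. DOP filter (strictly greater than the threshold is removed)
    keep = df["dop"].to_numpy() <= th.dop_max
    audit["removed_dop"] = int((~keep).sum())
    df = df.loc[keep]

    # 2. nocturnal window
    if "bio_day" not in df.columns or "diurnal" not in df.columns:
        df = assign_biological_day(df, th.night_start_hour, th.night_end_hour)
    keep = ~df["diurnal"].to_numpy()
    audit["removed_diurnal"] = int((~keep).sum())
    df = df.loc[keep]

    # 3. biological days with < 2 fixes
    if len(df):
        counts = df.groupby(["animal_id", "bio_day"])["timestamp"].transform("size")
        keep = counts.to_numpy() >= th.min_fixes_per_day
        audit["removed_sparse_days"] = int((~keep).sum())
        df = df.loc[keep]

    # 4. animals monitored < min_days
    if len(df):
        if th.min_days_unit == "span":
            span = df.groupby("animal_id")["bio_day"].transform(
                lambda s: (s.max() - s.min()).days + 1
            )
            keep = span.to_numpy() >= th.min_days
        else:
            ndays = df.groupby("animal_id")["bio_day"].transform("nunique")
            keep = ndays.to_numpy() >= th.min_days
        audit["removed_short_animals"] = int((~keep).sum())
        audit["animals_removed"] = int(df.loc[~keep, "animal_id"].nunique())
        df = df.loc[keep]

    # 5. monthly eligibility flags
    if len(df):
        month = df["bio_day"].dt.to_period("M")
        elig = (
            df.assign(month=month)
            .groupby(["animal_id", "month"])["bio_day"]
            .nunique()
            .rename("n_days")
            .reset_index()
        )
        elig["eligible"] = elig["n_days"] >= th.min_days_per_month
        audit["ineligible_months"] = int((~elig["eligible"]).sum())
    else:
        elig = empty_elig

    df = df.reset_index(drop=True)
    audit["retained_fixes"] = int(len(df))
    audit["retained_animals"] = int(df["animal_id"].nunique()) if len(df) else 0
    return ScreenResult(fixes=df, audit=audit, month_eligibility=elig)
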