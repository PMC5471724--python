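"""Synthetic multi-study GPS telemetry with known movement drivers.

Generates the kind of heterogeneous telemetry that large collaborative
wildlife-movement datasets contain — many studies with different fix
schedules, sex/age structure, regional (ecoregion) baselines, and
weather-driven movement — but with the generative coefficients recorded, so
that every downstream stage (screening, movement metrics, home ranges,
covariate attachment, variable screening, additive mixed models) can be
checked against ground truth.

The movement model is a discrete-time Ornstein–Uhlenbeck (OU) attraction to
a home-range centre.  The per-step displacement scale ``s`` is log-linear in
covariates::

    log s = ecoregion intercept + a*T^2 + b*T + c + pressure_slope*(P - P0)
            + sex/age offset + animal effect + study effect + daily anomaly

which guarantees positivity and makes a concave (inverted-U) temperature
reaction norm on the natural scale a testable property.  An exact OU
transition is available (``exact_ou=True``) for variogram work; the Euler
step is the default.  A linear drift of the home-range centre
(``drift_km_per_day``) produces non-stationary, dispersal-like tracks for
home-range bias scenarios.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import LineString, Point, Polygon, box

__all__ = [
    "ECOREGIONS",
    "TrueEffects",
    "StudyConfig",
    "SimConfig",
    "SimulatedDataset",
    "InvalidConfigError",
    "CoverageError",
    "default_config",
    "small_config",
    "simulate_weather",
    "simulate_track",
    "simulate_landscape",
    "simulate_dataset",
    "export_dataset",
    "load_truth",
]

#: Level-III ecoregion labels of the southern-US study domain.
ECOREGIONS = [
    "Southern Coastal Plain",
    "Southeastern Plains",
    "Mississippi Alluvial Plain",
    "Western Gulf Coastal Plain",
    "South Central Plains",
    "Ozark Highlands",
    "Central Irregular Plains",
    "East Central Texas Plains",
    "Southern Texas Plains",
]

STANDARD_PRESSURE_PA = 101_325.0
KM_PER_DEG_LAT = 110.574


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


class CoverageError(ValueError):
    """Raised when weather does not cover an animal's monitoring span."""


@dataclass
class TrueEffects:
    """Generative coefficients, retained for parameter-recovery tests.

    All movement coefficients act on the log per-step displacement scale
    (log km at a 1-h reference step).
    """

    ecoregion_intercepts: dict[str, float] = field(
        default_factory=lambda: {
            # drier regions (Texas plains, Ozarks) move more; mesic ones less
            "Southern Coastal Plain": -1.55,
            "Southeastern Plains": -1.50,
            "Mississippi Alluvial Plain": -1.70,
            "Western Gulf Coastal Plain": -1.55,
            "South Central Plains": -1.45,
            "Ozark Highlands": -1.25,
            "Central Irregular Plains": -1.40,
            "East Central Texas Plains": -1.35,
            "Southern Texas Plains": -1.20,
        }
    )
    #: quadratic temperature reaction norm a*T^2 + b*T + c, peak at 20 degC
    temp_quad: tuple[float, float, float] = (-0.004, 0.16, -1.6)
    #: slope on (pressure - 101325 Pa); negative = more movement at low pressure
    pressure_slope: float = -5e-5
    sex_age_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "adult-F": 0.0,
            "adult-M": 0.40,
            "subadult-F": -0.05,
            "subadult-M": 0.20,
            "juvenile-F": -0.25,
            "juvenile-M": -0.25,
        }
    )
    animal_sd: float = 0.3
    study_sd: float = 0.2
    #: daily behavioural anomaly, AR(1) on the log-scale
    daily_ar_phi: float = 0.5
    daily_ar_sd: float = 0.15

    def temp_peak_c(self) -> float:
        a, b, _ = self.temp_quad
        return -b / (2.0 * a)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrueEffects":
        d = dict(d)
        d["temp_quad"] = tuple(d["temp_quad"])
        return cls(**d)


@dataclass
class StudyConfig:
    study_id: str
    n_animals: int
    fix_interval_min: float
    start: datetime
    n_days: int
    ecoregion: str
    center_lon: float
    center_lat: float
    extent_km: float = 30.0

    def __post_init__(self) -> None:
        if self.fix_interval_min <= 0:
            raise InvalidConfigError("fix_interval_min must be > 0")
        if self.n_days < 1:
            raise InvalidConfigError(
                f"study {self.study_id}: span shorter than 1 day"
            )
        if self.ecoregion not in ECOREGIONS:
            raise InvalidConfigError(f"unknown ecoregion {self.ecoregion!r}")


@dataclass
class SimConfig:
    """Full generator configuration.

    Defaults for the weather and observation-noise blocks emulate southern-US
    conditions: seasonal + diurnal temperature cycles with AR(1) daily
    anomalies, surface pressure fluctuating around 101,325 Pa, and a
    lognormal DOP distribution with ~5% of mass above 10 so the DOP filter
    is exercised.
    """

    studies: list[StudyConfig]
    effects: TrueEffects = field(default_factory=TrueEffects)
    seed: int = 0
    # movement
    tau_hours: float = 12.0
    exact_ou: bool = False
    drift_km_per_day: float = 0.0
    # observation
    fix_failure_prob: float = 0.10
    dop_mu: float = 0.75
    dop_sigma: float = 0.95
    gps_noise_km_per_dop: float = 0.005
    # weather
    weather_burn_in_days: int = 400
    seasonal_amp_c: float = 9.0
    diurnal_amp_c: float = 5.0
    anomaly_phi: float = 0.7
    anomaly_sd_c: float = 2.5
    temp_noise_sd_c: float = 0.3
    pressure_phi: float = 0.8
    pressure_sd_pa: float = 700.0
    # landscape densities (expected feature count per study area)
    landscape_density: dict = field(
        default_factory=lambda: {
            "water": 4,
            "stream": 2,
            "agriculture": 2,
            "forest": 2,
            "road_major": 1,
            "road_medium": 1,
            "road_minor": 2,
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.fix_failure_prob <= 1.0):
            raise InvalidConfigError("fix_failure_prob must lie in [0, 1]")
        if self.effects.animal_sd < 0 or self.effects.study_sd < 0:
            raise InvalidConfigError("random-effect sds must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for s in d["studies"]:
            s["start"] = s["start"].isoformat()
        d["effects"]["temp_quad"] = list(d["effects"]["temp_quad"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["studies"] = [
            StudyConfig(**{**s, "start": datetime.fromisoformat(s["start"])})
            for s in d["studies"]
        ]
        d["effects"] = TrueEffects.from_dict(d["effects"])
        return cls(**d)


@dataclass
class SimulatedDataset:
    telemetry: pd.DataFrame
    weather: pd.DataFrame
    landscape: pd.DataFrame
    effects: TrueEffects
    config: SimConfig
    #: realised per-animal and per-study random intercepts (log-scale)
    animal_effects: dict[str, float] = field(default_factory=dict)
    study_effects: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# configurations


def default_config(seed: int = 0) -> SimConfig:
    """Paper-scale default: 13 studies, 6 states' worth of spread, ~226
    animals, fix intervals from 15 min to 12 h, 2004–2016 span."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    intervals = [15, 30, 30, 60, 60, 60, 60, 120, 120, 240, 480, 720, 60]
    n_animals = [12, 15, 20, 25, 18, 20, 15, 22, 16, 18, 15, 12, 18]  # 226
    years = [2004, 2005, 2006, 2007, 2008, 2009, 2010, 2011, 2012, 2013,
             2014, 2015, 2016]
    # rough southern-US longitudinal gradient
    lons = np.linspace(-98.5, -81.5, 13)
    lats = 27.5 + 5.0 * rng.random(13)
    studies = []
    for i in range(13):
        studies.append(
            StudyConfig(
                study_id=f"study{i + 1:02d}",
                n_animals=n_animals[i],
                fix_interval_min=intervals[i],
                start=datetime(years[i], 3, 1),
                n_days=int(rng.integers(60, 180)),
                ecoregion=ECOREGIONS[i % len(ECOREGIONS)],
                center_lon=float(lons[i]),
                center_lat=float(lats[i]),
            )
        )
    return SimConfig(studies=studies, seed=seed)


def small_config(
    seed: int = 0,
    n_studies: int = 5,
    animals_per_study: int = 20,
    n_days: int = 60,
    fix_interval_min: float = 60.0,
    start_month: int = 4,
    **overrides,
) -> SimConfig:
    """Compact configuration for tests and worked examples."""
    studies = [
        StudyConfig(
            study_id=f"study{i + 1:02d}",
            n_animals=animals_per_study,
            fix_interval_min=fix_interval_min,
            start=datetime(2010, start_month, 1) + timedelta(days=7 * i),
            n_days=n_days,
            ecoregion=ECOREGIONS[i % len(ECOREGIONS)],
            center_lon=-97.0 + 3.0 * i,
            center_lat=28.0 + 1.5 * (i % 4),
        )
        for i in range(n_studies)
    ]
    return SimConfig(studies=studies, seed=seed, **overrides)


def _study_rng(config: SimConfig, study_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), study_index, stream])
    )


# ---------------------------------------------------------------------------
# weather


def _seasonal_temp(config: SimConfig, study: StudyConfig, times: pd.DatetimeIndex) -> np.ndarray:
    doy = times.dayofyear.to_numpy()
    hour = times.hour.to_numpy()
    base = 26.0 - 0.6 * (study.center_lat - 28.0)
    seasonal = config.seasonal_amp_c * np.cos(2 * np.pi * (doy - 196) / 365.25)
    diurnal = config.diurnal_amp_c * np.cos(2 * np.pi * (hour - 15) / 24.0)
    return base + seasonal + diurnal


def simulate_weather(config: SimConfig) -> pd.DataFrame:
    """Hourly weather per study: temp_c, pressure_pa, precip_mm, wind_ms,
    rh_pct.

    Temperature = seasonal + diurnal sinusoid + AR(1) daily anomaly + hourly
    noise; pressure fluctuates around 101,325 Pa with an AR(1) anomaly.  The
    series starts ``weather_burn_in_days`` before each study so that monthly
    lagged covariates (up to 12 months) always have history.  Deterministic
    under the config seed.
    """
    frames = []
    for i, study in enumerate(config.studies):
        if study.n_days < 1:
            raise InvalidConfigError("span shorter than 1 day")
        rng = _study_rng(config, i, stream=1)
        t0 = study.start - timedelta(days=config.weather_burn_in_days)
        t1 = study.start + timedelta(days=study.n_days + 1)
        times = pd.date_range(t0, t1, freq="h", inclusive="left")
        n_days = (times[-1].normalize() - times[0].normalize()).days + 1

        day_index = ((times.normalize() - times[0].normalize()).days).to_numpy()
        anom_day = _ar1_series(n_days, config.anomaly_phi, config.anomaly_sd_c, rng)
        temp = (
            _seasonal_temp(config, study, times)
            + anom_day[day_index]
            + (rng.normal(0.0, config.temp_noise_sd_c, len(times))
               if config.temp_noise_sd_c > 0 else 0.0)
        )

        p_anom_day = _ar1_series(n_days, config.pressure_phi, config.pressure_sd_pa, rng)
        pressure = STANDARD_PRESSURE_PA + p_anom_day[day_index] + rng.normal(
            0.0, 40.0, len(times)
        )

        wet = rng.random(len(times)) < 0.05
        precip = np.where(wet, rng.exponential(1.5, len(times)), 0.0)
        wind = np.abs(rng.normal(3.0, 1.5, len(times)))
        rh = np.clip(
            78.0 - 1.1 * (temp - _seasonal_temp(config, study, times))
            - 0.4 * (temp - 22.0) + rng.normal(0.0, 6.0, len(times)),
            20.0,
            100.0,
        )
        frames.append(
            pd.DataFrame(
                {
                    "study_id": study.study_id,
                    "timestamp": times,
                    "temp_c": temp,
                    "pressure_pa": pressure,
                    "precip_mm": precip,
                    "wind_ms": wind,
                    "rh_pct": rh,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _ar1_series(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


# ---------------------------------------------------------------------------
# movement


@dataclass
class _Animal:
    animal_id: str
    study: StudyConfig
    sex: str
    age_class: str
    managed: bool
    effect: float  # animal-level random intercept (log-scale)


def _sex_age_key(age_class: str, sex: str) -> str:
    return f"{age_class}-{sex}"


def simulate_track(
    animal: _Animal,
    weather: pd.DataFrame,
    effects: TrueEffects,
    config: SimConfig,
    rng: np.random.Generator,
    study_effect: float = 0.0,
) -> pd.DataFrame:
    """Simulate one animal's fix sequence on the study schedule.

    OU attraction to a home-range centre in a local km plane; the per-step
    displacement scale follows the log-linear covariate model; fixes are
    thinned by the fix-failure probability; each fix receives a lognormal DOP
    draw and DOP-proportional position noise.
    """
    study = animal.study
    dt_h = study.fix_interval_min / 60.0
    n_steps = int(round(study.n_days * 24.0 / dt_h))
    times = pd.date_range(
        study.start, periods=n_steps, freq=pd.Timedelta(minutes=study.fix_interval_min)
    )

    w = weather[weather["study_id"] == study.study_id]
    if len(w) == 0 or w["timestamp"].min() > times[0] or w["timestamp"].max() < times[-1]:
        raise CoverageError(
            f"weather does not cover monitoring span of {animal.animal_id}"
        )
    w = w.set_index("timestamp")
    hours = times.floor("h")
    temp = w["temp_c"].reindex(hours).to_numpy()
    pres = w["pressure_pa"].reindex(hours).to_numpy()

    a, b, c = effects.temp_quad
    n_days = study.n_days + 1
    daily_anom = _ar1_series(n_days, effects.daily_ar_phi, effects.daily_ar_sd, rng)
    day_index = ((times.normalize() - times[0].normalize()).days).to_numpy()

    linpred = (
        effects.ecoregion_intercepts[study.ecoregion]
        + a * temp**2
        + b * temp
        + c
        + effects.pressure_slope * (pres - STANDARD_PRESSURE_PA)
        + effects.sex_age_offsets.get(_sex_age_key(animal.age_class, animal.sex), 0.0)
        + animal.effect
        + study_effect
        + daily_anom[day_index]
    )
    step_scale = np.exp(linpred)  # km per sqrt(hour), per axis

    tau = config.tau_hours
    # home-range centre in the local km plane, offset within the study extent
    mu0 = rng.uniform(-study.extent_km / 2, study.extent_km / 2, size=2)
    drift = config.drift_km_per_day / 24.0  # km per hour, along +x

    pos = np.empty((n_steps, 2))
    x = mu0 + rng.normal(0.0, step_scale[0] * np.sqrt(tau / 2.0), size=2)
    eps = rng.standard_normal((n_steps, 2))
    if config.exact_ou:
        rho = np.exp(-dt_h / tau)
        stat_fac = np.sqrt(tau / 2.0) * np.sqrt(1.0 - rho**2)
        for t in range(n_steps):
            mu = mu0 + np.array([drift * t * dt_h, 0.0])
            x = mu + rho * (x - mu) + step_scale[t] * stat_fac * eps[t]
            pos[t] = x
    else:
        pull = min(dt_h / tau, 1.0)
        sq = np.sqrt(dt_h)
        for t in range(n_steps):
            mu = mu0 + np.array([drift * t * dt_h, 0.0])
            x = x + pull * (mu - x) + step_scale[t] * sq * eps[t]
            pos[t] = x

    kept = rng.random(n_steps) >= config.fix_failure_prob
    if not kept.any():
        return _empty_track()
    dop = np.exp(rng.normal(config.dop_mu, config.dop_sigma, n_steps))
    gps_noise = rng.normal(0.0, 1.0, (n_steps, 2)) * (
        config.gps_noise_km_per_dop * dop[:, None]
    )
    xy = pos + gps_noise

    lat = study.center_lat + xy[:, 1] / KM_PER_DEG_LAT
    lon = study.center_lon + xy[:, 0] / (
        KM_PER_DEG_LAT * np.cos(np.radians(study.center_lat))
    )
    df = pd.DataFrame(
        {
            "study_id": study.study_id,
            "animal_id": animal.animal_id,
            "sex": animal.sex,
            "age_class": animal.age_class,
            "managed": int(animal.managed),
            "timestamp": times,
            "lon": lon,
            "lat": lat,
            "dop": dop,
        }
    )
    return df.loc[kept].reset_index(drop=True)


def _empty_track() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "study_id", "animal_id", "sex", "age_class", "managed",
            "timestamp", "lon", "lat", "dop",
        ]
    )


# ---------------------------------------------------------------------------
# landscape


def _study_bbox(study: StudyConfig) -> tuple[float, float, float, float]:
    dlat = study.extent_km / KM_PER_DEG_LAT
    dlon = study.extent_km / (KM_PER_DEG_LAT * np.cos(np.radians(study.center_lat)))
    return (
        study.center_lon - dlon,
        study.center_lat - dlat,
        study.center_lon + dlon,
        study.center_lat + dlat,
    )


def simulate_landscape(config: SimConfig) -> pd.DataFrame:
    """Labelled vector features per study: water points, stream/road
    polylines (roads in three classes), agriculture and forest polygons, and
    one ecoregion polygon per study (the study bounding boxes partition the
    study domain because studies are placed apart).

    A density of 0 for a class yields no features of that class; downstream
    distance computation flags the class as missing.
    """
    rows = []
    for i, study in enumerate(config.studies):
        rng = _study_rng(config, i, stream=2)
        x0, y0, x1, y1 = _study_bbox(study)

        def rand_pt():
            return rng.uniform(x0, x1), rng.uniform(y0, y1)

        def n_of(cls: str) -> int:
            dens = config.landscape_density.get(cls, 0)
            return int(max(rng.poisson(dens), 1)) if dens > 0 else 0

        for j in range(n_of("water")):
            rows.append((study.study_id, "water", "", Point(rand_pt()).wkt,
                         f"{study.study_id}-water{j}"))
        for cls, detail in [
            ("stream", ""),
            ("road_major", "major"),
            ("road_medium", "medium"),
            ("road_minor", "minor"),
        ]:
            base = "road" if cls.startswith("road") else "stream"
            for j in range(n_of(cls)):
                pts = [rand_pt() for _ in range(3)]
                rows.append((study.study_id, base if base == "stream" else "road",
                             detail, LineString(pts).wkt,
                             f"{study.study_id}-{cls}{j}"))
        for cls in ("agriculture", "forest"):
            for j in range(n_of(cls)):
                cx, cy = rand_pt()
                w = (x1 - x0) * rng.uniform(0.05, 0.15)
                h = (y1 - y0) * rng.uniform(0.05, 0.15)
                rows.append((study.study_id, cls, "",
                             box(cx - w, cy - h, cx + w, cy + h).wkt,
                             f"{study.study_id}-{cls}{j}"))
        rows.append((study.study_id, "ecoregion", "",
                     box(x0, y0, x1, y1).wkt, study.ecoregion))
    return pd.DataFrame(
        rows, columns=["study_id", "feature_class", "class_detail", "wkt", "label"]
    )


# ---------------------------------------------------------------------------
# orchestration and export


_SEX_AGE_CLASSES = [
    ("F", "adult"), ("M", "adult"), ("F", "subadult"), ("M", "subadult"),
    ("F", "juvenile"), ("M", "unknown"),
]
_SEX_AGE_PROBS = [0.32, 0.28, 0.14, 0.14, 0.02, 0.10]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: weather, landscape, and one track per animal."""
    weather = simulate_weather(config)
    landscape = simulate_landscape(config)
    telemetry_parts = []
    animal_effects: dict[str, float] = {}
    study_effects: dict[str, float] = {}
    for i, study in enumerate(config.studies):
        rng = _study_rng(config, i, stream=3)
        s_eff = float(rng.normal(0.0, config.effects.study_sd))
        study_effects[study.study_id] = s_eff
        for k in range(study.n_animals):
            aid = f"{study.study_id}-a{k + 1:03d}"
            ci = rng.choice(len(_SEX_AGE_CLASSES), p=_SEX_AGE_PROBS)
            sex, age = _SEX_AGE_CLASSES[ci]
            a_eff = float(rng.normal(0.0, config.effects.animal_sd))
            animal_effects[aid] = a_eff
            animal = _Animal(
                animal_id=aid, study=study, sex=sex, age_class=age,
                managed=bool(rng.random() < 0.3), effect=a_eff,
            )
            telemetry_parts.append(
                simulate_track(animal, weather, config.effects, config, rng, s_eff)
            )
    telemetry = pd.concat(telemetry_parts, ignore_index=True)
    return SimulatedDataset(
        telemetry=telemetry,
        weather=weather,
        landscape=landscape,
        effects=config.effects,
        config=config,
        animal_effects=animal_effects,
        study_effects=study_effects,
    )


def export_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write telemetry/weather CSVs, landscape WKT-in-CSV, and a truth JSON.

    Round-trips through :mod:`movescale.telemetry` without loss.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "telemetry": outdir / "telemetry.csv",
        "weather": outdir / "weather.csv",
        "landscape": outdir / "landscape.csv",
        "truth": outdir / "truth.json",
    }
    tel = dataset.telemetry.copy()
    tel["timestamp"] = pd.to_datetime(tel["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    tel.to_csv(paths["telemetry"], index=False)
    wx = dataset.weather.copy()
    wx["timestamp"] = pd.to_datetime(wx["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    wx.to_csv(paths["weather"], index=False)
    dataset.landscape.to_csv(paths["landscape"], index=False)
    truth = {
        "effects": dataset.effects.to_dict(),
        "config": dataset.config.to_dict(),
        "animal_effects": dataset.animal_effects,
        "study_effects": dataset.study_effects,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def load_truth(path: str | Path) -> tuple[TrueEffects, SimConfig]:
    d = json.loads(Path(path).read_text())
    return TrueEffects.from_dict(d["effects"]), SimConfig.from_dict(d["config"])


def parse_landscape(df: pd.DataFrame):
    """Decode the WKT column into shapely geometries (adds 'geometry')."""
    out = df.copy()
    out["geometry"] = [shapely_wkt.loads(w) for w in out["wkt"]]
    return out
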