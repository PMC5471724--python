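import numpy as np
import pandas as pd
import pytest

from movescale import covariates as cov
from movescale import gamm, metrics, synthetic, telemetry


@pytest.fixture(scope="session")
def sim_small():
    """2 studies x 5 animals x 40 days of hourly fixes."""
    cfg = synthetic.small_config(seed=1, n_studies=2, animals_per_study=5, n_days=40)
    return synthetic.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def screened_small(sim_small):
    fixes = telemetry.assign_biological_day(sim_small.telemetry)
    return telemetry.screen(fixes)


@pytest.fixture(scope="session")
def daily_small(screened_small):
    return metrics.build_daily_records(screened_small.fixes)


@pytest.fixture(scope="session")
def recovery():
    """Parameter-recovery scenario: 100 animals (5 studies x 20), 60 days of
    hourly fixes starting in late winter so the 20 degC temperature optimum
    sits interior to the observed range.  Daily and monthly covariate tables
    plus the fitted meteorological / individual / geographic models."""
    cfg = synthetic.small_config(
        seed=7, n_studies=5, animals_per_study=20, n_days=60, start_month=2
    )
    ds = synthetic.simulate_dataset(cfg)
    fixes = telemetry.assign_biological_day(ds.telemetry)
    res = telemetry.screen(fixes)
    daily = metrics.build_daily_records(res.fixes)
    monthly = metrics.aggregate(daily, "monthly", res.month_eligibility)
    t_daily, _ = cov.attach(daily, ds.weather, ds.landscape, "daily")
    t_monthly, _ = cov.attach(monthly, ds.weather, ds.landscape, "monthly")

    re_terms = [gamm.RandomIntercept("animal_id"), gamm.RandomIntercept("study_id")]
    spatial = [gamm.SmoothTerm("cen_lat"), gamm.SmoothTerm("cen_lon")]

    met_terms = [gamm.SmoothTerm("tmean_c"), gamm.SmoothTerm("pressure_pa")]
    fit_met_daily = gamm.fit_ar1(gamm.build_design(
        gamm.ModelSpec("mxd_km", "daily", "meteorological",
                       met_terms + spatial + re_terms,
                       weights_col="n_fixes", ar1=True),
        t_daily,
    ))
    fit_met_monthly = gamm.fit(gamm.build_design(
        gamm.ModelSpec("mxd_km", "monthly", "meteorological",
                       [gamm.SmoothTerm("tmean_c"), gamm.SmoothTerm("pressure_pa")]
                       + spatial + re_terms,
                       weights_col="weight"),
        t_monthly,
    ))
    fit_ind = gamm.fit_ar1(gamm.build_design(
        gamm.ModelSpec("mxd_km", "daily", "individual",
                       [gamm.FactorTerm("sex_age"), gamm.LinearTerm("managed")]
                       + spatial + re_terms,
                       weights_col="n_fixes", ar1=True),
        t_daily,
    ))
    fit_geo = gamm.fit_ar1(gamm.build_design(
        gamm.ModelSpec("mxd_km", "daily", "geographic",
                       [gamm.FactorTerm("ecoregion")] + spatial + re_terms,
                       weights_col="n_fixes", ar1=True),
        t_daily,
    ))
    return {
        "dataset": ds,
        "daily": t_daily,
        "monthly": t_monthly,
        "fit_met_daily": fit_met_daily,
        "fit_met_monthly": fit_met_monthly,
        "fit_individual": fit_ind,
        "fit_geographic": fit_geo,
    }


def make_fixes(rows):
    """Build a telemetry frame from (animal, iso-timestamp, lon, lat, dop)."""
    df = pd.DataFrame(rows, columns=["animal_id", "timestamp", "lon", "lat", "dop"])
    df["study_id"] = "s1"
    df["sex"] = "F"
    df["age_class"] = "adult"
    df["managed"] = 0
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df
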