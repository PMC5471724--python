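"""End-to-end orchestration: simulate or ingest telemetry, screen, compute
movement metrics and home ranges, attach covariates, screen predictors, and
fit the response x scale x category model grid.

The model grid covers the five predictor categories for each response at
each applicable scale: MxD and MHD at daily/monthly/overall, home-range
area (MCP) at monthly/overall — 5 x (2 x 3 + 1 x 2) = 40 model attempts.
Variable screening (random-forest ranking + de-correlation + accuracy
plateau) is applied to the meteorological and temporal-lag predictor sets,
where multicollinearity is concentrated; a failed or non-converged model
cell does not abort the grid — it is retried once with a reduced predictor
set and recorded in the manifest either way.

A fixed global seed fans out to per-stage seeds via crc32(stage) so partial
reruns are reproducible; rerunning a completed output directory is a no-op
unless forced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import gamm, homerange, metrics, screening, synthetic, telemetry

__all__ = ["RunConfig", "ResultBundle", "run", "summarize"]

log = logging.getLogger("movescale")

RESPONSES = {"MxD": "mxd_km", "MHD": "mhd_km", "HR": "area_km2"}
SCALES = ["daily", "monthly", "overall"]
CATEGORIES = ["individual", "meteorological", "temporal", "geographic", "landscape"]


@dataclass
class RunConfig:
    outdir: str = "movescale_run"
    seed: int = 0
    # input: either simulate (with optional sim sizing) or paths to CSVs
    simulate: bool = True
    sim_n_studies: int = 5
    sim_animals_per_study: int = 20
    sim_n_days: int = 60
    sim_fix_interval_min: float = 60.0
    telemetry_path: str | None = None
    weather_path: str | None = None
    landscape_path: str | None = None
    # screening thresholds (defaults are the study's rules)
    dop_max: float = 10.0
    min_fixes_per_day: int = 2
    min_days: int = 20
    min_days_per_month: int = 15
    night_start_hour: int = 18
    night_end_hour: int = 8
    # metrics
    mhd_target_min: float = 60.0
    mhd_window_min: tuple = (50.0, 70.0)
    # home range
    mcp_percent: float = 95.0
    # predictor screening
    r_threshold: float = 0.5
    epsilon: float = 0.01
    screen_categories: tuple = ("meteorological", "temporal")
    # models
    basis_k: int = 10
    reml: bool = True
    responses: tuple = ("MxD", "MHD", "HR")
    scales: tuple = ("daily", "monthly", "overall")
    categories: tuple = tuple(CATEGORIES)
    force: bool = False

    def thresholds(self) -> telemetry.ScreenThresholds:
        return telemetry.ScreenThresholds(
            dop_max=self.dop_max,
            min_fixes_per_day=self.min_fixes_per_day,
            min_days=self.min_days,
            min_days_per_month=self.min_days_per_month,
            night_start_hour=self.night_start_hour,
            night_end_hour=self.night_end_hour,
        )

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 1_000_003 + zlib.crc32(stage.encode())) % 2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kw = {}
        for k, v in d.items():
            if k not in known:
                raise KeyError(f"unknown config key: {k}")
            fld = next(f for f in dataclasses.fields(cls) if f.name == k)
            if fld.type == "tuple" or isinstance(getattr(cls, k, None), tuple):
                v = tuple(v) if isinstance(v, (list, tuple)) else v
            kw[k] = v
        return cls(**kw)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for k, v in self.to_dict().items():
            if v is None:
                continue
            if isinstance(v, bool):
                lines.append(f"{k} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{k} = {v}")
            elif isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, list):
                items = ", ".join(
                    f'"{x}"' if isinstance(x, str) else str(x) for x in v
                )
                lines.append(f"{k} = [{items}]")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ResultBundle:
    config: RunConfig
    outdir: Path
    audit: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    screening: dict = field(default_factory=dict)  # (resp, scale, cat) key -> result dict
    models: dict = field(default_factory=dict)  # key -> model summary dict
    manifest: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)  # key -> GAMMFit (in-memory only)


def _applicable(response: str, scale: str) -> bool:
    if response == "HR":
        return scale in {"monthly", "overall"}
    return True


def _grid(config: RunConfig):
    for response in config.responses:
        for scale in config.scales:
            if not _applicable(response, scale):
                continue
            for category in config.categories:
                yield response, scale, category


def run(config: RunConfig) -> ResultBundle:
    """Execute the pipeline; see module docstring.

    Returns a :class:`ResultBundle`; all stage outputs are also written
    under ``config.outdir`` with a manifest linking every summary number to
    the stage file it came from.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not config.force:
        log.info("completed run found at %s; skipping (use force to rerun)", outdir)
        return _load_bundle(config, outdir)

    _setup_logging(outdir)
    manifest: dict = {"seed": config.seed, "stages": {}, "models": {}}
    bundle = ResultBundle(config=config, outdir=outdir, manifest=manifest)

    # --- stage: data ------------------------------------------------------
    if config.simulate:
        sim_cfg = synthetic.small_config(
            seed=config.stage_seed("simulate"),
            n_studies=config.sim_n_studies,
            animals_per_study=config.sim_animals_per_study,
            n_days=config.sim_n_days,
            fix_interval_min=config.sim_fix_interval_min,
        )
        dataset = synthetic.simulate_dataset(sim_cfg)
        paths = synthetic.export_dataset(dataset, outdir / "data")
        tel_path, wx_path, land_path = (
            paths["telemetry"], paths["weather"], paths["landscape"],
        )
        log.info("simulated %d fixes across %d studies",
                 len(dataset.telemetry), len(sim_cfg.studies))
    else:
        tel_path = Path(config.telemetry_path)
        wx_path = Path(config.weather_path) if config.weather_path else None
        land_path = Path(config.landscape_path) if config.landscape_path else None
    manifest["stages"]["data"] = {"telemetry": str(tel_path)}

    # --- stage: screen ----------------------------------------------------
    fixes, report = telemetry.read_fixes(tel_path)
    fixes = telemetry.assign_biological_day(
        fixes, config.night_start_hour, config.night_end_hour
    )
    sres = telemetry.screen(fixes, config.thresholds())
    audit = {"read": report.to_dict(), "screen": sres.audit}
    (outdir / "audit.json").write_text(json.dumps(audit, indent=1))
    screened_path = outdir / "screened.csv"
    sres.fixes.to_csv(screened_path, index=False)
    bundle.audit = audit
    manifest["stages"]["screen"] = {
        "audit": str(outdir / "audit.json"), "screened": str(screened_path),
    }
    log.info("screening: %d -> %d fixes, %d animals",
             sres.audit["input_fixes"], sres.audit["retained_fixes"],
             sres.audit["retained_animals"])

    weather = pd.read_csv(wx_path, parse_dates=["timestamp"]) if wx_path else None
    landscape = pd.read_csv(land_path) if land_path else None

    # --- stage: metrics ---------------------------------------------------
    daily = metrics.build_daily_records(
        sres.fixes, config.mhd_target_min, tuple(config.mhd_window_min)
    )
    monthly = metrics.aggregate(daily, "monthly", sres.month_eligibility)
    overall = metrics.aggregate(daily, "overall")
    for name, df in [("daily", daily), ("monthly", monthly), ("overall", overall)]:
        path = outdir / f"metrics_{name}.csv"
        df.to_csv(path, index=False)
        manifest["stages"][f"metrics_{name}"] = {"path": str(path), "rows": len(df)}
        bundle.tables[f"metrics_{name}"] = df
    log.info("metrics: %d daily, %d monthly, %d overall records",
             len(daily), len(monthly), len(overall))

    # --- stage: home ranges ----------------------------------------------
    hr_monthly = homerange.home_range_table(
        sres.fixes, "monthly", config.mcp_percent, sres.month_eligibility
    )
    hr_overall = homerange.home_range_table(
        sres.fixes, "overall", config.mcp_percent, with_sakde=True
    )
    for name, df in [("monthly", hr_monthly), ("overall", hr_overall)]:
        path = outdir / f"homerange_{name}.csv"
        df.to_csv(path, index=False)
        manifest["stages"][f"homerange_{name}"] = {"path": str(path), "rows": len(df)}
        bundle.tables[f"homerange_{name}"] = df
    log.info("home ranges: %d monthly, %d overall estimates",
             len(hr_monthly), len(hr_overall))

    # --- stage: covariates ------------------------------------------------
    if weather is not None:
        dw = cov.daily_weather_table(
            weather, config.night_start_hour, config.night_end_hour
        )
        cov_tables = {}
        manifests = {}
        for scale, recs in [("daily", daily), ("monthly", monthly), ("overall", overall)]:
            if len(recs) == 0:
                continue
            table, man = cov.attach(recs, weather, landscape, scale, daily_weather=dw)
            cov_tables[scale] = table
            manifests[scale] = man
            path = outdir / f"covariates_{scale}.csv"
            table.to_csv(path, index=False)
            manifest["stages"][f"covariates_{scale}"] = {"path": str(path)}
            bundle.tables[f"covariates_{scale}"] = table
        # home-range covariates (monthly / overall), with metric weights
        for scale, hr in [("monthly", hr_monthly), ("overall", hr_overall)]:
            mcp = hr[hr["method"] == "MCP"].copy()
            if len(mcp) == 0:
                continue
            keys = ["animal_id", "month"] if scale == "monthly" else ["animal_id"]
            wsrc = monthly if scale == "monthly" else overall
            if len(wsrc):
                mcp = mcp.merge(wsrc[keys + ["weight"]], on=keys, how="left")
            else:
                mcp["weight"] = 1.0
            table, man = cov.attach(mcp, weather, landscape, scale, daily_weather=dw)
            cov_tables[f"hr_{scale}"] = table
            manifests[f"hr_{scale}"] = man
            path = outdir / f"covariates_hr_{scale}.csv"
            table.to_csv(path, index=False)
            bundle.tables[f"covariates_hr_{scale}"] = table
        (outdir / "covariate_manifest.json").write_text(
            json.dumps(
                {k: v for k, v in manifests.items()}, indent=1, default=str
            )
        )
    else:
        cov_tables, manifests = {}, {}

    # --- stages: predictor screening + models -----------------------------
    for response, scale, category in _grid(config):
        key = f"{response}-{scale}-{category}"
        try:
            table, man = _model_table(response, scale, cov_tables, manifests)
        except KeyError:
            manifest["models"][key] = {"status": "no-data"}
            continue
        if table is None or len(table) < 30:
            manifest["models"][key] = {"status": "no-data"}
            continue
        ycol = RESPONSES[response]
        predictors = man["categories"].get(category, [])
        predictors = [p for p in predictors if p in table.columns]
        screen_info = None
        if category in config.screen_categories and len(predictors) > 1:
            numeric = [p for p in predictors if table[p].dtype.kind in "fiu"]
            try:
                sc = screening.screen_predictors(
                    table[ycol], table[numeric],
                    weights=table.get("weight"),
                    threshold=config.r_threshold,
                    epsilon=config.epsilon,
                    seed=config.stage_seed(f"select-{key}"),
                )
                screen_info = sc
                predictors = sc.final + [p for p in predictors if p not in numeric]
                bundle.screening[key] = sc.to_dict()
                sc.to_json(outdir / f"screening_{key}.json")
            except ValueError:
                pass
        status = _fit_cell(
            bundle, key, response, scale, category, table, predictors, config
        )
        if screen_info is not None:
            status["screened"] = True
        manifest["models"][key] = status

    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    summary = summarize(bundle)
    summary.to_csv(outdir / "significance_matrix.csv", index=False)
    bundle.tables["significance"] = summary
    log.info("run complete: %d model cells attempted", len(manifest["models"]))
    return bundle


def _model_table(response, scale, cov_tables, manifests):
    key = f"hr_{scale}" if response == "HR" else scale
    if key not in cov_tables:
        raise KeyError(key)
    return cov_tables[key], manifests[key]


def _spec_terms(category: str, scale: str, predictors: list[str],
                table: pd.DataFrame, k: int) -> list:
    terms: list = []
    if category == "individual":
        terms.append(gamm.FactorTerm("sex_age"))
        terms.append(gamm.LinearTerm("managed"))
    elif category == "geographic":
        terms.append(gamm.FactorTerm("ecoregion"))
    elif category == "landscape":
        for p in predictors:
            terms.append(gamm.LinearTerm(p))  # distances linearly related
    elif category == "meteorological":
        for p in predictors:
            terms.append(gamm.SmoothTerm(p, k=k))
    elif category == "temporal":
        for p in predictors:
            if p == "month":
                if scale != "overall":
                    terms.append(gamm.SmoothTerm("month", k=min(k, 12),
                                                 cyclic=True, period=(0.5, 12.5)))
            elif p == "year":
                terms.append(gamm.LinearTerm("year"))
            else:
                terms.append(gamm.SmoothTerm(p, k=k))
    # spatial smooths in every model
    terms.append(gamm.SmoothTerm("cen_lat", k=k))
    terms.append(gamm.SmoothTerm("cen_lon", k=k))
    return terms


def _spec_random(scale: str) -> list:
    if scale == "overall":
        return [gamm.RandomIntercept("study_id")]
    return [gamm.RandomIntercept("animal_id"), gamm.RandomIntercept("study_id")]


def _fit_cell(bundle, key, response, scale, category, table, predictors, config):
    ycol = RESPONSES[response]
    weights_col = "n_fixes" if scale == "daily" else "weight"
    if weights_col not in table.columns:
        weights_col = None
    method = "reml" if config.reml else "gcv"

    def attempt(preds):
        terms = _spec_terms(category, scale, preds, table, config.basis_k)
        terms += _spec_random(scale)
        spec = gamm.ModelSpec(
            response=ycol, scale=scale, category=category, terms=terms,
            weights_col=weights_col, ar1=(scale == "daily"),
        )
        design = gamm.build_design(spec, table)
        if scale == "daily":
            return gamm.fit_ar1(design, method=method)
        return gamm.fit(design, method=method)

    try:
        result = attempt(predictors)
        status = {"status": "ok" if result.converged else "nonconverged"}
        if not result.converged and len(predictors) > 2:
            # the study's fallback: reduce to the top predictors and refit
            result2 = attempt(predictors[:2])
            if result2.converged:
                result, status = result2, {"status": "ok", "fallback": True}
    except Exception as exc:  # one failed cell must not abort the grid
        log.warning("model %s failed: %s", key, exc)
        bundle.manifest["models"][key] = {"status": "failed", "error": str(exc)}
        return {"status": "failed", "error": str(exc)}

    summary = result.summary_dict()
    bundle.models[key] = summary
    bundle.fits[key] = result
    (bundle.outdir / f"model_{key}.json").write_text(
        json.dumps(summary, indent=1, default=str)
    )
    curves = []
    for b in result.design.blocks:
        if b.kind == "smooth":
            rn = gamm.reaction_norm(result, b.col)
            curves.append(pd.DataFrame({
                "covariate": b.col, "grid": rn.grid,
                "effect": rn.effect, "se": rn.se,
            }))
    if curves:
        pd.concat(curves, ignore_index=True).to_csv(
            bundle.outdir / f"curves_{key}.csv", index=False
        )
    status["file"] = f"model_{key}.json"
    return status


def summarize(bundle: ResultBundle, alpha: float = 0.05) -> pd.DataFrame:
    """Term x response x scale significance matrix (the tabular analogue of
    a significant-variable summary diagram)."""
    rows = []
    for key, summary in bundle.models.items():
        response, scale, category = key.split("-", 2)
        for term, p in summary["pvalues"].items():
            rows.append({
                "response": response, "scale": scale, "category": category,
                "term": term, "pvalue": p,
                "significant": bool(np.isfinite(p) and p < alpha),
            })
    return pd.DataFrame(rows)


def _setup_logging(outdir: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(sh)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    log.addHandler(fh)


def _load_bundle(config: RunConfig, outdir: Path) -> ResultBundle:
    manifest = json.loads((outdir / "manifest.json").read_text())
    bundle = ResultBundle(config=config, outdir=outdir, manifest=manifest)
    if (outdir / "audit.json").exists():
        bundle.audit = json.loads((outdir / "audit.json").read_text())
    for f in outdir.glob("model_*.json"):
        key = f.stem[len("model_"):]
        bundle.models[key] = json.loads(f.read_text())
    for name in ["metrics_daily", "metrics_monthly", "metrics_overall",
                 "homerange_monthly", "homerange_overall", "significance_matrix"]:
        p = outdir / f"{name}.csv"
        if p.exists():
            bundle.tables[name.replace("_matrix", "")] = pd.read_csv(p)
    return bundle
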