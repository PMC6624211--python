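"""End-to-end orchestration of the sighting-bias analysis.

One :func:`run_pipeline` call executes the full sequence on either a
real record table plus GIS layers or a synthetic scenario:

    ingest -> temporal -> spatial summaries -> density -> covariates
           -> point-process inference

writing every table as CSV, every raster as an ESRI ASCII grid, every
statistic as JSON, and a run manifest reconciling record counts across
stages.  Any stage failure aborts with the stage name and the cleaning
report accumulated so far.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import distance_raster
from .density import classify_density, kde_gaussian, scott_bandwidth
from .grid import FeatureSet, PointPattern, Raster, StudyWindow, read_geojson, write_geojson
from .ingest import clean_pipeline, reporter_stats, summarize_attributes
from .ppp import berman_test, fit_loglinear_ppm, intensity_multiplier, rhohat, roc_auc
from .spatial_summaries import coast_distance_bands, elevation_classes, polygon_tabulate
from .synthetic import SimulationScenario, generate_scenario_data
from .temporal import decompose_additive, monthly_counts, period_aggregate

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

DEFAULT_PERIOD_BREAKS = [(1997, 2000), (2001, 2004), (2005, 2008), (2009, 2013)]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cleaning counts so far."""

    def __init__(self, stage: str, cause: Exception, report=None):
        self.stage = stage
        self.report = report
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``scenario`` (synthetic) or ``records_csv`` plus
    GIS layer paths (real) must be supplied.  All analysis constants
    surface here with the study's standard values as defaults.
    """

    outdir: str | Path = "results/run"
    # synthetic branch
    scenario: SimulationScenario | str | Path | None = None
    # real-data branch
    records_csv: str | Path | None = None
    window_width_km: float | None = None
    window_height_km: float | None = None
    roads_geojson: dict[str, str] = field(default_factory=dict)
    habitat_geojson: dict[str, str] = field(default_factory=dict)
    coastline_geojson: str | Path | None = None
    dem_ascii: str | Path | None = None
    regions_geojson: str | Path | None = None
    # analysis constants
    period_breaks: list[tuple[int, int]] = field(
        default_factory=lambda: [tuple(p) for p in DEFAULT_PERIOD_BREAKS]
    )
    coast_breaks_km: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0)
    elevation_breaks_m: tuple[float, ...] = (100.0, 200.0)
    density_breaks: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    n_dummy: int = 80
    conf_level: float = 0.95
    covariate_sample_mode: str = "bilinear"
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        synthetic = self.scenario is not None
        real = self.records_csv is not None
        if synthetic == real:
            raise ValueError(
                "exactly one of a synthetic scenario or a real records_csv "
                "must be supplied"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        if "period_breaks" in doc:
            doc["period_breaks"] = [tuple(p) for p in doc["period_breaks"]]
        for key in ("coast_breaks_km", "elevation_breaks_m", "density_breaks"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if isinstance(doc.get("scenario"), dict):
            doc["scenario"] = SimulationScenario(**doc["scenario"])
        return cls(**doc)


def _period_label(year: int, breaks: list[tuple[int, int]]) -> str:
    for a, b in breaks:
        if a <= year <= b:
            return f"{a}-{b}"
    return "outside"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": "synthetic" if config.scenario is not None else "real",
        "stages": {},
        "outputs": [],
    }

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    def save_json(obj, name: str) -> None:
        (outdir / name).write_text(json.dumps(obj, indent=2, default=float))
        manifest["outputs"].append(name)

    # ---- inputs ----------------------------------------------------------
    stage = "inputs"
    try:
        if config.scenario is not None:
            scenario = (
                config.scenario
                if isinstance(config.scenario, SimulationScenario)
                else SimulationScenario.from_yaml(config.scenario)
            )
            if config.seed:
                scenario.seed = config.seed
            data = generate_scenario_data(scenario)
            window = data.window
            records_raw = data.records
            roads = data.roads
            habitat = data.habitat
            coastline = data.coastline
            dem = data.elevation
            regions = data.regions
            manifest["stages"]["inputs"] = {
                "n_simulated_points": data.pattern.n,
                "n_rows": len(records_raw),
                "injected_duplicates": data.injection_log.n_duplicates_injected,
                "injected_corrupt": data.injection_log.n_corrupt_injected,
            }
        else:
            if config.window_width_km is None or config.window_height_km is None:
                raise ValueError("real-data runs must give window dimensions")
            window = StudyWindow(config.window_width_km, config.window_height_km)
            records_raw = pd.read_csv(config.records_csv, dtype={"id": str, "reporter_id": str})
            roads = {}
            for cls_name, path in config.roads_geojson.items():
                geoms, _ = read_geojson(path)
                roads[cls_name] = FeatureSet(geometries=geoms, feature_class=cls_name)
            habitat = {}
            for cls_name, path in config.habitat_geojson.items():
                geoms, _ = read_geojson(path)
                habitat[cls_name] = FeatureSet(geometries=geoms, feature_class=cls_name)
            coastline = None
            if config.coastline_geojson:
                geoms, _ = read_geojson(config.coastline_geojson)
                coastline = FeatureSet(geometries=geoms, feature_class="coastline")
            dem = Raster.from_ascii(config.dem_ascii) if config.dem_ascii else None
            regions = None
            if config.regions_geojson:
                geoms, props = read_geojson(config.regions_geojson)
                regions = FeatureSet(geometries=geoms, feature_class="region")
                regions.names = [p.get("name", f"region_{i}") for i, p in enumerate(props)]
            manifest["stages"]["inputs"] = {"n_rows": len(records_raw)}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- ingest ----------------------------------------------------------
    stage = "ingest"
    try:
        records, report = clean_pipeline(records_raw, window)
        report.to_json(outdir / "cleaning_report.json")
        manifest["outputs"].append("cleaning_report.json")
        manifest["stages"]["ingest"] = {
            "n_input": report.n_input,
            "n_excluded_coords": report.n_excluded_coords,
            "n_excluded_status": report.n_excluded_status,
            "n_excluded_duplicate": report.n_excluded_duplicate,
            "n_retained": report.n_retained,
        }
        save_csv(summarize_attributes(records), "attribute_summary.csv")
        per_year, overall = reporter_stats(records)
        save_csv(per_year, "reporter_stats_by_year.csv")
        save_json(overall, "reporter_stats_overall.json")
        save_csv(
            records.drop(columns=["coord_valid", "date_valid"], errors="ignore"),
            "records_clean.csv",
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    pattern = PointPattern(records["x"].to_numpy(), records["y"].to_numpy(), window)
    years = pd.to_datetime(records["date"].astype(str)).dt.year
    period_of_row = years.map(lambda y: _period_label(int(y), config.period_breaks))

    # ---- temporal --------------------------------------------------------
    stage = "temporal"
    try:
        series = monthly_counts(records)
        save_csv(period_aggregate(records, config.period_breaks), "period_month_counts.csv")
        if len(series) >= 24:
            decomp = decompose_additive(series)
            save_csv(decomp.to_frame(), "decomposition.csv")
            manifest["stages"]["temporal"] = {
                "n_months": len(series),
                "seasonal_peak_month": int(np.argmax(decomp.seasonal_effects) + 1),
            }
        else:
            save_csv(series.to_frame(), "monthly_counts.csv")
            manifest["stages"]["temporal"] = {"n_months": len(series), "decomposed": False}
    except Exception as exc:
        raise PipelineError(stage, exc, report) from exc

    # ---- spatial summaries ----------------------------------------------
    stage = "spatial_summaries"
    try:
        summaries = {}
        if coastline is not None and len(coastline):
            bands = coast_distance_bands(pattern, coastline, config.coast_breaks_km)
            save_csv(bands.to_frame(), "coast_distance_bands.csv")
            summaries["coast_within_20km_share"] = float(
                bands.counts[:-1].sum() / bands.n
            ) if bands.n else np.nan
        if dem is not None:
            elev = elevation_classes(pattern, dem, config.elevation_breaks_m)
            save_csv(elev.to_frame(), "elevation_classes.csv")
        if regions is not None and len(regions):
            region_names = getattr(regions, "names", [f"region_{i}" for i in range(len(regions))])
            save_csv(
                polygon_tabulate(pattern, regions, region_names),
                "region_counts.csv",
            )
        if habitat:
            geoms, levels = [], []
            for cls_name, fs in habitat.items():
                geoms.extend(fs.geometries)
                levels.extend([cls_name] * len(fs))
            save_csv(
                polygon_tabulate(pattern, geoms, levels, periods=period_of_row),
                "habitat_counts_by_period.csv",
            )
        manifest["stages"]["spatial_summaries"] = summaries
    except Exception as exc:
        raise PipelineError(stage, exc, report) from exc

    # ---- density ---------------------------------------------------------
    stage = "density"
    try:
        dens_stats = {}
        class_frames = []
        for a, b in config.period_breaks:
            label = f"{a}-{b}"
            sel = (period_of_row == label).to_numpy()
            sub = pattern.subset(sel)
            if sub.n < 2:
                continue
            grid = kde_gaussian(sub, window, period_label=label)
            grid.to_ascii(outdir / f"density_{label}.asc")
            manifest["outputs"].append(f"density_{label}.asc")
            cls = classify_density(grid, config.density_breaks, period_label=label)
            class_frames.append(cls.to_frame())
            dens_stats[label] = {
                "n": sub.n,
                "bandwidth_km": list(scott_bandwidth(sub)),
                "max_density": cls.density_range[1],
            }
        if class_frames:
            save_csv(pd.concat(class_frames, ignore_index=True), "density_classification.csv")
        manifest["stages"]["density"] = dens_stats
    except Exception as exc:
        raise PipelineError(stage, exc, report) from exc

    # ---- covariates ------------------------------------------------------
    stage = "covariates"
    try:
        covariate_rasters: dict[str, Raster] = {}
        for cls_name, fs in {**roads, **habitat}.items():
            if len(fs) == 0:
                continue
            rast = distance_raster(fs, window)
            rast.feature_class = cls_name
            covariate_rasters[cls_name] = rast
            rast.to_ascii(outdir / f"dist_{cls_name}.asc")
            manifest["outputs"].append(f"dist_{cls_name}.asc")
        manifest["stages"]["covariates"] = {"classes": sorted(covariate_rasters)}
    except Exception as exc:
        raise PipelineError(stage, exc, report) from exc

    # ---- point-process inference ----------------------------------------
    stage = "ppp_inference"
    try:
        inference: dict[str, dict] = {}
        rho_frames = []
        for cls_name, rast in covariate_rasters.items():
            entry: dict = {}
            bt = berman_test(pattern, rast, window, sample_mode=config.covariate_sample_mode)
            entry["berman_z1"] = bt.statistic_z1
            entry["berman_p"] = bt.p_value
            roc = roc_auc(pattern, rast, window, sample_mode=config.covariate_sample_mode)
            entry["auc"] = roc.auc
            if pattern.n >= 20:
                rho = rhohat(pattern, rast, window, sample_mode=config.covariate_sample_mode)
                rf = rho.to_frame()
                rf.insert(0, "covariate", cls_name)
                rho_frames.append(rf)
            fit = fit_loglinear_ppm(
                pattern, rast, window,
                n_dummy=config.n_dummy, sample_mode=config.covariate_sample_mode,
            )
            mult, pct = intensity_multiplier(fit)
            entry.update(
                {
                    "alpha": fit.intercept_alpha,
                    "beta_per_km": fit.beta,
                    "se_beta": float(fit.se_beta[0]),
                    "multiplier_per_km": mult,
                    "percent_decrease_per_km": pct,
                    "model_auc": fit.auc,
                }
            )
            inference[cls_name] = entry
        save_json(inference, "inference.json")
        if rho_frames:
            save_csv(pd.concat(rho_frames, ignore_index=True), "rhohat_curves.csv")
        manifest["stages"]["ppp_inference"] = {"n_covariates": len(inference)}
        if config.make_plots and rho_frames:
            _plot_rhohat(pd.concat(rho_frames), inference, outdir)
            manifest["outputs"].append("rhohat_panels.png")
    except Exception as exc:
        raise PipelineError(stage, exc, report) from exc

    manifest["n_retained"] = int(report.n_retained)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def _plot_rhohat(rho_df: pd.DataFrame, inference: dict, outdir: Path) -> None:
    """Panel per covariate: rho(z) with bands, parametric fit overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = list(dict.fromkeys(rho_df["covariate"]))
    ncol = 3
    nrow = int(np.ceil(len(classes) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, cls_name in zip(axes.ravel(), classes):
        sub = rho_df[rho_df["covariate"] == cls_name]
        ax.fill_between(sub["z"], sub["lo"], sub["hi"], color="0.8")
        ax.plot(sub["z"], sub["rho"], "k-", lw=1)
        info = inference.get(cls_name, {})
        if "alpha" in info:
            lam = np.exp(info["alpha"] + info["beta_per_km"] * sub["z"])
            ax.plot(sub["z"], lam, "r-", lw=1)
        ax.set_title(cls_name, fontsize=9)
        ax.set_xlabel("distance (km)")
        ax.set_ylabel(r"$\hat\rho$ (per km$^2$)")
    for ax in axes.ravel()[len(classes):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(outdir / "rhohat_panels.png", dpi=120)
    plt.close(fig)
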