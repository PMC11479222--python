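"""End-to-end pipeline: config, stage orchestration, output bundle.

``run_pipeline`` executes the full analysis — composites, mean surface,
focal CV, trends, dual-significance classification, proportion tables,
driver trend summaries, correlation summaries, stratified samples,
random-forest importances and climate/human aggregate shares — from a
single validated config, writing every intermediate surface and table
plus a run manifest into the output directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, metrics, raster_io, synthetic, trends, attribution
from .containers import AnnualStack, DRIVER_NAMES, RasterGrid

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated knobs of the full analysis (defaults follow the method:
    3x3 window, alpha 0.05, NDVI threshold 0.2, 10,000-sample cap)."""

    output_dir: str = "vegdyn_output"
    input_dir: str | None = None  # a written scene; None -> simulate
    synthetic_noise_sd: float = 0.02
    synthetic_grid_size: int = 120
    years: list[int] = field(default_factory=lambda: list(range(2000, 2023)))
    months: list[int] = field(default_factory=lambda: [5, 6, 7, 8, 9])
    min_valid_months: int = 3
    window: int = 3
    alpha: float = 0.05
    ndvi_threshold: float = 0.2
    min_valid_years: int = 15
    buffer_distance: float = 250.0
    excluded_landcover: list[str] = field(
        default_factory=lambda: list(("water", "impervious", "wetland", "glacier"))
    )
    epsilon: dict = field(default_factory=dict)
    sample_cap: int = 10000
    tree_grid: list[int] = field(default_factory=lambda: list(attribution.DEFAULT_TREE_GRID))
    cv_folds: int = 5
    cv_order: str = "annual"  # or "monthly"
    sample_unit: str = "pixel_year"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.sample_cap < 1:
            raise ValueError("sample_cap must be >= 1")
        if self.buffer_distance < 0:
            raise ValueError("buffer_distance must be >= 0")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        if len(self.years) < 3:
            raise ValueError("need at least 3 years")
        if self.cv_order not in ("annual", "monthly"):
            raise ValueError("cv_order must be 'annual' or 'monthly'")


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def _load_scene(cfg: PipelineConfig) -> synthetic.SyntheticScene:
    if cfg.input_dir is None:
        n = cfg.synthetic_grid_size
        grid = RasterGrid(n_rows=n, n_cols=n)
        specs = synthetic.demo_scene_specs(cfg.synthetic_noise_sd, grid_size=n)
        return synthetic.build_scene(specs, grid, cfg.years, seed=cfg.seed)
    d = Path(cfg.input_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    grid = RasterGrid.from_dict(manifest["grid"])
    stack = raster_io.read_stack(d / "ndvi_monthly.tif", expected_grid=grid)
    variables = {}
    for name in DRIVER_NAMES:
        vals, _, index = raster_io.read_raster(d / f"driver_{name}.tif", expected_grid=grid)
        variables[name] = vals
    drivers = synthetic.DriverStack(grid, manifest["years"], variables)
    grass, _, _ = raster_io.read_raster(d / "grassland_type.tif", expected_grid=grid)
    landcover, _, _ = raster_io.read_raster(d / "landcover.tif", expected_grid=grid)
    truth, _, _ = raster_io.read_raster(d / "truth.tif", expected_grid=grid)
    lines = raster_io.read_lines_geojson(d / "lines.geojson")
    specs = [synthetic.ScenarioSpec(**{**s, "block": tuple(s["block"])})
             for s in manifest["specs"]]
    return synthetic.SyntheticScene(
        monthly_ndvi=stack, drivers=drivers,
        grassland_type=np.asarray(grass[0], dtype=np.int16),
        landcover=np.asarray(landcover[0], dtype=np.int16),
        lines=lines, truth=np.asarray(truth[0], dtype=np.int16),
        seed=manifest["seed"], specs=specs,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the in-memory result bundle."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    t0 = time.time()
    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        logger.info("stage %-16s t=%.1fs", name, time.time() - t0)

    try:
        stage("scene")
        scene = _load_scene(cfg)
        grid = scene.grid
        results["scene"] = scene

        stage("masks")
        mask = raster_io.build_mask_set(
            scene.landcover, cfg.excluded_landcover, scene.lines,
            cfg.buffer_distance, grid,
        )
        logger.info(
            "masking: %d landcover, %d buffer, %d combined of %d pixels",
            mask.landcover_mask.sum(), mask.buffer_mask.sum(),
            mask.combined.sum(), mask.combined.size,
        )
        results["mask"] = mask

        stage("composite")
        composite = metrics.growing_season_median(
            scene.monthly_ndvi, tuple(cfg.months), cfg.min_valid_months
        )
        raster_io.write_stack(composite, out / "ndvi_annual.tif")
        mean_ndvi = metrics.period_mean(composite, cfg.min_valid_years)
        raster_io.write_raster(out / "ndvi_mean.tif", mean_ndvi, grid)
        results["composite"], results["mean_ndvi"] = composite, mean_ndvi

        stage("heterogeneity")
        if cfg.cv_order == "annual":
            cv = metrics.focal_cv(composite, cfg.window, mask)
        else:
            cv = metrics.focal_cv_monthly(
                scene.monthly_ndvi, cfg.window, mask,
                tuple(cfg.months), cfg.min_valid_months,
            )
        raster_io.write_stack(cv, out / "cv_annual.tif")
        results["cv"] = cv

        stage("trends")
        ndvi_trend = trends.fit_linear_trend(composite, cfg.min_valid_years, "NDVI")
        cv_trend = trends.fit_linear_trend(cv, cfg.min_valid_years, "CV")
        for ts, tag in ((ndvi_trend, "ndvi"), (cv_trend, "cv")):
            raster_io.write_raster(out / f"trend_{tag}_slope.tif", ts.slope, grid)
            raster_io.write_raster(out / f"trend_{tag}_p.tif", ts.p_value, grid)
            # single-variable significance map: -1/0/+1 for sig down/none/sig up
            sig = np.where(
                np.isnan(ts.slope), synthetic.NODATA_CODE,
                np.sign(ts.slope) * (ts.p_value < cfg.alpha),
            ).astype(np.int16)
            raster_io.write_raster(out / f"significance_{tag}.tif", sig, grid, dtype=np.int16)
        results["ndvi_trend"], results["cv_trend"] = ndvi_trend, cv_trend

        stage("classify")
        classes = trends.classify_change(
            ndvi_trend, cv_trend, mean_ndvi, cfg.alpha, cfg.ndvi_threshold
        )
        raster_io.write_raster(out / "change_classes.tif", classes, grid, dtype=np.int16)
        n_sig = int(np.sum((classes >= 1) & (classes <= 6)))
        logger.info("dual-significant pixels: %d of %d valid", n_sig, int(np.sum(classes >= 0)))
        proportions = trends.summarize_proportions(classes, scene.grassland_type, grid.pixel_size)
        proportions.to_csv(out / "class_proportions.csv", index=False)
        results["classes"], results["proportions"] = classes, proportions

        stage("driver_trends")
        driver_trends = [
            trends.fit_linear_trend(scene.drivers.as_annual_stack(name),
                                    min(cfg.min_valid_years, len(cfg.years)), name)
            for name in DRIVER_NAMES
        ]
        driver_summary = trends.driver_trend_summary(driver_trends, cfg.epsilon, cfg.alpha)
        driver_summary.to_csv(out / "driver_trend_summary.csv", index=False)
        results["driver_summary"] = driver_summary

        stage("correlations")
        corr = {}
        for resp_name, resp in (("NDVI", composite), ("CV", cv)):
            for name in DRIVER_NAMES:
                corr[(resp_name, name)] = attribution.pixelwise_pearson(
                    resp, scene.drivers.as_annual_stack(name)
                )
        corr_summary = attribution.summarize_correlations(corr, cfg.alpha)
        corr_summary.to_csv(out / "correlation_summary.csv", index=False)
        results["correlations"], results["corr_summary"] = corr, corr_summary

        stage("samples")
        samples = attribution.extract_strata_samples(
            classes, scene.grassland_type, composite, cv, scene.drivers,
            cfg.sample_cap, cfg.seed, cfg.sample_unit,
        )
        samples.to_csv(out / "strata_samples.csv", index=False)
        results["samples"] = samples

        stage("importance")
        imp_frames = []
        for resp in ("NDVI", "CV"):
            imp = attribution.fit_importance(
                samples, resp, tuple(cfg.tree_grid), cfg.cv_folds, cfg.seed
            )
            imp_frames.append(imp)
        imp_frames = [f for f in imp_frames if not f.empty]
        importance = pd.concat(imp_frames, ignore_index=True) if imp_frames else pd.DataFrame()
        importance.to_csv(out / "importance.csv", index=False)
        shares = attribution.aggregate_contributions(importance)
        shares.to_csv(out / "climate_human_shares.csv", index=False)
        results["importance"], results["shares"] = importance, shares

        stage("manifest")
        manifest = {
            "config": asdict(cfg),
            "software": {"vegdyn": __version__, "numpy": np.__version__},
            "runtime_s": round(time.time() - t0, 2),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {err}") from err
    return results
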