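"""End-to-end orchestration: simulate → reconstruct → trends → validate.

`run_all` drives the whole pipeline on a synthetic world (or one supplied
by the caller), writes every artifact to ``outdir`` and returns both the
paths and the in-memory results. Identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import RunConfig, write_manifest
from .grid import (AGB_UNITS, RasterField, aggregate_total,
                   area_weighted_mean, write_stack)
from .pipeline import (deficit_arithmetic, deficit_map, deficit_series,
                       run_ensemble)
from .synthetic import SyntheticWorld, generate_world, write_world
from .trends import (CorrelationResult, IndexSeries, annual_delta, correlate,
                     detrend, linear_trend, pixelwise_temporal_correlation,
                     spatial_correlation, zscore)
from .validation import compare_deficit_to_lulcc, holdout_validate


def _cr(c: CorrelationResult) -> dict:
    return {"r": c.r, "n": c.n, "p": c.p, "degenerate": c.degenerate}


def totals_series(stack: np.ndarray, years, grid, mask,
                  kind: str) -> IndexSeries:
    vals = [aggregate_total(RasterField(grid, stack[k], AGB_UNITS), mask)
            for k in range(len(years))]
    return IndexSeries(list(years), np.asarray(vals), kind=kind)


def trend_report(config: RunConfig, world: SyntheticWorld, runs, table) -> dict:
    """Segment trends, deficit arithmetic, spatial/temporal correlation and
    ENSO statistics for one completed reconstruction."""
    grid = world.grid
    years = world.years
    first, last = years[0], years[-1]
    # keep both trend segments inside the run and at least 3 years long
    seg_end = int(np.clip(config.trend_segment_end, first + 2, last - 2))
    dist = world.masks.disturbed

    frac = deficit_series(table, "mean", "deficit_fraction")
    obs = deficit_series(table, "mean", "agb_obs_pg")
    pot = deficit_series(table, "mean", "agb_pot_pg")
    deficit = deficit_series(table, "mean", "agb_def_pg")

    def _seg(series, lo, hi):
        slope, intercept, corr = linear_trend(series, (lo, hi))
        return {"slope": slope, "intercept": intercept, **_cr(corr)}

    report: dict = {
        "deficit_fraction_trend_early": _seg(frac, first, seg_end),
        "deficit_fraction_trend_late": _seg(frac, seg_end, last),
        "obs_loss_rate_early_pg_per_yr":
            -_seg(obs, first, seg_end)["slope"],
        "obs_loss_rate_late_pg_per_yr":
            -_seg(obs, seg_end, last)["slope"],
        "arithmetic": deficit_arithmetic(
            obs.values[0], obs.values[-1], pot.values[0], pot.values[-1],
            first, last, config.assumed_start_year),
    }

    # spatial correlation of the first- and last-year deficit maps
    mean_run = runs["mean"]
    d_first = deficit_map(
        RasterField(grid, mean_run.pot_maps[0], AGB_UNITS),
        world.agb_obs.field("mean", first))
    d_last = deficit_map(
        RasterField(grid, mean_run.pot_maps[-1], AGB_UNITS),
        world.agb_obs.field("mean", last))
    report["deficit_spatial_correlation"] = _cr(
        spatial_correlation(d_first, d_last, dist))

    # per-pixel temporal correlation: primary fraction vs deficit
    def_stack = mean_run.pot_maps - world.agb_obs.maps["mean"]
    r_map, p_map, sig = pixelwise_temporal_correlation(
        world.primary_fraction, def_stack, dist, grid)
    n_valid = int(np.isfinite(r_map.values).sum())
    report["primary_vs_deficit_pixels"] = {
        "n_valid": n_valid,
        "n_significant": int(sig.sum()),
        "median_r": (float(np.nanmedian(r_map.values))
                     if n_valid else float("nan")),
    }

    # ENSO: MEI_w against detrended annual increments of pot and obs totals
    enso = {
        "mei_w_vs_detrended_delta_pot": _cr(
            correlate(world.mei_w, detrend(annual_delta(pot)))),
        "mei_w_vs_detrended_delta_obs": _cr(
            correlate(world.mei_w, detrend(annual_delta(obs)))),
    }
    # stress factor vs intact-forest AGB stocks
    ifl_obs = totals_series(world.agb_obs.maps["mean"], years, grid,
                            world.masks.ifl, "ifl_obs_pg")
    enso["stress_vs_ifl_agb"] = _cr(correlate(world.stress_s,
                                              zscore(ifl_obs)))
    report["enso"] = enso
    report["pixelwise_maps"] = {"r": r_map, "p": p_map, "significant": sig}
    report["deficit_maps"] = {"first": d_first, "last": d_last}
    return report


def run_all(config: RunConfig, outdir, world: SyntheticWorld | None = None
            ) -> dict:
    """Execute simulate → train/predict/deficit → trends → validate.

    Returns ``{"paths": ..., "world": ..., "runs": ..., "table": ...,
    "trends": ..., "validation": ...}``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if world is None:
        world = generate_world(config.world_config())
    paths = write_world(world, outdir)

    params = config.forest_params()
    runs, table = run_ensemble(world.agb_obs, world.climatology, world.masks,
                               params, config.seed, config.levels)
    table_path = outdir / "deficit_table.csv"
    table.to_csv(table_path, index=False, float_format="%.10g")
    paths["deficit_table.csv"] = str(table_path)
    for level, run in runs.items():
        p = outdir / f"agb_pot_{level}.nc"
        write_stack(run.pot_maps, "year", run.years, world.grid, p,
                    "agb_pot", AGB_UNITS)
        paths[p.name] = str(p)
        d = outdir / f"agb_def_{level}.nc"
        write_stack(run.pot_maps - world.agb_obs.maps[level], "year",
                    run.years, world.grid, d, "agb_def", AGB_UNITS)
        paths[d.name] = str(d)

    trends = trend_report(config, world, runs, table)
    serializable = {k: v for k, v in trends.items()
                    if k not in ("pixelwise_maps", "deficit_maps")}
    tr_path = outdir / "trend_report.json"
    tr_path.write_text(json.dumps(serializable, indent=2, sort_keys=True))
    paths["trend_report.json"] = str(tr_path)
    r_path = outdir / "primary_deficit_correlation.nc"
    write_stack(np.stack([trends["pixelwise_maps"]["r"].values,
                          trends["pixelwise_maps"]["p"].values]),
                "layer", np.array([0, 1]), world.grid, r_path, "r_p", "1")
    paths[r_path.name] = str(r_path)

    vrep = holdout_validate(world.agb_obs, world.climatology, world.masks,
                            params, config.seed)
    pf_total = IndexSeries(
        world.years,
        np.asarray([area_weighted_mean(
            RasterField(world.grid, world.primary_fraction[k], "1"),
            world.masks.disturbed) for k in range(len(world.years))]),
        kind="primary_fraction_total")
    lulcc = compare_deficit_to_lulcc(deficit_series(table),
                                     world.deforestation_rate, pf_total)
    val_doc = {
        "pooled_integrated_bias_pct": vrep.pooled_integrated_bias_pct,
        "integrated_bias_pct": {str(k): v
                                for k, v in vrep.integrated_bias_pct.items()},
        "local_mean_relative_bias_pct": vrep.local_mean_relative_bias_pct,
        "lulcc": {k: _cr(v) for k, v in lulcc.items()},
    }
    val_path = outdir / "validation_report.json"
    val_path.write_text(json.dumps(val_doc, indent=2, sort_keys=True))
    paths["validation_report.json"] = str(val_path)
    res_path = outdir / "validation_residuals.nc"
    write_stack(vrep.residuals, "year", world.years, world.grid, res_path,
                "residual", AGB_UNITS)
    paths[res_path.name] = str(res_path)

    manifest = write_manifest(outdir, config, paths.values())
    paths["manifest.json"] = str(manifest)
    return {"paths": paths, "world": world, "runs": runs, "table": table,
            "trends": trends, "validation": vrep, "lulcc": lulcc}
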