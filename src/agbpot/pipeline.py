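"""Per-year potential-biomass reconstruction and deficit accounting.

For every year (and every observation quantile level) a fresh model-tree
ensemble is trained on intact-forest (IFL) pixels — features are the 12
monthly layers of each climatology variable, latitude, and the open-water
flag; the target is that year's observed AGB. The fitted model predicts the
counterfactual potential AGB on disturbed (basin-minus-IFL) pixels, the
space-for-time substitution at the heart of the method. Inside IFL the
potential is, by definition, the observation itself; the deficit
AGB_def = AGB_pot − AGB_obs is therefore identically zero there and all
basin totals are restricted to the disturbed region.

The per-year retraining is what lets the potential vary interannually even
though the climatology is static: the annual signal enters through the IFL
training targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .forest import ForestParams, ModelTreeForest, TrainingTable, fit_forest, predict
from .grid import (AGB_UNITS, AnnualEnsembleSeries, GridSpec, MaskSet,
                   RasterField, aggregate_total)
from .trends import IndexSeries

DEFICIT_COLUMNS = ("year", "level", "agb_obs_pg", "agb_pot_pg", "agb_def_pg",
                   "deficit_fraction")


def feature_names(climate_vars) -> list[str]:
    names = [f"{var}_m{m:02d}" for var in climate_vars
             for m in range(1, 13)]
    names.append("latitude")
    return names


def feature_matrix(climatology: dict[str, np.ndarray], grid: GridSpec,
                   select: np.ndarray):
    """Feature rows for the pixels under ``select`` with complete data.

    Returns ``(X, row_id, keep)`` where ``keep`` is the boolean 2-D mask of
    pixels actually retained (rows with any missing feature are dropped).
    """
    select = np.asarray(select, dtype=bool)
    layers = [stack[m] for stack in climatology.values() for m in range(12)]
    layers.append(grid.lat_grid())
    cube = np.stack(layers, axis=-1)            # (n_lat, n_lon, p)
    complete = np.isfinite(cube).all(axis=-1)
    keep = select & complete
    flat_idx = np.flatnonzero(keep.ravel())
    X = cube.reshape(-1, cube.shape[-1])[flat_idx]
    return X, flat_idx, keep


def build_training_table(agb: RasterField, climatology: dict[str, np.ndarray],
                         masks: MaskSet, train_mask: np.ndarray | None = None
                         ) -> TrainingTable:
    """Training rows from the intact pixels (or an explicit train mask)."""
    if train_mask is None:
        train_mask = masks.ifl
    target_ok = np.isfinite(agb.values)
    X, row_id, keep = feature_matrix(climatology, agb.grid,
                                     np.asarray(train_mask, bool) & target_ok)
    y = agb.values.ravel()[row_id]
    water = masks.water.ravel()[row_id]
    return TrainingTable(X, water, y, row_id,
                         feature_names(climatology.keys()))


@dataclass
class PotentialRun:
    level: str
    years: list[int]
    pot_maps: np.ndarray                  # (n_years, n_lat, n_lon)
    forests: list[ModelTreeForest]
    seed: int


def run_year(agb: RasterField, climatology: dict[str, np.ndarray],
             masks: MaskSet, params: ForestParams, seed: int,
             train_mask: np.ndarray | None = None,
             predict_mask: np.ndarray | None = None,
             keep_forest: bool = True):
    """Train on intact pixels, predict potential AGB on disturbed pixels.

    Returns ``(forest, pot_field)``. The potential map equals the
    observation inside IFL, the model prediction on disturbed pixels with
    complete climatology, and is missing elsewhere.
    """
    table = build_training_table(agb, climatology, masks, train_mask)
    min_rows = 2 * (table.n_features + 1)
    if table.n_rows < min_rows:
        raise ConfigurationError(
            f"only {table.n_rows} usable training rows (< {min_rows})")
    forest = fit_forest(table, params, seed)

    if predict_mask is None:
        predict_mask = masks.disturbed
    Xp, flat_idx, keep = feature_matrix(climatology, agb.grid, predict_mask)
    pred = predict(forest, Xp, masks.water.ravel()[flat_idx])

    pot = np.full(agb.grid.shape, np.nan)
    pot.ravel()[flat_idx] = pred
    if train_mask is None:
        # intact pixels are at potential by definition
        pot[masks.ifl] = agb.values[masks.ifl]
    return (forest if keep_forest else None), RasterField(agb.grid, pot,
                                                          AGB_UNITS)


def run_ensemble(series: AnnualEnsembleSeries,
                 climatology: dict[str, np.ndarray], masks: MaskSet,
                 params: ForestParams, seed: int,
                 levels=("q05", "mean", "q95"),
                 keep_forests: bool = False):
    """Full pipeline per quantile level, sharing one master seed.

    Returns ``(runs, deficit_table)`` where ``runs`` maps level →
    :class:`PotentialRun` and the deficit table has one row per
    (year, level) with Pg C totals over the disturbed region.
    """
    for level in levels:
        if level not in series.maps:
            raise ConfigurationError(f"level {level!r} missing from series")
    runs: dict[str, PotentialRun] = {}
    rows = []
    dist = masks.disturbed
    for level in levels:
        pot_maps = np.full((len(series.years), *series.grid.shape), np.nan)
        forests = []
        for k, year in enumerate(series.years):
            agb = series.field(level, year)
            forest, pot = run_year(agb, climatology, masks, params, seed,
                                   keep_forest=keep_forests)
            pot_maps[k] = pot.values
            if keep_forests:
                forests.append(forest)
            obs_pg = aggregate_total(agb, dist)
            pot_pg = aggregate_total(pot, dist)
            def_pg = pot_pg - obs_pg
            rows.append({"year": year, "level": level,
                         "agb_obs_pg": obs_pg, "agb_pot_pg": pot_pg,
                         "agb_def_pg": def_pg,
                         "deficit_fraction": (def_pg / pot_pg
                                              if pot_pg > 0 else np.nan)})
        runs[level] = PotentialRun(level, list(series.years), pot_maps,
                                   forests, seed)
    return runs, pd.DataFrame(rows, columns=list(DEFICIT_COLUMNS))


def deficit_map(pot: RasterField, obs: RasterField) -> RasterField:
    """AGB_def = AGB_pot − AGB_obs, pixel-wise; negative values mean a
    recovery beyond the modelled potential and are deliberately kept."""
    if pot.grid != obs.grid:
        raise DomainError("maps on different grids")
    return RasterField(pot.grid, pot.values - obs.values, AGB_UNITS)


def deficit_series(table: pd.DataFrame, level: str = "mean",
                   column: str = "agb_def_pg") -> IndexSeries:
    sub = table[table["level"] == level].sort_values("year")
    return IndexSeries(list(sub["year"].astype(int)),
                       sub[column].to_numpy(float), kind=column)


def deficit_arithmetic(obs_first: float, obs_last: float, pot_first: float,
                       pot_last: float, first_year: int, last_year: int,
                       assumed_start_year: int = 1960) -> dict[str, float]:
    """Scalar bookkeeping from period-endpoint basin totals (Pg C).

    Computes the observed loss, the change in potential, the deficits at
    both endpoints, the deficit increase, the mean deficit growth rate over
    the period, and the implied pre-period rate assuming the deficit
    accumulated linearly from ``assumed_start_year``.
    """
    if last_year <= first_year:
        raise DomainError("zero-length period")
    if first_year <= assumed_start_year:
        raise DomainError("assumed start year must precede the first year")
    for v in (obs_first, obs_last, pot_first, pot_last):
        if not np.isfinite(v):
            raise DomainError("totals must be finite")
    deficit_first = pot_first - obs_first
    deficit_last = pot_last - obs_last
    deficit_change = deficit_last - deficit_first
    return {
        "obs_loss_pg": obs_first - obs_last,
        "pot_reduction_pg": pot_first - pot_last,
        "deficit_first_pg": deficit_first,
        "deficit_last_pg": deficit_last,
        "deficit_change_pg": deficit_change,
        "mean_rate_pg_per_yr": deficit_change / (last_year - first_year),
        "pre_period_rate_pg_per_yr":
            deficit_first / (first_year - assumed_start_year),
    }
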