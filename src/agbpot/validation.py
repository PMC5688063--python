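"""Out-of-sample validation of the reconstruction and land-use comparisons.

The reconstruction cannot be validated against field data, so two indirect
checks are used: (1) a holdout experiment — train on ~50% of randomly
selected intact pixels, predict the rest, and summarize the integrated
(area-weighted total) and local (per-pixel relative) biases; (2) agreement
of the deficit dynamics with independent land-use series — annual
deforestation rates should track the annual deficit increments, and the
total primary-land fraction should move opposite to the deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .forest import ForestParams
from .grid import (AGB_UNITS, AnnualEnsembleSeries, MaskSet, RasterField,
                   aggregate_total)
from .pipeline import run_year
from .trends import CorrelationResult, IndexSeries, annual_delta, correlate

#: observed-AGB floor (Mg C ha⁻¹) below which pixels are excluded from the
#: local relative-bias average, to keep near-zero denominators out
RELATIVE_BIAS_FLOOR = 10.0


def split_ifl(masks: MaskSet, fraction: float = 0.5, seed: int = 0,
              min_train_rows: int = 2):
    """Random partition of the IFL pixels into train and holdout masks."""
    idx = np.flatnonzero(masks.ifl.ravel())
    if idx.size < 2 * min_train_rows:
        raise ConfigurationError(
            f"{idx.size} IFL pixels is too few to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51F7]))
    perm = rng.permutation(idx.size)
    n_train = int(round(fraction * idx.size))
    train = np.zeros(masks.grid.shape, dtype=bool).ravel()
    hold = train.copy()
    train[idx[perm[:n_train]]] = True
    hold[idx[perm[n_train:]]] = True
    return train.reshape(masks.grid.shape), hold.reshape(masks.grid.shape)


@dataclass
class ValidationReport:
    years: list[int]
    integrated_bias_pct: dict[int, float]
    pooled_integrated_bias_pct: float
    local_mean_relative_bias_pct: float
    residuals: np.ndarray          # (n_years, n_lat, n_lon), pred − obs
    split_seed: int
    fraction: float

    def recompute_integrated_bias(self, obs_stack: np.ndarray,
                                  masks: MaskSet, hold: np.ndarray) -> float:
        """Pooled integrated bias recomputed from the stored residuals —
        must match ``pooled_integrated_bias_pct`` exactly."""
        grid = masks.grid
        num = den = 0.0
        for k in range(len(self.years)):
            pred = RasterField(grid, obs_stack[k] + self.residuals[k],
                               AGB_UNITS)
            obs = RasterField(grid, obs_stack[k], AGB_UNITS)
            num += aggregate_total(pred, hold)
            den += aggregate_total(obs, hold)
        return 100.0 * (num - den) / den


def holdout_validate(series: AnnualEnsembleSeries,
                     climatology: dict[str, np.ndarray], masks: MaskSet,
                     params: ForestParams, seed: int,
                     fraction: float = 0.5, level: str = "mean"
                     ) -> ValidationReport:
    """Train on a random half of IFL, predict the other half, every year."""
    train, hold = split_ifl(masks, fraction, seed)
    grid = series.grid
    years = series.years
    residuals = np.full((len(years), *grid.shape), np.nan)
    bias_by_year: dict[int, float] = {}
    tot_pred = tot_obs = 0.0
    rel_sum = 0.0
    rel_n = 0
    for k, year in enumerate(years):
        agb = series.field(level, year)
        _, pot = run_year(agb, climatology, masks, params, seed,
                          train_mask=train, predict_mask=hold,
                          keep_forest=False)
        sel = hold & np.isfinite(pot.values) & np.isfinite(agb.values)
        res = np.full(grid.shape, np.nan)
        res[sel] = pot.values[sel] - agb.values[sel]
        residuals[k] = res
        pred_pg = aggregate_total(pot, sel)
        obs_pg = aggregate_total(agb, sel)
        bias_by_year[year] = 100.0 * (pred_pg - obs_pg) / obs_pg
        tot_pred += pred_pg
        tot_obs += obs_pg
        loc = sel & (agb.values >= RELATIVE_BIAS_FLOOR)
        rel_sum += float(np.sum((pot.values[loc] - agb.values[loc])
                                / agb.values[loc]))
        rel_n += int(loc.sum())
    return ValidationReport(
        years=list(years),
        integrated_bias_pct=bias_by_year,
        pooled_integrated_bias_pct=100.0 * (tot_pred - tot_obs) / tot_obs,
        local_mean_relative_bias_pct=100.0 * rel_sum / max(rel_n, 1),
        residuals=residuals,
        split_seed=seed,
        fraction=fraction,
    )


def compare_deficit_to_lulcc(deficit: IndexSeries,
                             deforestation_rate: IndexSeries | None = None,
                             primary_fraction_total: IndexSeries | None = None
                             ) -> dict[str, CorrelationResult]:
    """Correlate deficit dynamics with independent land-use series.

    Annual deficit increments vs the clearing-rate series (expected
    positive under clearing-driven loss), and deficit totals vs the total
    primary-land fraction (expected negative).
    """
    out: dict[str, CorrelationResult] = {}
    if deforestation_rate is not None:
        out["delta_deficit_vs_rate"] = correlate(annual_delta(deficit),
                                                 deforestation_rate)
    if primary_fraction_total is not None:
        out["deficit_vs_primary_fraction"] = correlate(
            deficit, primary_fraction_total)
    return out
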