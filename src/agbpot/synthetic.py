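"""Synthetic gridded worlds with the statistical structure the analysis assumes.

The generator emulates the inputs of the basin-scale biomass analysis:

* a static monthly climatology (precipitation, mean temperature, diurnal
  temperature range) as smooth spatially-correlated random surfaces with a
  seasonal cycle — static across years, as a long-term climatology is;
* a *true* potential-biomass surface f(climatology, latitude) with a
  saturating (tanh) precipitation response, so a single global linear model
  cannot fit it but a model-tree ensemble can;
* interannual variation of the potential entering only through spatially
  uniform annual anomalies: an ENSO-coupled term (``enso_coupling`` ×
  winter-composite MEI) plus Gaussian climate noise;
* a disturbed region outside intact-forest landscapes (IFL) with spatially
  clustered Bernoulli clearing (an "arc of deforestation"), an initial
  biomass deficit, and exponential regrowth toward the potential;
* observed AGB = clean AGB + pixel noise, published at three quantile
  levels (q05/mean/q95) with a symmetric relative spread;
* companion series: bimonthly AR(1) ENSO index, a vegetation-stress z-score
  anti-correlated with it, an annual deforestation biomass-loss rate, and
  per-year primary-land-fraction maps that decline where clearing occurs.

Pixels flagged as large open water keep their first-year observation for
every year, mirroring how passive-microwave retrievals are held constant
over open water. All randomness flows from one seeded generator; ground
truth (true potential, clean observations, injected coupling) is retained
on the world object so recovery tests can score the pipeline against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError
from .grid import (AGB_UNITS, AnnualEnsembleSeries, GridSpec, MaskSet,
                   RasterField, aggregate_total, write_ensemble,
                   write_mask_set, write_stack)
from .trends import (IndexSeries, BIMONTHS, annual_delta, bimonth_label,
                     correlate, detrend, linear_trend,
                     winter_composite_series, zscore)

DEFAULT_GRID = GridSpec(-15.0, -5.0, -70.0, -60.0, 0.25)


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world; defaults mirror the real
    domain: a 0.25° grid, years 1993–2012, ~55% of the basin intact, an
    initial deficit of ~18% of potential, and ±8% observation spread."""

    grid: GridSpec = dc_field(default_factory=lambda: DEFAULT_GRID)
    year_start: int = 1993
    year_end: int = 2012
    seed: int = 0
    climate_vars: tuple[str, ...] = ("precip", "tmean", "dtr")
    basin_fraction: float = 0.85
    ifl_fraction: float = 0.55
    water_fraction: float = 0.02
    enso_coupling: float = -3.0       # Mg C ha-1 per MEI_w unit
    interannual_sd: float = 1.0       # Mg C ha-1, non-ENSO climate anomaly
    disturbance_intensity: float = 0.015  # expected fractional loss / yr
    clearing_loss_fraction: float = 0.6
    regrowth_rate: float = 0.04
    initial_deficit: float = 0.18     # mean AGB_def/AGB_pot at year_start
    obs_noise_sd: float = 2.0         # Mg C ha-1 iid pixel noise
    obs_spread: float = 0.08          # relative half-width of q05..q95
    mei_ar1: float = 0.85             # bimonthly AR(1) coefficient

    def __post_init__(self) -> None:
        if not (0.0 < self.ifl_fraction < 1.0):
            raise ConfigurationError("ifl_fraction must be in (0, 1)")
        if not (0.0 <= self.regrowth_rate < 1.0):
            raise ConfigurationError("regrowth_rate must be in [0, 1)")
        if self.obs_spread < 0.0:
            raise ConfigurationError("obs_spread must be >= 0")
        if self.year_end <= self.year_start:
            raise ConfigurationError("year_end must exceed year_start")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @property
    def n_features(self) -> int:
        return 12 * len(self.climate_vars) + 1  # monthly layers + latitude


@dataclass
class SyntheticWorld:
    config: WorldConfig
    climatology: dict[str, np.ndarray]       # var -> (12, n_lat, n_lon)
    masks: MaskSet
    truth_potential: np.ndarray               # (n_years, n_lat, n_lon)
    truth_obs_clean: np.ndarray               # (n_years, n_lat, n_lon)
    agb_obs: AnnualEnsembleSeries
    mei_bimonthly: IndexSeries
    mei_w: IndexSeries
    primary_fraction: np.ndarray              # (n_years, n_lat, n_lon)
    stress_s: IndexSeries
    deforestation_rate: IndexSeries           # Pg C cleared per year
    clip_count: int
    f_info: dict

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    @property
    def years(self) -> list[int]:
        return self.config.years


def _smooth(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized spatially correlated Gaussian surface."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _climatology(rng: np.random.Generator, cfg: WorldConfig) -> dict[str, np.ndarray]:
    shape = cfg.grid.shape
    sigma = max(min(shape) / 10.0, 1.5)
    months = np.arange(12)
    out: dict[str, np.ndarray] = {}
    specs = {
        # name: (spatial mean, spatial sd, seasonal amp, monthly noise, floor)
        # monthly surfaces carry independent spatial structure comparable to
        # the shared base, as real monthly climatologies do — this keeps the
        # per-month layers from being collinear copies of one another
        "precip": (180.0, 40.0, 70.0, 30.0, 0.0),
        "tmean": (25.0, 1.5, 1.5, 1.0, None),
        "dtr": (10.0, 1.2, 0.8, 0.8, 0.0),
    }
    for var in cfg.climate_vars:
        mean, sd, amp, noise, floor = specs.get(var, (0.0, 1.0, 0.5, 0.1, None))
        base = mean + sd * _smooth(rng, shape, sigma)
        phase = _smooth(rng, shape, sigma)  # spatially varying seasonal phase
        stack = np.empty((12, *shape))
        for m in months:
            seasonal = amp * np.cos(2 * np.pi * (m - 1) / 12 + 0.3 * phase)
            stack[m] = base + seasonal + noise * _smooth(rng, shape, sigma)
        if floor is not None:
            stack = np.clip(stack, floor, None)
        out[var] = stack
    return out


def _true_potential_base(clim: dict[str, np.ndarray], grid: GridSpec,
                         cfg: WorldConfig) -> tuple[np.ndarray, dict]:
    """Smooth nonlinear climate→biomass surface (Mg C ha⁻¹).

    Linear terms in temperature, diurnal range and latitude plus a
    saturating tanh response to annual precipitation; coefficients are
    reported so truth can be reconstructed exactly."""
    lat = grid.lat_grid()
    lat_mid = 0.5 * (grid.lat_min + grid.lat_max)
    coeffs = {"intercept": 60.0, "precip_sat_amp": 90.0,
              "precip_center": 150.0, "precip_scale": 90.0,
              "tmean_coef": 4.0, "dtr_coef": -2.5, "lat_coef": 0.8}
    base = np.full(grid.shape, coeffs["intercept"])
    if "precip" in clim:
        p_ann = clim["precip"].mean(axis=0)
        base = base + coeffs["precip_sat_amp"] * np.tanh(
            (p_ann - coeffs["precip_center"]) / coeffs["precip_scale"])
    if "tmean" in clim:
        base = base + coeffs["tmean_coef"] * (clim["tmean"].mean(axis=0) - 25.0)
    if "dtr" in clim:
        base = base + coeffs["dtr_coef"] * (clim["dtr"].mean(axis=0) - 10.0)
    base = base + coeffs["lat_coef"] * (lat - lat_mid)
    return np.clip(base, 0.0, None), coeffs


def _masks(rng: np.random.Generator, cfg: WorldConfig) -> tuple[MaskSet, np.ndarray]:
    """Basin, clustered IFL and water masks; returns the human-pressure
    surface used for clustering (high pressure = disturbed)."""
    grid = cfg.grid
    shape = grid.shape
    sigma = max(min(shape) / 8.0, 2.0)
    b = _smooth(rng, shape, sigma)
    basin = b >= np.quantile(b, 1.0 - cfg.basin_fraction)
    # human pressure mixes a broad gradient (the "arc" of clearing) with
    # regional texture so intact and disturbed pixels interleave and share
    # the climate envelope, as real intact-forest maps do
    pressure = (0.6 * _smooth(rng, shape, sigma)
                + 0.8 * _smooth(rng, shape, 1.5))
    thr = np.quantile(pressure[basin], cfg.ifl_fraction)
    ifl = basin & (pressure <= thr)
    w = _smooth(rng, shape, sigma / 2.0)
    if cfg.water_fraction > 0:
        wthr = np.quantile(w[basin], 1.0 - cfg.water_fraction)
        water = basin & (w > wthr)
    else:
        water = np.zeros(shape, dtype=bool)
    return MaskSet(grid, basin, ifl, water), pressure


def _mei(rng: np.random.Generator, cfg: WorldConfig) -> IndexSeries:
    """Bimonthly AR(1) ENSO index, stationary unit variance."""
    n = 12 * len(cfg.years)
    phi = cfg.mei_ar1
    innov_sd = np.sqrt(1.0 - phi ** 2)
    vals = np.empty(n)
    vals[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * innov_sd
    for i in range(1, n):
        vals[i] = phi * vals[i - 1] + eps[i - 1]
    labels = [bimonth_label(y, bm) for y in cfg.years for bm in BIMONTHS]
    return IndexSeries(labels, vals, kind="MEI")


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete input bundle plus ground truth, deterministically
    from ``config.seed``."""
    cfg = config
    grid = cfg.grid
    years = cfg.years
    n_years = len(years)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA6B]))

    clim = _climatology(rng, cfg)
    masks, pressure = _masks(rng, cfg)
    min_rows = 2 * (cfg.n_features + 1)
    n_ifl = int(masks.ifl.sum())
    if n_ifl < min_rows:
        raise ConfigurationError(
            f"grid too small: {n_ifl} IFL pixels < minimum training size "
            f"{min_rows}")

    base, coeffs = _true_potential_base(clim, grid, cfg)

    mei = _mei(rng, cfg)
    mei_w = winter_composite_series(mei, years)
    eps = rng.standard_normal(n_years) * cfg.interannual_sd

    pot = np.clip(base[None, :, :] + (cfg.enso_coupling * mei_w.values
                                      + eps)[:, None, None], 0.0, None)

    # --- disturbance history on basin \ IFL -------------------------------
    disturbed = masks.disturbed
    nd = int(disturbed.sum())
    # rank-normalized pressure -> clustered clearing weights, mean ~1
    ranks = np.empty(nd)
    ranks[np.argsort(pressure[disturbed], kind="stable")] = np.arange(nd)
    weight = 2.0 * (ranks + 0.5) / max(nd, 1)

    loss_frac = cfg.clearing_loss_fraction
    if cfg.disturbance_intensity > 0:
        d = np.clip(cfg.initial_deficit * weight, 0.0, 0.85)
        p_clear = np.clip(cfg.disturbance_intensity / loss_frac * weight,
                          0.0, 1.0)
    else:
        d = np.zeros(nd)
        p_clear = np.zeros(nd)
    cleared_cum = d.copy()  # primary land already converted at year_start

    areas_ha = _areas(grid)
    obs_clean = np.empty_like(pot)
    pf = np.full((n_years, *grid.shape), np.nan)
    defo_rate = np.zeros(n_years)
    for k, year in enumerate(years):
        if k > 0:
            d *= (1.0 - cfg.regrowth_rate)
            events = rng.random(nd) < p_clear
            biomass_before = pot[k][disturbed] * (1.0 - d)
            lost = biomass_before * loss_frac * events
            defo_rate[k] = float(np.sum(lost * areas_ha[disturbed]) / 1e9)
            d = d + (1.0 - d) * loss_frac * events
            cleared_cum = cleared_cum + (1.0 - cleared_cum) * loss_frac * events
        layer = pot[k].copy()
        layer[disturbed] = pot[k][disturbed] * (1.0 - d)
        layer[~masks.basin] = np.nan
        obs_clean[k] = layer
        frame = np.full(grid.shape, np.nan)
        frame[masks.basin] = 1.0
        frame[disturbed] = 1.0 - cleared_cum
        pf[k] = frame

    # --- observation model ------------------------------------------------
    noise = rng.standard_normal(obs_clean.shape) * cfg.obs_noise_sd
    mean_maps = obs_clean + np.where(np.isnan(obs_clean), 0.0, noise)
    clip_count = int(np.sum(mean_maps < 0.0))
    mean_maps = np.clip(mean_maps, 0.0, None)
    mean_maps[:, ~masks.basin] = np.nan
    # open-water pixels: observation held at the first year's value
    mean_maps[:, masks.water] = mean_maps[0, masks.water]
    agb_obs = AnnualEnsembleSeries(grid, years, {
        "q05": mean_maps * (1.0 - cfg.obs_spread),
        "mean": mean_maps,
        "q95": mean_maps * (1.0 + cfg.obs_spread),
    }, AGB_UNITS)

    # --- companion series -------------------------------------------------
    stress_raw = IndexSeries(
        years, -mei_w.values + 0.8 * rng.standard_normal(n_years),
        kind="GLEAM_S")
    stress = zscore(stress_raw)
    rate = IndexSeries(years, defo_rate, kind="deforestation_rate")

    truth_masked = pot.copy()
    truth_masked[:, ~masks.basin] = np.nan

    return SyntheticWorld(cfg, clim, masks, truth_masked, obs_clean, agb_obs,
                          mei, mei_w, pf, stress, rate, clip_count,
                          {"coefficients": coeffs,
                           "form": "intercept + amp*tanh((P_ann-c)/s) "
                                   "+ a_T*(T-25) + a_D*(D-10) "
                                   "+ a_lat*(lat-lat_mid)"})


def _areas(grid: GridSpec) -> np.ndarray:
    from .grid import cell_area_grid
    return cell_area_grid(grid)


def truth_report(world: SyntheticWorld) -> dict:
    """Ground-truth summary: true deficit/obs/pot totals over the disturbed
    region (Pg C), the true deficit trend, and the injected ENSO coupling as
    actually realized in this world."""
    masks = world.masks
    grid = world.grid
    years = world.years
    dist = masks.disturbed
    obs_t, pot_t, def_t = [], [], []
    for k in range(len(years)):
        pot_f = RasterField(grid, world.truth_potential[k], AGB_UNITS)
        obs_f = RasterField(grid, world.truth_obs_clean[k], AGB_UNITS)
        po = aggregate_total(pot_f, dist)
        ob = aggregate_total(obs_f, dist)
        pot_t.append(po)
        obs_t.append(ob)
        def_t.append(po - ob)
    def_series = IndexSeries(years, np.asarray(def_t), kind="true_deficit")
    pot_series = IndexSeries(years, np.asarray(pot_t), kind="true_pot")
    slope, intercept, tr = linear_trend(def_series)
    enso = correlate(world.mei_w, detrend(annual_delta(pot_series)))
    return {
        "years": years,
        "true_obs_pg": obs_t,
        "true_pot_pg": pot_t,
        "true_deficit_pg": def_t,
        "true_trend_slope_pg_per_yr": slope,
        "true_trend_r": tr.r,
        "injected_enso_r": enso.r,
        "injected_enso_p": enso.p,
        "enso_coupling": world.config.enso_coupling,
        "clip_count": world.clip_count,
        "potential_surface": world.f_info,
    }


def write_world(world: SyntheticWorld, outdir) -> dict[str, str]:
    """Write the full bundle (NetCDF rasters + CSV series + truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = world.grid
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(outdir / name)
        return outdir / name

    write_ensemble(world.agb_obs, _p("agb_obs.nc"))
    write_mask_set(world.masks, _p("masks.nc"))
    for var, stack in world.climatology.items():
        write_stack(stack, "month", np.arange(1, 13), grid,
                    _p(f"climatology_{var}.nc"), var)
    write_stack(world.truth_potential, "year", world.years, grid,
                _p("truth_potential.nc"), "agb_pot_true", AGB_UNITS)
    write_stack(world.primary_fraction, "year", world.years, grid,
                _p("primary_fraction.nc"), "primary_fraction", "1")
    world.mei_bimonthly.to_csv(_p("mei_bimonthly.csv"))
    world.mei_w.to_csv(_p("mei_winter.csv"))
    world.stress_s.to_csv(_p("stress_s.csv"))
    world.deforestation_rate.to_csv(_p("deforestation_rate.csv"))
    report = truth_report(world)
    _p("truth_report.json")
    (outdir / "truth_report.json").write_text(json.dumps(report, indent=2))
    return paths
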