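"""Grid geometry, raster containers, masks and area-weighted aggregation.

All rasters live on a regular latitude/longitude grid. Cell coordinates refer
to cell *centers*; a cell spans the half-open interval ``[edge, edge + res)``.
Latitude is stored south→north and longitude west→east; file I/O normalizes
to this orientation. Missing data is ``NaN`` and is excluded from sums and
regressions, never treated as zero.

Biomass density maps carry units of Mg C ha⁻¹; basin totals are reported in
Pg C (1 Pg = 10⁹ Mg). Pixel areas are geodesic spherical-cap strips on a
sphere of mean radius 6,371,000 m.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

from .exceptions import ConfigurationError, DomainError, FormatError

EARTH_RADIUS_M = 6_371_000.0
M2_PER_HA = 1.0e4
MG_PER_PG = 1.0e9

#: canonical unit string for biomass density fields
AGB_UNITS = "Mg C ha-1"

LEVELS = ("q05", "mean", "q95")


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid defined by its outer edges and resolution."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.25

    def __post_init__(self) -> None:
        for name, span in (("lat", self.lat_max - self.lat_min),
                           ("lon", self.lon_max - self.lon_min)):
            n = span / self.resolution
            if span <= 0 or abs(n - round(n)) > 1e-9:
                raise ConfigurationError(
                    f"{name} span {span} is not a positive multiple of "
                    f"resolution {self.resolution}")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ConfigurationError("latitude edges must lie in [-90, 90]")

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.resolution * (np.arange(self.n_lat) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.n_lon) + 0.5)

    def lat_grid(self) -> np.ndarray:
        """Per-pixel latitude of cell centers, shape (n_lat, n_lon)."""
        return np.broadcast_to(self.lat_centers[:, None], self.shape).copy()


@dataclass
class RasterField:
    """A 2-D field on a :class:`GridSpec` with a unit tag and NaN missing."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"field shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "RasterField":
        return RasterField(self.grid, self.values.copy(), self.units)


@dataclass
class MaskSet:
    """Basin / intact-forest / open-water boolean masks on one grid.

    The intact-forest (IFL) mask must be a subset of the basin; the
    *disturbed* region is ``basin & ~ifl``.
    """

    grid: GridSpec
    basin: np.ndarray
    ifl: np.ndarray
    water: np.ndarray

    def __post_init__(self) -> None:
        for name in ("basin", "ifl", "water"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != self.grid.shape:
                raise ConfigurationError(f"mask {name!r} shape mismatch")
            setattr(self, name, arr)
        if np.any(self.ifl & ~self.basin):
            raise ConfigurationError("ifl mask is not a subset of basin mask")

    @property
    def disturbed(self) -> np.ndarray:
        return self.basin & ~self.ifl


@dataclass
class AnnualEnsembleSeries:
    """Per-year AGB maps at quantile levels q05 / mean / q95.

    ``maps[level]`` is an array of shape (n_years, n_lat, n_lon).
    """

    grid: GridSpec
    years: list[int]
    maps: dict[str, np.ndarray]
    units: str = AGB_UNITS

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        if sorted(self.years) != self.years or len(set(self.years)) != len(self.years):
            raise ConfigurationError("years must be strictly increasing")
        for level, arr in self.maps.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != (len(self.years), *self.grid.shape):
                raise ConfigurationError(f"maps[{level!r}] shape mismatch")
            self.maps[level] = arr

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(k for k in LEVELS if k in self.maps)

    def field(self, level: str, year: int) -> RasterField:
        if level not in self.maps:
            raise ConfigurationError(f"level {level!r} not present")
        if year not in self.years:
            raise DomainError(f"year {year} not in series")
        # copy so callers can edit fields without mutating the series
        return RasterField(self.grid,
                           self.maps[level][self.years.index(year)].copy(),
                           self.units)

    def check_order(self, atol: float = 1e-9) -> bool:
        """True if q05 ≤ mean ≤ q95 pixel-wise wherever all are defined."""
        if not all(lv in self.maps for lv in LEVELS):
            return True
        q05, mean, q95 = (self.maps[lv] for lv in LEVELS)
        ok = np.isfinite(q05) & np.isfinite(mean) & np.isfinite(q95)
        return bool(np.all(q05[ok] <= mean[ok] + atol)
                    and np.all(mean[ok] <= q95[ok] + atol))


def pixel_area(lat_center, resolution: float = 0.25) -> np.ndarray | float:
    """Geodesic area in hectares of a cell centered at ``lat_center``.

    Computed as R²·Δλ·(sin φ_top − sin φ_bottom) on the mean-radius sphere,
    so summing over a full-globe grid closes exactly to 4πR².
    """
    lat = np.asarray(lat_center, dtype=np.float64)
    if np.any(np.abs(lat) > 90.0):
        raise DomainError("latitude outside [-90, 90]")
    half = resolution / 2.0
    top = np.sin(np.deg2rad(np.minimum(lat + half, 90.0)))
    bot = np.sin(np.deg2rad(np.maximum(lat - half, -90.0)))
    area_m2 = EARTH_RADIUS_M ** 2 * np.deg2rad(resolution) * (top - bot)
    out = area_m2 / M2_PER_HA
    return float(out) if np.isscalar(lat_center) else out


def cell_area_grid(grid: GridSpec) -> np.ndarray:
    """Per-pixel areas in hectares, shape (n_lat, n_lon)."""
    col = pixel_area(grid.lat_centers, grid.resolution)
    return np.broadcast_to(col[:, None], grid.shape).copy()


def aggregate_total(field: RasterField, mask: np.ndarray) -> float:
    """Area-weighted total of a Mg C ha⁻¹ field over ``mask``, in Pg C.

    Missing (NaN) pixels contribute zero.
    """
    if field.units != AGB_UNITS:
        raise ConfigurationError(
            f"aggregate_total requires units {AGB_UNITS!r}, got "
            f"{field.units!r}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.grid.shape:
        raise ConfigurationError("mask shape does not match grid")
    areas = cell_area_grid(field.grid)
    vals = field.values
    sel = mask & ~np.isnan(vals)
    return float(np.sum(vals[sel] * areas[sel]) / MG_PER_PG)


def area_weighted_mean(field: RasterField, mask: np.ndarray) -> float:
    """Area-weighted mean of a field over ``mask`` (any units)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.grid.shape:
        raise ConfigurationError("mask shape does not match grid")
    areas = cell_area_grid(field.grid)
    sel = mask & ~np.isnan(field.values)
    w = areas[sel]
    if w.size == 0:
        raise DomainError("no non-missing pixels under mask")
    return float(np.sum(field.values[sel] * w) / np.sum(w))


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style lat/lon coordinates; NetCDF3 classic via scipy engine)

def write_raster(field: RasterField, path, variable: str = "field") -> None:
    grid = field.grid
    da = xr.DataArray(
        field.values,
        dims=("lat", "lon"),
        coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
        name=variable,
        attrs={"units": field.units} if field.units else {},
    )
    da["lat"].attrs["units"] = "degrees_north"
    da["lon"].attrs["units"] = "degrees_east"
    da.to_netcdf(Path(path), engine="scipy")


def _grid_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    dlat = np.diff(lat)
    dlon = np.diff(lon)
    if lat.size < 2 or lon.size < 2:
        raise FormatError("need at least 2 points per coordinate axis")
    if not (np.allclose(dlat, dlat[0]) and np.allclose(dlon, dlon[0])):
        raise FormatError("coordinates are not on a regular grid")
    res = float(abs(dlat[0]))
    if not np.isclose(abs(dlon[0]), res):
        raise FormatError("lat/lon resolutions differ")
    return GridSpec(float(lat.min() - res / 2), float(lat.max() + res / 2),
                    float(lon.min() - res / 2), float(lon.max() + res / 2),
                    res)


def read_raster(path, variable: str = "field",
                expect_grid: GridSpec | None = None) -> RasterField:
    """Read a 2-D variable; latitude is normalized south→north."""
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not in {path}")
        da = ds[variable]
        if "lat" not in da.coords or "lon" not in da.coords:
            raise FormatError("missing lat/lon coordinate variables")
        lat = np.asarray(da["lat"].values, dtype=float)
        lon = np.asarray(da["lon"].values, dtype=float)
        vals = np.asarray(da.transpose("lat", "lon").values, dtype=np.float64)
        units = str(da.attrs.get("units", ""))
    if lat.size > 1 and lat[0] > lat[-1]:
        lat = lat[::-1]
        vals = vals[::-1, :]
    if lon.size > 1 and lon[0] > lon[-1]:
        lon = lon[::-1]
        vals = vals[:, ::-1]
    grid = _grid_from_coords(lat, lon)
    if expect_grid is not None and grid != expect_grid:
        raise FormatError(f"grid in file {grid} != expected {expect_grid}")
    return RasterField(grid, vals, units)


def write_mask_set(masks: MaskSet, path) -> None:
    grid = masks.grid
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    ds = xr.Dataset(
        {name: (("lat", "lon"), getattr(masks, name).astype(np.int8))
         for name in ("basin", "ifl", "water")},
        coords=coords,
    )
    ds.to_netcdf(Path(path), engine="scipy")


def read_mask_set(path, expect_grid: GridSpec | None = None) -> MaskSet:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        arrs = {}
        for name in ("basin", "ifl", "water"):
            if name not in ds:
                raise FormatError(f"mask variable {name!r} missing")
            arrs[name] = np.asarray(ds[name].values)
    flip_lat = lat.size > 1 and lat[0] > lat[-1]
    if flip_lat:
        lat = lat[::-1]
        arrs = {k: v[::-1, :] for k, v in arrs.items()}
    grid = _grid_from_coords(lat, lon)
    if expect_grid is not None and grid != expect_grid:
        raise FormatError("mask grid mismatch")
    return MaskSet(grid, arrs["basin"].astype(bool), arrs["ifl"].astype(bool),
                   arrs["water"].astype(bool))


def write_stack(values: np.ndarray, dim_name: str, dim_values,
                grid: GridSpec, path, variable: str = "field",
                units: str = "") -> None:
    """Write a (k, n_lat, n_lon) stack with a leading dimension (month/year)."""
    da = xr.DataArray(
        np.asarray(values, dtype=np.float64),
        dims=(dim_name, "lat", "lon"),
        coords={dim_name: np.asarray(dim_values),
                "lat": grid.lat_centers, "lon": grid.lon_centers},
        name=variable,
        attrs={"units": units} if units else {},
    )
    da.to_netcdf(Path(path), engine="scipy")


def read_stack(path, variable: str, dim_name: str,
               expect_grid: GridSpec | None = None):
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not in {path}")
        da = ds[variable]
        lat = np.asarray(da["lat"].values, dtype=float)
        lon = np.asarray(da["lon"].values, dtype=float)
        dim_values = np.asarray(da[dim_name].values)
        vals = np.asarray(da.transpose(dim_name, "lat", "lon").values,
                          dtype=np.float64)
    if lat.size > 1 and lat[0] > lat[-1]:
        lat = lat[::-1]
        vals = vals[:, ::-1, :]
    grid = _grid_from_coords(lat, lon)
    if expect_grid is not None and grid != expect_grid:
        raise FormatError("stack grid mismatch")
    return vals, dim_values, grid


def write_ensemble(series: AnnualEnsembleSeries, path) -> None:
    grid = series.grid
    ds = xr.Dataset(
        {f"agb_{lv}": (("year", "lat", "lon"), series.maps[lv],
                       {"units": series.units})
         for lv in series.levels},
        coords={"year": np.asarray(series.years, dtype=np.int32),
                "lat": grid.lat_centers, "lon": grid.lon_centers},
    )
    ds.to_netcdf(Path(path), engine="scipy")


def read_ensemble(path, expect_grid: GridSpec | None = None) -> AnnualEnsembleSeries:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        years = [int(y) for y in ds["year"].values]
        maps = {}
        units = AGB_UNITS
        for lv in LEVELS:
            name = f"agb_{lv}"
            if name in ds:
                maps[lv] = np.asarray(ds[name].values, dtype=np.float64)
                units = str(ds[name].attrs.get("units", AGB_UNITS))
    if not maps:
        raise FormatError("no agb_* variables found")
    if lat.size > 1 and lat[0] > lat[-1]:
        maps = {k: v[:, ::-1, :] for k, v in maps.items()}
        lat = lat[::-1]
    grid = _grid_from_coords(lat, lon)
    if expect_grid is not None and grid != expect_grid:
        raise FormatError("ensemble grid mismatch")
    return AnnualEnsembleSeries(grid, years, maps, units)
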