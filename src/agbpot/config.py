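"""Run configuration: YAML schema, defaults, and provenance manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .forest import ForestParams
from .grid import GridSpec
from .synthetic import WorldConfig

CONFIG_SCHEMA_VERSION = 1

#: the ensemble size used for the published-scale analysis
N_TREES_FULL = 1000
#: reduced ensemble size for routine runs and test suites
N_TREES_FAST = 100


@dataclass
class RunConfig:
    grid: GridSpec = dc_field(
        default_factory=lambda: GridSpec(-15.0, -5.0, -70.0, -60.0, 0.25))
    year_start: int = 1993
    year_end: int = 2012
    seed: int = 0
    n_trees: int = N_TREES_FAST
    max_depth: int = 12
    min_leaf_rows: int | None = None
    mtry: int | None = None
    levels: tuple[str, ...] = ("q05", "mean", "q95")
    trend_segment_end: int = 2005
    assumed_start_year: int = 1960
    world: WorldConfig | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if not (self.year_start < self.year_end):
            raise ConfigurationError("year_start must precede year_end")

    def forest_params(self) -> ForestParams:
        return ForestParams(self.n_trees, self.max_depth,
                            self.min_leaf_rows, self.mtry)

    def world_config(self) -> WorldConfig:
        if self.world is not None:
            return self.world
        return WorldConfig(grid=self.grid, year_start=self.year_start,
                           year_end=self.year_end, seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "schema_version": CONFIG_SCHEMA_VERSION,
            "grid": {"lat_min": self.grid.lat_min,
                     "lat_max": self.grid.lat_max,
                     "lon_min": self.grid.lon_min,
                     "lon_max": self.grid.lon_max,
                     "resolution": self.grid.resolution},
            "year_start": self.year_start, "year_end": self.year_end,
            "seed": self.seed, "n_trees": self.n_trees,
            "max_depth": self.max_depth,
            "min_leaf_rows": self.min_leaf_rows, "mtry": self.mtry,
            "levels": list(self.levels),
            "trend_segment_end": self.trend_segment_end,
            "assumed_start_year": self.assumed_start_year,
        }
        if self.world is not None:
            w = dataclasses.asdict(self.world)
            w["grid"] = d["grid"]
            w["climate_vars"] = list(self.world.climate_vars)
            d["world"] = w
        return d


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if doc.get("schema_version", CONFIG_SCHEMA_VERSION) != CONFIG_SCHEMA_VERSION:
        raise ConfigurationError("unsupported config schema version")
    g = doc.get("grid", {})
    grid = GridSpec(g.get("lat_min", -15.0), g.get("lat_max", -5.0),
                    g.get("lon_min", -70.0), g.get("lon_max", -60.0),
                    g.get("resolution", 0.25))
    world = None
    if "world" in doc:
        w = dict(doc["world"])
        w.pop("grid", None)
        w["climate_vars"] = tuple(w.get("climate_vars",
                                        ("precip", "tmean", "dtr")))
        world = WorldConfig(grid=grid, **w)
    return RunConfig(
        grid=grid,
        year_start=doc.get("year_start", 1993),
        year_end=doc.get("year_end", 2012),
        seed=doc.get("seed", 0),
        n_trees=doc.get("n_trees", N_TREES_FAST),
        max_depth=doc.get("max_depth", 12),
        min_leaf_rows=doc.get("min_leaf_rows"),
        mtry=doc.get("mtry"),
        levels=tuple(doc.get("levels", ("q05", "mean", "q95"))),
        trend_segment_end=doc.get("trend_segment_end", 2005),
        assumed_start_year=doc.get("assumed_start_year", 1960),
        world=world,
    )


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: RunConfig, files, path_name="manifest.json"):
    """Record the resolved config and a sha256 per output file."""
    outdir = Path(outdir)
    manifest = {
        "config": config.to_dict(),
        "files": {str(Path(f).name): file_sha256(f) for f in sorted(map(str, files))},
    }
    out = outdir / path_name
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
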