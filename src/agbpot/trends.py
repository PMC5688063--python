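"""Trend, anomaly and correlation statistics.

Covers segment linear trends, first differences of annual stock series,
OLS detrending, the boreal-winter ENSO composite (MEI_w), Pearson
correlations of aligned series, spatial correlation of two maps, and
per-pixel temporal correlation maps with a p < 0.05 significance mask.

Significance is parametric throughout: p is two-sided from
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. No multiple-testing
correction is applied to pixel-wise maps (a deliberately liberal choice,
see docs). Zero-variance inputs yield a flagged degenerate result in map
contexts and raise :class:`~agbpot.exceptions.DomainError` in scalar
contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError
from .grid import GridSpec, RasterField

#: bimonthly label sequence; "Dec/Jan" belongs to the year containing the Jan
BIMONTHS = ("Dec/Jan", "Jan/Feb", "Feb/Mar", "Mar/Apr", "Apr/May", "May/Jun",
            "Jun/Jul", "Jul/Aug", "Aug/Sep", "Sep/Oct", "Oct/Nov", "Nov/Dec")

WINTER_BIMONTHS = BIMONTHS[:4]  # Dec/Jan .. Mar/Apr


@dataclass
class IndexSeries:
    """A 1-D labelled series (annual years or bimonthly "YYYY Dec/Jan")."""

    labels: list
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.labels) != self.values.size:
            raise DomainError("labels and values length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise DomainError("duplicate time labels")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "") -> "IndexSeries":
        df = pd.read_csv(Path(path))
        labels = [int(x) if str(x).lstrip("-").isdigit() else str(x)
                  for x in df["label"]]
        return cls(labels, df["value"].to_numpy(dtype=float), kind)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    degenerate: bool = False


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    n = x.size
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CorrelationResult(0.0, n, 1.0, degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), n, float(p))


def linear_trend(series: IndexSeries, window: tuple[int, int] | None = None):
    """OLS of value on year over ``window`` (inclusive).

    Returns ``(slope, intercept, CorrelationResult)``; a constant series is
    reported with slope 0 and a degenerate flag rather than an error.
    """
    years = np.asarray(series.labels, dtype=float)
    vals = series.values
    if window is not None:
        lo, hi = window
        if lo < years.min() or hi > years.max():
            raise DomainError(f"window {window} outside series years")
        sel = (years >= lo) & (years <= hi)
        years, vals = years[sel], vals[sel]
    if years.size < 3:
        raise DomainError("need at least 3 points for a trend")
    if np.std(vals) == 0.0:
        return 0.0, float(vals[0]), CorrelationResult(0.0, years.size, 1.0,
                                                      degenerate=True)
    res = sps.linregress(years, vals)
    return (float(res.slope), float(res.intercept),
            CorrelationResult(float(res.rvalue), years.size,
                              float(res.pvalue)))


def annual_delta(series: IndexSeries) -> IndexSeries:
    """First differences Δ(y) = value(y) − value(y−1), labelled by year y."""
    years = np.asarray(series.labels, dtype=int)
    if years.size < 2:
        raise DomainError("need at least 2 points")
    if np.any(np.diff(years) != 1):
        raise DomainError("gaps in years")
    return IndexSeries(list(years[1:]), np.diff(series.values),
                       kind=f"delta_{series.kind}" if series.kind else "delta")


def detrend(series: IndexSeries) -> IndexSeries:
    """Residuals of the OLS linear fit of value on time.

    Idempotent; residuals have zero mean and zero correlation with time.
    """
    if len(series) < 3:
        raise DomainError("need at least 3 points to detrend")
    t = np.arange(len(series), dtype=float)
    coef = np.polyfit(t, series.values, 1)
    resid = series.values - np.polyval(coef, t)
    return IndexSeries(series.labels, resid,
                       kind=f"detrended_{series.kind}" if series.kind else "detrended")


def zscore(series: IndexSeries) -> IndexSeries:
    """(x − mean)/sd with the sample (n−1) standard deviation."""
    if len(series) < 2:
        raise DomainError("need at least 2 points")
    sd = float(np.std(series.values, ddof=1))
    if sd == 0.0:
        raise DomainError("zero variance")
    z = (series.values - series.values.mean()) / sd
    return IndexSeries(series.labels, z, kind=f"z_{series.kind}")


def bimonth_label(year: int, bimonth: str) -> str:
    return f"{year} {bimonth}"


def winter_composite(mei_bimonthly: IndexSeries, year: int) -> float:
    """Mean of the four bimonthly values Dec/Jan .. Mar/Apr for ``year``.

    The Dec/Jan bimonth is assigned to the calendar year containing the
    January, so all four winter bimonths carry the same year label.
    """
    lut = dict(zip(mei_bimonthly.labels, mei_bimonthly.values))
    vals = []
    for bm in WINTER_BIMONTHS:
        lab = bimonth_label(year, bm)
        if lab not in lut:
            raise DomainError(f"missing bimonth {lab!r}")
        vals.append(lut[lab])
    return float(np.mean(vals))


def winter_composite_series(mei_bimonthly: IndexSeries,
                            years) -> IndexSeries:
    years = list(years)
    vals = [winter_composite(mei_bimonthly, y) for y in years]
    return IndexSeries(years, np.asarray(vals), kind="MEI_w")


def correlate(a: IndexSeries, b: IndexSeries) -> CorrelationResult:
    """Pearson r and two-sided p on the intersection of time labels."""
    common = [lab for lab in a.labels if lab in set(b.labels)]
    if len(common) < 3:
        raise DomainError("fewer than 3 common labels")
    la = {lab: v for lab, v in zip(a.labels, a.values)}
    lb = {lab: v for lab, v in zip(b.labels, b.values)}
    x = np.array([la[c] for c in common])
    y = np.array([lb[c] for c in common])
    return _pearson(x, y)


def spatial_correlation(map1: RasterField, map2: RasterField,
                        mask: np.ndarray) -> CorrelationResult:
    """Unweighted Pearson correlation across pixels under ``mask``."""
    if map1.grid != map2.grid:
        raise DomainError("maps on different grids")
    sel = (np.asarray(mask, dtype=bool)
           & ~np.isnan(map1.values) & ~np.isnan(map2.values))
    if sel.sum() < 3:
        raise DomainError("fewer than 3 common non-missing pixels")
    return _pearson(map1.values[sel], map2.values[sel])


def pixelwise_temporal_correlation(
        fields_a: np.ndarray, fields_b: np.ndarray, mask: np.ndarray,
        grid: GridSpec, alpha: float = 0.05,
) -> tuple[RasterField, RasterField, np.ndarray]:
    """Per-pixel Pearson r of two (n_years, n_lat, n_lon) stacks over years.

    Returns ``(r_map, p_map, significant)`` where ``significant`` is the
    boolean p < alpha mask. Pixels with fewer than 3 common years or zero
    variance in either stack are missing in all outputs (never spuriously
    significant).
    """
    a = np.asarray(fields_a, dtype=np.float64)
    b = np.asarray(fields_b, dtype=np.float64)
    if a.shape != b.shape or a.shape[1:] != grid.shape:
        raise DomainError("stack shapes mismatch")
    mask = np.asarray(mask, dtype=bool)
    ok = np.isfinite(a) & np.isfinite(b)
    n = ok.sum(axis=0).astype(float)
    aa = np.where(ok, a, np.nan)
    bb = np.where(ok, b, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.maximum(n, 1)
        ma = np.nansum(aa, axis=0) / n_safe
        mb = np.nansum(bb, axis=0) / n_safe
        da = aa - ma
        db = bb - mb
        cov = np.nansum(da * db, axis=0)
        va = np.nansum(da * da, axis=0)
        vb = np.nansum(db * db, axis=0)
        r = cov / np.sqrt(va * vb)
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = 2.0 * sps.t.sf(np.abs(t), np.maximum(n - 2, 1))
        # perfect correlation: t -> inf, p -> 0
        p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    valid = mask & (n >= 3) & (va > 0) & (vb > 0)
    r = np.where(valid, r, np.nan)
    p = np.where(valid, p, np.nan)
    sig = valid & (p < alpha)
    return (RasterField(grid, r, "1"), RasterField(grid, p, "1"), sig)
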