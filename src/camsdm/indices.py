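"""Derived climate predictors for succulent/CAM habitat modelling.

The predictors computed here summarise how much water arrives and how
reliably it arrives, the quantities classically used to explain where
stem succulents occur:

* **Annual precipitation totals** aggregated from a monthly record, with a
  strict per-cell completeness rule (a year contributes only if all twelve
  months are valid there).
* **Hellmann–Eberle quotient** ``Q`` — the ratio of the wettest year's
  precipitation to the driest year's over the record.  ``Q`` close to 1
  means rainfall arrives predictably year after year; large ``Q`` means
  the supply is erratic.  Succulents favour dry but *predictable* regimes.
* **Ellenberg index** — a binary flag for the succulent-hostile
  combination: mean annual rainfall below ``p_threshold`` (default 500 mm)
  *and* ``Q`` above ``q_threshold`` (default 5), i.e. dry and erratic.
* **Aridity index** ``P/PET`` and **R-index** ``AET/PET`` — moisture supply
  relative to atmospheric demand.  PET/AET arrive as input rasters; this
  package does not compute evapotranspiration from first principles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, RasterLayer

__all__ = [
    "MonthlyPrecipSeries",
    "AnnualPrecip",
    "EllenbergParams",
    "annual_totals",
    "hellmann_eberle",
    "ellenberg_index",
    "aridity_index",
    "r_index",
]


@dataclass
class MonthlyPrecipSeries:
    """Monthly precipitation record on a grid.

    ``values`` has shape ``(n_years, 12, n_rows, n_cols)`` in mm/month,
    with NaN for missing months.  Years are contiguous calendar years
    starting at ``start_year``.
    """

    grid: GridSpec
    start_year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[1] != 12:
            raise ValueError("values must have shape (n_years, 12, n_rows, n_cols)")
        if self.values.shape[2:] != self.grid.shape:
            raise ValueError("spatial shape does not match grid")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("precipitation must be >= 0 or NaN")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)


@dataclass
class AnnualPrecip:
    """Per-year annual totals plus their mean, on one grid.

    ``totals`` has shape ``(n_years, n_rows, n_cols)``; a cell-year is NaN
    unless all 12 months were valid there (the completeness rule).
    """

    grid: GridSpec
    years: np.ndarray
    totals: np.ndarray
    mean_annual: RasterLayer

    def year_layer(self, year: int) -> RasterLayer:
        idx = int(year - self.years[0])
        if not (0 <= idx < len(self.years)):
            raise KeyError(f"year {year} not in record")
        return RasterLayer(self.grid, self.totals[idx], f"annual_precip_{year}", "mm")


@dataclass(frozen=True)
class EllenbergParams:
    """Thresholds of the dry-and-erratic rule: < p_threshold mm with Q > q_threshold."""

    p_threshold: float = 500.0
    q_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.q_threshold <= 0:
            raise ValueError("thresholds must be > 0")


def annual_totals(series: MonthlyPrecipSeries) -> AnnualPrecip:
    """Aggregate a monthly record to per-year totals and their mean.

    Only complete years (all 12 months valid at a cell) contribute; cells
    with no complete year at all are nodata in the mean.
    """
    if series.n_years < 1:
        raise ValueError("empty series")
    complete = ~np.any(np.isnan(series.values), axis=1)  # (n_years, r, c)
    totals = np.where(complete, np.nansum(series.values, axis=1), np.nan)
    if not np.any(complete):
        raise ValueError("no complete year at any cell")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(totals, axis=0)
    layer = RasterLayer(series.grid, mean, "mean_annual_precip", "mm/yr")
    return AnnualPrecip(series.grid, series.years, totals, layer)


def hellmann_eberle(annual: AnnualPrecip) -> RasterLayer:
    """Hellmann–Eberle quotient: wettest-year / driest-year annual total.

    Defined per cell over complete years only; requires at least two
    complete years, else nodata.  A driest year of exactly 0 mm is masked
    to nodata rather than mapped to infinity, so the quotient map stays
    finite for downstream learners.
    """
    n_complete = np.sum(~np.isnan(annual.totals), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hi = np.nanmax(annual.totals, axis=0)
        lo = np.nanmin(annual.totals, axis=0)
    q = np.full(annual.grid.shape, np.nan)
    ok = (n_complete >= 2) & (lo > 0)
    q[ok] = hi[ok] / lo[ok]
    return RasterLayer(annual.grid, q, "hellmann_eberle_q", "dimensionless")


def ellenberg_index(
    mean_annual: RasterLayer,
    quotient: RasterLayer,
    params: EllenbergParams = EllenbergParams(),
) -> RasterLayer:
    """Binary flag: 1 where rainfall is both scarce and erratic.

    Cell = 1 iff ``mean_annual < p_threshold`` and ``quotient >
    q_threshold``; nodata in either input propagates.
    """
    if mean_annual.grid != quotient.grid:
        raise ValueError("mean_annual and quotient are on different grids")
    with np.errstate(invalid="ignore"):
        flag = (
            (mean_annual.values < params.p_threshold)
            & (quotient.values > params.q_threshold)
        ).astype(float)
    flag[np.isnan(mean_annual.values) | np.isnan(quotient.values)] = np.nan
    return RasterLayer(mean_annual.grid, flag, "ellenberg_index", "binary")


def _ratio(numer: RasterLayer, denom: RasterLayer, name: str) -> RasterLayer:
    if numer.grid != denom.grid:
        raise ValueError("layers are on different grids")
    out = np.full(numer.grid.shape, np.nan)
    with np.errstate(invalid="ignore"):
        ok = (~np.isnan(numer.values)) & (~np.isnan(denom.values)) & (denom.values > 0)
    out[ok] = numer.values[ok] / denom.values[ok]
    return RasterLayer(numer.grid, out, name, "dimensionless")


def aridity_index(annual_precip: RasterLayer, pet: RasterLayer) -> RasterLayer:
    """Aridity index = annual precipitation / potential evapotranspiration.

    PET <= 0 (or nodata) yields nodata.
    """
    return _ratio(annual_precip, pet, "aridity_index")


def r_index(aet: RasterLayer, pet: RasterLayer) -> RasterLayer:
    """R-index = actual / potential evapotranspiration (supply vs demand).

    Values are passed through unclamped; AET exceeding PET is physically
    suspect and raises a warning but not an error.
    """
    with np.errstate(invalid="ignore"):
        if np.any(aet.values > pet.values):
            warnings.warn("AET exceeds PET at some cells", stacklevel=2)
    return _ratio(aet, pet, "r_index")
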