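"""Lon/lat raster grids, layers and stacks.

All stages of the pipeline share one raster convention:

* WGS84 geographic coordinates in decimal degrees, square cells.
* Cell (0, 0) is the north-west cell; rows increase southward.
* Cells are half-open ``[edge, edge + cell_size)``: a point exactly on a
  shared edge belongs to the cell to the south/east.
* Nodata is represented internally as ``NaN`` and handled by masking; any
  arithmetic with a nodata operand yields nodata.  The ``nodata`` sentinel
  on :class:`GridSpec` is only used at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridSpec",
    "RasterLayer",
    "RasterStack",
    "resample_to",
    "collinearity_screen",
    "CollinearityReport",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; at least 1 each.
    lon_origin
        Longitude of the west edge of the grid, in [-180, 180).
    lat_origin
        Latitude of the north edge of the grid.
    cell_size
        Square cell size in degrees (e.g. ``2.5 / 60`` for 2.5 arc-minutes).
    nodata
        Sentinel written to files for missing cells; in memory nodata is NaN.
    """

    n_rows: int
    n_cols: int
    lon_origin: float
    lat_origin: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not (-180.0 <= self.lon_origin < 180.0):
            raise ValueError(f"lon_origin {self.lon_origin} outside [-180, 180)")
        if self.lat_origin > 90.0:
            raise ValueError(f"lat_origin {self.lat_origin} above the pole")
        if self.lat_origin - self.n_rows * self.cell_size < -90.0 - 1e-9:
            raise ValueError("grid extends south of -90 degrees latitude")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_origin + self.cell_size * np.arange(self.n_cols + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        """North-to-south latitude edges (length n_rows + 1)."""
        return self.lat_origin - self.cell_size * np.arange(self.n_rows + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_origin + self.cell_size * (np.arange(self.n_cols) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        """North-to-south latitude cell centers."""
        return self.lat_origin - self.cell_size * (np.arange(self.n_rows) + 0.5)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the grid's bounding box."""
        return (
            self.lon_origin,
            self.lon_origin + self.n_cols * self.cell_size,
            self.lat_origin - self.n_rows * self.cell_size,
            self.lat_origin,
        )

    def point_to_cell(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col) by the half-open convention.

        Uses ``floor((coord - origin) / cell_size)``; the returned indices
        may lie outside the grid — use :meth:`contains` to filter.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_origin) / self.cell_size).astype(int)
        row = np.floor((self.lat_origin - lat) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.point_to_cell(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon_origin + (col + 0.5) * self.cell_size
        lat = self.lat_origin - (row + 0.5) * self.cell_size
        return lon, lat


@dataclass
class RasterLayer:
    """One named predictor field on a :class:`GridSpec`; NaN marks nodata."""

    grid: GridSpec
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean nodata mask (True where missing)."""
        return np.isnan(self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, values, self.name if name is None else name, self.units)


class RasterStack:
    """An ordered, uniquely named collection of layers on one grid."""

    def __init__(self, layers: Iterable[RasterLayer]):
        layers = list(layers)
        if not layers:
            raise ValueError("stack needs at least one layer")
        self.grid = layers[0].grid
        self._layers: dict[str, RasterLayer] = {}
        for lyr in layers:
            if lyr.grid != self.grid:
                raise ValueError(f"layer {lyr.name!r} is on a different grid")
            if not lyr.name:
                raise ValueError("stack layers must be named")
            if lyr.name in self._layers:
                raise ValueError(f"duplicate layer name {lyr.name!r}")
            self._layers[lyr.name] = lyr

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[RasterLayer]:
        return iter(self._layers.values())

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> RasterLayer:
        return self._layers[name]

    def subset(self, names: Iterable[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])

    def add(self, layer: RasterLayer) -> "RasterStack":
        return RasterStack(list(self) + [layer])

    def to_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) array in stack order."""
        return np.stack([lyr.values for lyr in self], axis=0)

    @property
    def valid_mask(self) -> np.ndarray:
        """True where every layer has data (complement of the union nodata mask)."""
        return ~np.any(np.isnan(self.to_array()), axis=0)

    def values_at_cells(self, rows, cols) -> pd.DataFrame:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return pd.DataFrame(
            {name: self._layers[name].values[rows, cols] for name in self.names}
        )


def _interpolator(layer: RasterLayer, method: str) -> RegularGridInterpolator:
    # RegularGridInterpolator wants ascending axes; latitude runs north->south.
    lat_asc = layer.grid.lat_centers[::-1]
    vals = layer.values[::-1, :]
    return RegularGridInterpolator(
        (lat_asc, layer.grid.lon_centers),
        vals,
        method=method,
        bounds_error=False,
        fill_value=np.nan,
    )


def resample_to(layer: RasterLayer, target: GridSpec, method: str = "bilinear") -> RasterLayer:
    """Resample a layer onto a target grid.

    ``bilinear`` is appropriate for continuous fields, ``nearest`` for
    categorical/binary ones.  Nodata propagates: a bilinear cell with any
    nodata support becomes nodata, and cells outside the source support are
    nodata.  Resampling onto the source grid itself is the identity.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    if target == layer.grid:
        return RasterLayer(target, layer.values.copy(), layer.name, layer.units)
    s = layer.grid.extent
    t = target.extent
    if s[0] >= t[1] or t[0] >= s[1] or s[2] >= t[3] or t[2] >= s[3]:
        raise ValueError("source and target grids do not overlap spatially")
    interp = _interpolator(layer, "linear" if method == "bilinear" else "nearest")
    lon, lat = np.meshgrid(target.lon_centers, target.lat_centers)
    out = interp(np.column_stack([lat.ravel(), lon.ravel()])).reshape(target.shape)
    return RasterLayer(target, out, layer.name, layer.units)


@dataclass
class CollinearityReport:
    """Pairwise Pearson correlations between stack layers over shared valid cells."""

    r: pd.DataFrame
    threshold: float
    n_cells: int
    flagged: list[tuple[str, str, float]] = field(default_factory=list)


def collinearity_screen(stack: RasterStack, threshold: float = 0.7) -> CollinearityReport:
    """Screen predictors for collinearity with pairwise Pearson r.

    Computed over cells valid in *all* layers.  Pairs with ``|r| >=
    threshold`` are flagged; the report is advisory — no layer is dropped
    automatically, predictor choice stays a configuration decision.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if len(stack) < 2:
        raise ValueError("need at least two layers to screen")
    valid = stack.valid_mask
    if valid.sum() < 2:
        raise ValueError("fewer than 2 cells valid in all layers")
    data = pd.DataFrame({name: stack[name].values[valid] for name in stack.names})
    r = data.corr(method="pearson")
    names = stack.names
    flagged = [
        (names[i], names[j], float(r.iloc[i, j]))
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(r.iloc[i, j]) >= threshold
    ]
    return CollinearityReport(r=r, threshold=threshold, n_cells=int(valid.sum()), flagged=flagged)
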