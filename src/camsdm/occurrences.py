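"""Occurrence ingestion, validity filtering, spatial thinning, extraction.

The thinning rule caps records per 1-degree grid cell (default 5) to
reduce the collection bias typical of aggregated biodiversity archives:
heavily surveyed regions would otherwise dominate both model fitting and
the climate envelope that drives pseudo-absence placement.  The 1-degree
lattice is anchored at integer degrees; selection inside an over-full
cell is uniform random under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterStack
from .seeds import derive_seed

__all__ = ["OccurrenceSet", "basic_clean", "thin_per_cell", "extract_predictors"]

# Darwin-Core-ish column aliases accepted on CSV ingest
_LON_ALIASES = ("lon", "longitude", "decimalLongitude", "decimallongitude", "x")
_LAT_ALIASES = ("lat", "latitude", "decimalLatitude", "decimallatitude", "y")


@dataclass
class OccurrenceSet:
    """Point records of one species: columns record_id, lon, lat.

    The container itself is lenient about coordinate validity so raw
    archive downloads can be loaded; :func:`basic_clean` enforces ranges.
    Duplicate record ids are rejected.
    """

    species: str
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["record_id", "lon", "lat"]))

    def __post_init__(self) -> None:
        missing = {"record_id", "lon", "lat"} - set(self.table.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns {sorted(missing)}")
        if self.table["record_id"].duplicated().any():
            raise ValueError("duplicated record_id")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lon(self) -> np.ndarray:
        return self.table["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.table["lat"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, species: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        lon_col = next((c for c in _LON_ALIASES if c in df.columns), None)
        lat_col = next((c for c in _LAT_ALIASES if c in df.columns), None)
        if lon_col is None or lat_col is None:
            raise ValueError("CSV has no recognisable longitude/latitude columns")
        if species is None:
            species = str(df["species"].iloc[0]) if "species" in df.columns and len(df) else ""
        out = pd.DataFrame(
            {
                "record_id": df["record_id"] if "record_id" in df.columns else np.arange(len(df)),
                "lon": pd.to_numeric(df[lon_col], errors="coerce"),
                "lat": pd.to_numeric(df[lat_col], errors="coerce"),
            }
        )
        return cls(species=species, table=out)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def basic_clean(occ: OccurrenceSet, duplicate_cap: int = 1) -> OccurrenceSet:
    """Drop records with invalid coordinates and cap exact duplicates.

    Removed: missing/non-finite coordinates, lon outside [-180, 180), lat
    outside [-90, 90], and the exact (0, 0) point (a common database
    placeholder).  At most ``duplicate_cap`` records are kept per exact
    coordinate pair, lowest record_id first — fully deterministic.

    This is a deliberately reduced validity filter; full archive-cleaning
    protocols (institution coordinates, country centroids, sea tests) are
    out of scope and should be applied upstream if needed.
    """
    t = occ.table
    lon = pd.to_numeric(t["lon"], errors="coerce")
    lat = pd.to_numeric(t["lat"], errors="coerce")
    keep = (
        np.isfinite(lon)
        & np.isfinite(lat)
        & (lon >= -180.0)
        & (lon < 180.0)
        & (lat >= -90.0)
        & (lat <= 90.0)
        & ~((lon == 0.0) & (lat == 0.0))
    )
    out = t[keep.to_numpy(dtype=bool)].copy()
    out = out.sort_values("record_id")
    out = out.groupby(["lon", "lat"], sort=False).head(duplicate_cap)
    out = out.sort_values("record_id").reset_index(drop=True)
    if out.empty:
        warnings.warn(f"basic_clean removed every record for {occ.species!r}", stacklevel=2)
    return OccurrenceSet(occ.species, out)


def thin_per_cell(
    occ: OccurrenceSet,
    cell_size: float = 1.0,
    max_per_cell: int = 5,
    seed: int = 0,
) -> OccurrenceSet:
    """Retain at most ``max_per_cell`` records per ``cell_size``-degree cell.

    The lattice is anchored at integer multiples of ``cell_size`` from the
    (0, 0) graticule.  Cells at or below the cap are untouched, so the
    operation is idempotent; over-full cells are subsampled uniformly at
    random under a per-cell seed derived from ``seed``.  Output rows are
    ordered by record_id.
    """
    if max_per_cell < 1:
        raise ValueError("max_per_cell must be >= 1")
    t = occ.table
    if t.empty:
        return OccurrenceSet(occ.species, t.copy())
    cx = np.floor(t["lon"].to_numpy(dtype=float) / cell_size).astype(int)
    cy = np.floor(t["lat"].to_numpy(dtype=float) / cell_size).astype(int)
    keep_idx: list[np.ndarray] = []
    df = t.assign(_cx=cx, _cy=cy)
    for (kx, ky), sub in df.groupby(["_cx", "_cy"], sort=True):
        if len(sub) <= max_per_cell:
            keep_idx.append(sub.index.to_numpy())
        else:
            rng = np.random.default_rng(derive_seed(seed, "thin", kx, ky))
            keep_idx.append(rng.choice(sub.index.to_numpy(), size=max_per_cell, replace=False))
    kept = df.loc[np.concatenate(keep_idx), ["record_id", "lon", "lat"]]
    kept = kept.sort_values("record_id").reset_index(drop=True)
    return OccurrenceSet(occ.species, kept)


def extract_predictors(
    points: OccurrenceSet | pd.DataFrame, stack: RasterStack
) -> tuple[pd.DataFrame, int]:
    """Read predictor values at the cell containing each point.

    No interpolation: each point takes the value of its containing cell
    under the half-open convention.  Points outside the grid or on a cell
    where any layer is nodata are dropped; the drop count is returned.

    Returns ``(table, n_dropped)`` where ``table`` has columns
    ``lon, lat`` plus one column per stack layer in stack order.
    """
    if isinstance(points, OccurrenceSet):
        lon, lat = points.lon, points.lat
    else:
        lon = points["lon"].to_numpy(dtype=float)
        lat = points["lat"].to_numpy(dtype=float)
    grid = stack.grid
    inside = grid.contains(lon, lat)
    row, col = grid.point_to_cell(lon[inside], lat[inside])
    values = stack.values_at_cells(row, col)
    valid = ~values.isna().any(axis=1).to_numpy()
    table = pd.DataFrame({"lon": lon[inside][valid], "lat": lat[inside][valid]})
    for name in stack.names:
        table[name] = values.loc[valid, name].to_numpy()
    n_dropped = int(len(lon) - len(table))
    if len(table) == 0:
        raise ValueError(f"all {len(lon)} points fell outside the grid or on nodata")
    return table.reset_index(drop=True), n_dropped
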