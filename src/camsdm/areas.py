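"""Binary suitability maps, latitude-aware area accounting, deviation maps.

Grid cells on a lon/lat raster shrink toward the poles, so suitable-area
totals must weight each cell by its spherical area
``R^2 * dlambda * (sin(phi_top) - sin(phi_bottom))`` rather than count
cells.  A spherical Earth with R = 6371 km is used; at the 3-significant-
figure precision of continental totals the ellipsoidal correction is
immaterial.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, RasterLayer

__all__ = ["binarize", "cell_area_layer", "suitable_area", "deviation_map", "binary_change_map"]

EARTH_RADIUS_KM = 6371.0


def binarize(suitability: RasterLayer, cutoff: float) -> RasterLayer:
    """Threshold a continuous suitability map: 1 iff value >= cutoff.

    The tie-to-positive convention is shared with the evaluation module.
    Nodata propagates.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0, 1]")
    with np.errstate(invalid="ignore"):
        out = (suitability.values >= cutoff).astype(float)
    out[np.isnan(suitability.values)] = np.nan
    return RasterLayer(suitability.grid, out, f"{suitability.name}_binary")


def cell_area_layer(grid: GridSpec, earth_radius_km: float = EARTH_RADIUS_KM) -> RasterLayer:
    """Spherical cell areas in km²: constant along rows, shrinking poleward."""
    dlon = np.deg2rad(grid.cell_size)
    lat_edges = np.deg2rad(grid.lat_edges)  # north -> south
    band = np.sin(lat_edges[:-1]) - np.sin(lat_edges[1:])  # per-row band height
    row_area = earth_radius_km**2 * dlon * band
    values = np.repeat(row_area[:, None], grid.n_cols, axis=1)
    return RasterLayer(grid, values, "cell_area", "km2")


def suitable_area(
    binary: RasterLayer, areas: RasterLayer, mask: RasterLayer | None = None
) -> float:
    """Total area (million km²) of cells flagged 1, optionally within a mask."""
    if binary.grid != areas.grid:
        raise ValueError("binary and area layers are on different grids")
    sel = binary.values == 1
    if mask is not None:
        if mask.grid != binary.grid:
            raise ValueError("mask is on a different grid")
        sel &= mask.values == 1
    return float(np.nansum(areas.values[sel]) / 1e6)


def deviation_map(scenario: RasterLayer, baseline: RasterLayer) -> RasterLayer:
    """Signed difference of continuous suitability: scenario - baseline.

    Positive cells are more suitable under the scenario than under the
    baseline.  Nodata in either input propagates.
    """
    if scenario.grid != baseline.grid:
        raise ValueError("scenario and baseline are on different grids")
    return RasterLayer(
        scenario.grid,
        scenario.values - baseline.values,
        f"deviation_{scenario.name}_vs_{baseline.name}",
    )


def binary_change_map(scenario: RasterLayer, baseline: RasterLayer) -> RasterLayer:
    """Categorical change between two binary maps: +1 gain, -1 loss, 0 stable."""
    if scenario.grid != baseline.grid:
        raise ValueError("scenario and baseline are on different grids")
    out = scenario.values - baseline.values
    return RasterLayer(scenario.grid, out, "binary_change", "gain/loss")
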