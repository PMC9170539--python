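"""Raster file I/O: GeoTIFF (band 1), ESRI ASCII grid, NetCDF monthly series.

GeoTIFFs are written with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) so other GIS software can
place them; only north-up lon/lat grids are accepted on read — files in
other coordinate systems are rejected rather than silently reprojected.
Monthly precipitation series travel either as NetCDF3 (dimensions
``time, lat, lon``) or as a directory of GeoTIFFs named ``YYYY-MM``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

from .grid import GridSpec, RasterLayer, RasterStack
from .indices import MonthlyPrecipSeries

__all__ = [
    "write_geotiff",
    "read_geotiff",
    "write_ascii_grid",
    "read_ascii_grid",
    "read_stack",
    "write_monthly_netcdf",
    "read_monthly_netcdf",
    "read_monthly_geotiff_dir",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(layer: RasterLayer, path) -> None:
    """Write a single-band float64 GeoTIFF; NaN cells carry the nodata tag."""
    g = layer.grid
    vals = layer.values.copy()
    vals[np.isnan(vals)] = g.nodata
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.lon_origin, g.lat_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(g.nodata)),
    ]
    tifffile.imwrite(str(path), vals, extratags=extratags)


def read_geotiff(path, name: str | None = None, units: str = "") -> RasterLayer:
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        vals = np.asarray(page.asarray(), dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        if abs(sx - sy) > 1e-12:
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) not supported")
        if tuple(tie[:3]) != (0.0, 0.0, 0.0):
            raise ValueError(f"{path}: tiepoint not at the raster origin")
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    grid = GridSpec(
        n_rows=vals.shape[0],
        n_cols=vals.shape[1],
        lon_origin=float(tie[3]),
        lat_origin=float(tie[4]),
        cell_size=float(sx),
        nodata=nodata,
    )
    vals[vals == nodata] = np.nan
    return RasterLayer(grid, vals, name or path.stem, units)


def write_ascii_grid(layer: RasterLayer, path) -> None:
    """Write an ESRI ASCII grid (.asc), a plain-text raster format."""
    g = layer.grid
    lat_min = g.lat_origin - g.n_rows * g.cell_size
    vals = layer.values.copy()
    vals[np.isnan(vals)] = g.nodata
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.lon_origin:.17g}\n"
        f"yllcorner {lat_min:.17g}\n"
        f"cellsize {g.cell_size:.17g}\n"
        f"NODATA_value {g.nodata:.17g}\n"
    )
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path, name: str | None = None, units: str = "") -> RasterLayer:
    path = Path(path)
    text = path.read_text().split("\n")
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    vals = np.loadtxt(text[i:][: int(header["nrows"])], dtype=float, ndmin=2)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        lon_origin=header["xllcorner"],
        lat_origin=header["yllcorner"] + header["nrows"] * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )
    vals[vals == nodata] = np.nan
    return RasterLayer(grid, vals, name or path.stem, units)


def _read_any(path, name: str | None = None) -> RasterLayer:
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt"):
        return read_ascii_grid(path, name)
    return read_geotiff(path, name)


def read_stack(manifest: dict[str, str | Path]) -> RasterStack:
    """Read a stack from a manifest mapping layer name -> raster path."""
    return RasterStack([_read_any(p, name) for name, p in manifest.items()])


def write_monthly_netcdf(series: MonthlyPrecipSeries, path) -> None:
    """Write a monthly precipitation series as NetCDF3 (time, lat, lon)."""
    g = series.grid
    n_years = series.values.shape[0]
    time = np.arange(n_years * 12)
    ds = xr.Dataset(
        {
            "pr": (
                ("time", "lat", "lon"),
                series.values.reshape(n_years * 12, g.n_rows, g.n_cols),
            )
        },
        coords={
            "time": time,
            "lat": g.lat_centers,
            "lon": g.lon_centers,
            "year": ("time", np.repeat(series.years, 12)),
            "month": ("time", np.tile(np.arange(1, 13), n_years)),
        },
        attrs={"start_year": int(series.start_year), "cell_size": g.cell_size},
    )
    ds["pr"].attrs["units"] = "mm/month"
    ds.to_netcdf(str(path), engine="scipy", format="NETCDF3_64BIT")


def read_monthly_netcdf(path, nodata: float = -9999.0) -> MonthlyPrecipSeries:
    with xr.open_dataset(str(path), engine="scipy") as ds:
        pr = ds["pr"].values.astype(float)
        lat = ds["lat"].values
        lon = ds["lon"].values
        start_year = int(ds.attrs["start_year"])
    if lat[0] < lat[-1]:  # stored south-up: flip to north-up
        lat = lat[::-1]
        pr = pr[:, ::-1, :]
    cell = float(lon[1] - lon[0]) if lon.size > 1 else float(lat[0] - lat[1])
    grid = GridSpec(
        n_rows=lat.size,
        n_cols=lon.size,
        lon_origin=float(lon[0] - cell / 2),
        lat_origin=float(lat[0] + cell / 2),
        cell_size=cell,
        nodata=nodata,
    )
    n_years = pr.shape[0] // 12
    values = pr[: n_years * 12].reshape(n_years, 12, grid.n_rows, grid.n_cols)
    return MonthlyPrecipSeries(grid=grid, start_year=start_year, values=values)


_YM = re.compile(r"(\d{4})-(\d{2})")


def read_monthly_geotiff_dir(directory) -> MonthlyPrecipSeries:
    """Read a directory of GeoTIFFs named ``YYYY-MM*`` into a monthly series."""
    directory = Path(directory)
    found: dict[tuple[int, int], Path] = {}
    for p in sorted(directory.iterdir()):
        m = _YM.match(p.stem)
        if m:
            found[(int(m.group(1)), int(m.group(2)))] = p
    if not found:
        raise ValueError(f"no YYYY-MM rasters found in {directory}")
    years = sorted({y for y, _ in found})
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError("years are not a contiguous range")
    first = read_geotiff(found[min(found)])
    grid = first.grid
    values = np.full((len(years), 12, grid.n_rows, grid.n_cols), np.nan)
    for (y, mth), p in found.items():
        lyr = read_geotiff(p)
        if lyr.grid != grid:
            raise ValueError(f"{p}: grid differs from the first raster")
        values[y - years[0], mth - 1] = lyr.values
    return MonthlyPrecipSeries(grid=grid, start_year=years[0], values=values)
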