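"""Synthetic climate landscapes, a known niche, and biased presence samples.

Every pipeline stage can be exercised without any external download: this
module fabricates (a) spatially smooth, mutually correlated climate
fields on a lon/lat grid, (b) a multi-year monthly precipitation record
with controllable inter-annual variability, (c) a *known* species–climate
response (the "truth") from which presence points are sampled, optionally
with observer bias.  Because the truth is known, the pipeline's output
can be checked for niche recovery: does the fitted ensemble rank the
truly dominant predictor first and reproduce the true suitable region?

The default landscape (:func:`default_landscape`) is the desk-scale
stand-in for a global 2.5-arcmin analysis: a 64x64 quarter-degree grid
with the four standard bioclim-style predictors plus the derived index
inputs (PET, AET, cloud cover), a niche dominated by minimum temperature
of the coldest month with annual precipitation secondary, and 500
spatially biased presences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import GridSpec, RasterLayer, RasterStack
from .indices import MonthlyPrecipSeries
from .occurrences import OccurrenceSet
from .seeds import derive_seed

__all__ = [
    "FieldParams",
    "LogisticResponse",
    "GaussianResponse",
    "FlatResponse",
    "SyntheticTruth",
    "gen_smooth_fields",
    "gen_monthly_precip",
    "true_suitability",
    "sample_presences",
    "default_landscape",
    "Landscape",
]


@dataclass(frozen=True)
class FieldParams:
    """Recipe for a set of smooth correlated random fields."""

    grid: GridSpec
    means: tuple[float, ...]
    sds: tuple[float, ...]
    correlation_length: float = 5.0  # cells; 0 = white noise
    inter_field_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sds):
            raise ValueError("means and sds must have equal length")
        if any(s < 0 for s in self.sds):
            raise ValueError("sds must be >= 0")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        if not (0.0 <= self.inter_field_correlation < 1.0):
            raise ValueError(
                "inter_field_correlation must be in [0, 1): the common-factor "
                "construction cannot realise equal pairwise negative correlation"
            )


def _smooth_unit_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if length > 0:
        z = gaussian_filter(z, sigma=length, mode="wrap")
    sd = z.std()
    return z / sd if sd > 0 else z


def gen_smooth_fields(params: FieldParams, names: list[str]) -> RasterStack:
    """Generate named smooth random fields with approximate cross-correlation.

    Each field is low-pass-filtered white noise standardised to the
    requested mean/sd.  Pairwise correlation ``rho`` is imposed through a
    shared common factor: ``f_i = sqrt(rho) * f0 + sqrt(1-rho) * g_i``.
    Deterministic under ``params.seed``.
    """
    if len(names) != len(params.means):
        raise ValueError("one name per field required")
    rng = np.random.default_rng(params.seed)
    rho = params.inter_field_correlation
    shape = params.grid.shape
    common = _smooth_unit_field(rng, shape, params.correlation_length)
    layers = []
    for name, mean, sd in zip(names, params.means, params.sds):
        own = _smooth_unit_field(rng, shape, params.correlation_length)
        unit = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * own
        unit = unit / unit.std() if unit.std() > 0 else unit
        layers.append(RasterLayer(params.grid, mean + sd * unit, name))
    return RasterStack(layers)


def gen_monthly_precip(
    grid: GridSpec,
    n_years: int,
    mean_annual,
    interannual_log_sd: float = 0.4,
    seasonality: float = 0.6,
    seed: int = 0,
    start_year: int = 1960,
) -> MonthlyPrecipSeries:
    """Multi-year monthly precipitation with lognormal inter-annual totals.

    Per cell, each year's total is ``mean_annual * exp(sd * Z)`` with
    ``Z ~ N(0,1)`` — lognormal with median ``mean_annual`` and log-sd
    ``interannual_log_sd``.  The total is spread over months by a fixed
    sinusoidal seasonal profile with relative amplitude ``seasonality``
    (0 = uniform months, 1 = strongly peaked).  All values are >= 0.

    ``mean_annual`` may be a scalar or a :class:`RasterLayer` (mm/yr).
    """
    if n_years < 2:
        raise ValueError("need at least 2 years")
    if not (0.0 <= seasonality <= 1.0):
        raise ValueError("seasonality must be in [0, 1]")
    if isinstance(mean_annual, RasterLayer):
        if mean_annual.grid != grid:
            raise ValueError("mean_annual layer is on a different grid")
        base = mean_annual.values
    else:
        base = np.full(grid.shape, float(mean_annual))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_years, *grid.shape))
    totals = base[None, :, :] * np.exp(interannual_log_sd * z)
    months = np.arange(12)
    profile = 1.0 + seasonality * np.cos(2.0 * np.pi * (months - 0.5) / 12.0)
    profile = profile / profile.sum()
    values = totals[:, None, :, :] * profile[None, :, None, None]
    values[:, :, np.isnan(base)] = np.nan
    return MonthlyPrecipSeries(grid=grid, start_year=start_year, values=values)


@dataclass(frozen=True)
class LogisticResponse:
    """Sigmoid response: 1 / (1 + exp(-slope * (x - midpoint)))."""

    midpoint: float
    slope: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.slope * (x - self.midpoint)))


@dataclass(frozen=True)
class GaussianResponse:
    """Bell response: exp(-0.5 ((x - center)/width)^2), peaking at 1."""

    center: float
    width: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((x - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class FlatResponse:
    """No dependence on the predictor (factor 1 everywhere)."""

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.ones_like(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class SyntheticTruth:
    """Known species–climate relationship: product of per-predictor responses."""

    responses: dict[str, object]
    prevalence_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_scale <= 1.0):
            raise ValueError("prevalence_scale must be in (0, 1]")
        if all(isinstance(r, FlatResponse) for r in self.responses.values()):
            raise ValueError("at least one response must be non-flat")


def true_suitability(stack: RasterStack, truth: SyntheticTruth) -> RasterLayer:
    """Pointwise product of response curves, scaled by prevalence."""
    missing = [n for n in truth.responses if n not in stack]
    if missing:
        raise KeyError(f"stack is missing predictors {missing}")
    out = np.full(stack.grid.shape, truth.prevalence_scale)
    for name, response in truth.responses.items():
        out = out * response(stack[name].values)
    return RasterLayer(stack.grid, out, "true_suitability")


def sample_presences(
    suitability: RasterLayer,
    n_target: int,
    bias: RasterLayer | None = None,
    seed: int = 0,
    species: str = "synthetic_species",
) -> OccurrenceSet:
    """Sample presence points with probability proportional to suitability x bias.

    Cells are drawn with replacement with weight ``suitability * bias``
    (bias defaults to uniform); each record is jittered uniformly within
    its cell so downstream cell conventions are exercised off centers.
    Exactly ``n_target`` records are produced, deterministically under
    ``seed``.
    """
    grid = suitability.grid
    w = np.nan_to_num(suitability.values, nan=0.0).copy()
    if bias is not None:
        if bias.grid != grid:
            raise ValueError("bias layer is on a different grid")
        w = w * np.nan_to_num(bias.values, nan=0.0)
    w = np.clip(w, 0.0, None).ravel()
    if w.sum() <= 0:
        raise ValueError("all sampling weights are zero")
    rng = np.random.default_rng(seed)
    flat = rng.choice(w.size, size=n_target, replace=True, p=w / w.sum())
    rows, cols = np.unravel_index(flat, grid.shape)
    jitter_lon = rng.uniform(0.0, grid.cell_size, size=n_target)
    jitter_lat = rng.uniform(0.0, grid.cell_size, size=n_target)
    lon = grid.lon_origin + cols * grid.cell_size + jitter_lon
    lat = grid.lat_origin - rows * grid.cell_size - jitter_lat
    table = pd.DataFrame({"record_id": np.arange(n_target), "lon": lon, "lat": lat})
    return OccurrenceSet(species=species, table=table)


@dataclass
class Landscape:
    """A complete synthetic study system: predictors, truth, and samples."""

    stack: RasterStack  # all predictor layers incl. derived-index inputs
    truth: SyntheticTruth
    suitability: RasterLayer
    occurrences: OccurrenceSet
    precip_series: MonthlyPrecipSeries
    bias: RasterLayer


# Study conditions of the default desk-scale system.  64x64 quarter-degree
# grid (a 16-degree window), four bioclim-style predictors with mild
# cross-correlation, a 58-year monthly rainfall record, and 500 biased
# presences: min temperature of the coldest month dominates the niche,
# annual precipitation is secondary.
DEFAULT_GRID = GridSpec(n_rows=64, n_cols=64, lon_origin=10.0, lat_origin=-4.0, cell_size=0.25)

DEFAULT_FIELDS = {
    "mean_diurnal_range": (12.0, 3.0),  # deg C
    "min_temp_coldest_month": (8.0, 6.0),  # deg C
    "annual_precip": (500.0, 220.0),  # mm/yr
    "precip_seasonality": (60.0, 25.0),  # CV percent
    "pet": (1400.0, 250.0),  # mm/yr
    "aet": (700.0, 200.0),  # mm/yr
    "cloud_cover": (45.0, 15.0),  # percent
}

DEFAULT_TRUTH = SyntheticTruth(
    responses={
        "min_temp_coldest_month": LogisticResponse(midpoint=10.0, slope=1.2),
        "annual_precip": GaussianResponse(center=520.0, width=320.0),
    },
    prevalence_scale=1.0,
)


def default_landscape(seed: int = 0, n_presences: int = 500, n_years: int = 58) -> Landscape:
    """Build the canonical synthetic study system, fully seeded.

    The same master seed drives field generation, the rainfall record,
    the observer-bias field, and presence sampling through independent
    derived sub-seeds.
    """
    names = list(DEFAULT_FIELDS)
    params = FieldParams(
        grid=DEFAULT_GRID,
        means=tuple(v[0] for v in DEFAULT_FIELDS.values()),
        sds=tuple(v[1] for v in DEFAULT_FIELDS.values()),
        correlation_length=5.0,
        inter_field_correlation=0.3,
        seed=derive_seed(seed, "fields"),
    )
    stack = gen_smooth_fields(params, names)
    # physical floors: rainfall, PET/AET and cloud cover cannot be negative
    clipped = []
    for lyr in stack:
        if lyr.name in ("annual_precip", "pet", "aet"):
            clipped.append(lyr.with_values(np.clip(lyr.values, 1.0, None)))
        elif lyr.name == "cloud_cover":
            clipped.append(lyr.with_values(np.clip(lyr.values, 0.0, 100.0)))
        else:
            clipped.append(lyr)
    stack = RasterStack(clipped)
    suit = true_suitability(stack, DEFAULT_TRUTH)
    # observer bias: a smooth positive field, like accessibility gradients
    bias_field = gen_smooth_fields(
        FieldParams(
            grid=DEFAULT_GRID,
            means=(0.0,),
            sds=(1.0,),
            correlation_length=8.0,
            seed=derive_seed(seed, "bias"),
        ),
        ["bias"],
    )["bias"]
    bias = bias_field.with_values(np.exp(bias_field.values), "bias")
    occurrences = sample_presences(
        suit, n_presences, bias=bias, seed=derive_seed(seed, "presences")
    )
    precip = gen_monthly_precip(
        DEFAULT_GRID,
        n_years=n_years,
        mean_annual=stack["annual_precip"],
        interannual_log_sd=0.4,
        seasonality=0.6,
        seed=derive_seed(seed, "precip"),
    )
    return Landscape(
        stack=stack,
        truth=DEFAULT_TRUTH,
        suitability=suit,
        occurrences=occurrences,
        precip_series=precip,
        bias=bias,
    )
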