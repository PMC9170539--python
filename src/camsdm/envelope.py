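"""Surface range envelope (BIOCLIM-style) model and pseudo-absence design.

The surface range envelope (SRE) is the classic presence-only climate
model: for each predictor, take the ``[q, 1-q]`` empirical quantile
interval of the values observed at presences (default ``q = 0.025``,
roughly a 95% tolerance interval); a cell is "inside the envelope" iff
every predictor falls within its interval.

Pseudo-absences (PAs) are background points standing in for the absence
records that presence-only archives lack.  They are drawn uniformly,
without replacement, from cells that (a) have valid data in every
predictor, (b) lie *outside* the envelope, and (c) hold no presence —
so PA labels can never contradict a presence at the same cell.  Several
independent realizations (default 5) are drawn so downstream ensembles
do not hinge on one background sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterLayer, RasterStack
from .occurrences import OccurrenceSet
from .seeds import derive_seed

__all__ = ["SREModel", "PARealization", "fit_sre", "sre_predict", "sample_pseudoabsences"]


@dataclass(frozen=True)
class SREModel:
    """Per-predictor climate bounds at a presence quantile."""

    bounds: dict[str, tuple[float, float]]
    quantile: float

    @property
    def predictors(self) -> list[str]:
        return list(self.bounds)


@dataclass
class PARealization:
    """One seeded draw of pseudo-absence points (cell centers, label 0)."""

    index: int
    seed: int
    points: pd.DataFrame  # columns: lon, lat, row, col


def fit_sre(presence_values: pd.DataFrame, quantile: float = 0.025) -> SREModel:
    """Fit per-predictor bounds from presence values only.

    Bounds are the ``[q, 1-q]`` empirical quantiles with linear
    interpolation between order statistics.  ``quantile = 0`` gives the
    min–max envelope.
    """
    if not (0.0 <= quantile < 0.5):
        raise ValueError("quantile must be in [0, 0.5)")
    bounds: dict[str, tuple[float, float]] = {}
    for name in presence_values.columns:
        vals = presence_values[name].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError(f"predictor {name!r} has fewer than 2 presence values")
        lo, hi = np.quantile(vals, [quantile, 1.0 - quantile], method="linear")
        bounds[name] = (float(lo), float(hi))
    return SREModel(bounds=bounds, quantile=quantile)


def sre_predict(stack: RasterStack, model: SREModel) -> RasterLayer:
    """Binary envelope membership map: 1 iff every predictor is in bounds.

    Bounds are inclusive; nodata in any predictor propagates to nodata.
    """
    missing = [p for p in model.predictors if p not in stack]
    if missing:
        raise KeyError(f"stack is missing predictors {missing}")
    inside = np.ones(stack.grid.shape, dtype=float)
    invalid = np.zeros(stack.grid.shape, dtype=bool)
    for name, (lo, hi) in model.bounds.items():
        vals = stack[name].values
        invalid |= np.isnan(vals)
        with np.errstate(invalid="ignore"):
            inside *= ((vals >= lo) & (vals <= hi)).astype(float)
    inside[invalid] = np.nan
    return RasterLayer(stack.grid, inside, "sre_envelope", "binary")


def sample_pseudoabsences(
    stack: RasterStack,
    envelope: RasterLayer,
    presences: OccurrenceSet,
    n_per_realization: int,
    n_realizations: int = 5,
    seed: int = 0,
) -> list[PARealization]:
    """Draw seeded pseudo-absence realizations outside the envelope.

    Each realization samples ``n_per_realization`` cells uniformly without
    replacement from the eligible background (valid data, envelope = 0,
    not presence-occupied) and places the point at the cell center.
    Realizations use independent sub-seeds of ``seed`` and are mutually
    independent draws.
    """
    grid = stack.grid
    if envelope.grid != grid:
        raise ValueError("envelope grid differs from stack grid")
    eligible = stack.valid_mask & (envelope.values == 0)
    inside = grid.contains(presences.lon, presences.lat)
    prow, pcol = grid.point_to_cell(presences.lon[inside], presences.lat[inside])
    eligible[prow, pcol] = False
    rows, cols = np.nonzero(eligible)
    n_eligible = rows.size
    if n_eligible < n_per_realization:
        raise ValueError(
            f"only {n_eligible} eligible background cells for "
            f"{n_per_realization} pseudo-absences (short by {n_per_realization - n_eligible})"
        )
    out: list[PARealization] = []
    for k in range(1, n_realizations + 1):
        sub_seed = derive_seed(seed, "pa", k)
        rng = np.random.default_rng(sub_seed)
        pick = rng.choice(n_eligible, size=n_per_realization, replace=False)
        r, c = rows[pick], cols[pick]
        lon, lat = grid.cell_center(r, c)
        pts = pd.DataFrame({"lon": lon, "lat": lat, "row": r, "col": c})
        out.append(PARealization(index=k, seed=sub_seed, points=pts))
    return out
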