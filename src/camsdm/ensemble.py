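"""Performance-weighted ensembles, uncertainty maps, variable importance.

Individual runs are combined by a weighted mean of their suitability
predictions, with weights proportional to each member's held-out skill
(TSS by default, ROC optionally).  Members whose held-out ROC AUC does
not exceed 0.5 — no better than random — are excluded outright.  The
spread between members is summarised per cell as a coefficient of
variation (percent), the ensemble's uncertainty measure.

Variable importance follows the shuffle principle: permute one predictor
column, re-predict, and correlate shuffled with reference predictions.
Raw importance is ``1 - r`` averaged over shuffles — 0 means the
predictor has no influence, larger means more — clamped below at 0 and
standardized across predictors to percentages summing to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation
from .grid import RasterLayer
from .modeling import ModelRun
from .seeds import derive_seed

__all__ = [
    "EnsembleModel",
    "compute_weights",
    "weighted_mean_map",
    "cv_map",
    "ensemble_predict",
    "ensemble_evaluate",
    "variable_importance",
    "standardize_importance",
]


@dataclass
class EnsembleModel:
    """A weighted collection of fitted runs with its own cutoff and scores."""

    members: list[ModelRun]
    weights: np.ndarray
    weighting_metric: str = "tss"
    min_roc: float = 0.5
    ensemble_cutoff: float | None = None
    ensemble_scores: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return ensemble_predict(self.members, self.weights, table)


def compute_weights(
    members: list[ModelRun], metric: str = "tss", min_roc: float = 0.5
) -> np.ndarray:
    """Per-member weights proportional to held-out skill.

    Members with ROC AUC <= ``min_roc`` (strict inequality required to
    pass) get weight 0.  Negative TSS is clamped to 0 before
    normalisation.  If every included member has zero clamped score the
    included members share uniform weights.
    """
    if metric not in ("tss", "roc"):
        raise ValueError("metric must be 'tss' or 'roc'")
    if not members:
        raise ValueError("no members")
    roc = np.array([m.scores["roc_auc"] for m in members])
    included = roc > min_roc
    if not np.any(included):
        raise ValueError(f"no member has ROC AUC > {min_roc}")
    if metric == "tss":
        score = np.array([max(0.0, m.scores["tss"]) for m in members])
    else:
        score = roc.copy()
    score[~included] = 0.0
    total = score.sum()
    if total == 0:
        weights = included.astype(float) / included.sum()
    else:
        weights = score / total
    return weights


def weighted_mean_map(maps: list[RasterLayer], weights: np.ndarray) -> RasterLayer:
    """Per-cell convex combination of member maps; nodata propagates."""
    weights = np.asarray(weights, dtype=float)
    if len(maps) != len(weights):
        raise ValueError("one weight per map required")
    if abs(weights.sum() - 1.0) > 1e-12 or np.any(weights < 0):
        raise ValueError("weights must be non-negative and sum to 1")
    grid = maps[0].grid
    if any(m.grid != grid for m in maps):
        raise ValueError("maps are on different grids")
    stack = np.stack([m.values for m in maps], axis=0)
    out = np.tensordot(weights, stack, axes=1)  # NaN in any member -> NaN
    return RasterLayer(grid, out, "ensemble_weighted_mean")


def cv_map(maps: list[RasterLayer]) -> RasterLayer:
    """Coefficient of variation (percent) across members, per cell.

    Unweighted sample (n-1) standard deviation over unweighted mean,
    times 100; a zero mean is masked to nodata.
    """
    if len(maps) < 2:
        raise ValueError("CV needs at least 2 members")
    grid = maps[0].grid
    if any(m.grid != grid for m in maps):
        raise ValueError("maps are on different grids")
    stack = np.stack([m.values for m in maps], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    out = np.full(grid.shape, np.nan)
    ok = np.isfinite(mean) & (mean != 0)
    out[ok] = 100.0 * sd[ok] / mean[ok]
    return RasterLayer(grid, out, "ensemble_cv", "percent")


def ensemble_predict(members: list[ModelRun], weights: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    """Weighted mean of member predictions for rows with predictor columns."""
    preds = np.stack([m.predict(table) for m in members], axis=0)
    return np.asarray(weights) @ preds


def ensemble_evaluate(
    members: list[ModelRun],
    weights: np.ndarray,
    tables: list[pd.DataFrame],
) -> tuple[dict, float]:
    """Pooled-held-out evaluation of the ensemble.

    ``tables[i]`` is the supervised table member ``i`` was fitted on.
    For each member, the full ensemble predicts that member's held-out
    rows; the (label, prediction) pairs are pooled over members and
    scored once.  Returns ``(scores, cutoff)`` where scores holds TSS,
    ROC AUC, sensitivity and specificity at the TSS-optimal cutoff.
    """
    if len(members) != len(tables):
        raise ValueError("one table per member required")
    preds_all: list[np.ndarray] = []
    labels_all: list[np.ndarray] = []
    for m, table in zip(members, tables):
        held_out = table.iloc[m.test_idx]
        preds_all.append(ensemble_predict(members, weights, held_out))
        labels_all.append(held_out["label"].to_numpy())
    preds = np.concatenate(preds_all)
    labels = np.concatenate(labels_all)
    thr = evaluation.optimal_cutoff(preds, labels)
    scores = {
        "tss": thr.tss,
        "roc_auc": evaluation.roc_auc(preds, labels),
        "sensitivity": thr.sensitivity,
        "specificity": thr.specificity,
    }
    return scores, thr.cutoff


def variable_importance(
    ensemble: EnsembleModel,
    reference: pd.DataFrame,
    n_shuffles: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Shuffle-based importance of each predictor to the ensemble.

    For each predictor: permute its column (seeded), re-predict with the
    ensemble, take Pearson r against the reference predictions; raw
    importance is the mean of ``max(0, 1 - r)`` over ``n_shuffles``
    shuffles.  Raw values are standardized to percentages summing to 100.

    Returns a DataFrame indexed by predictor with columns ``raw`` and
    ``pct``.
    """
    if len(reference) < 3:
        raise ValueError("need at least 3 reference rows")
    feature_names = ensemble.members[0].feature_names
    ref_pred = ensemble.predict(reference)
    if np.std(ref_pred) == 0:
        raise ValueError("reference predictions have zero variance")
    raw = {}
    for j, name in enumerate(feature_names):
        vals = []
        for s in range(n_shuffles):
            rng = np.random.default_rng(derive_seed(seed, "shuffle", name, s))
            shuffled = reference.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            shuf_pred = ensemble.predict(shuffled)
            if np.std(shuf_pred) == 0:
                r = 0.0  # constant shuffled predictions share no signal
            else:
                r = float(np.corrcoef(ref_pred, shuf_pred)[0, 1])
            vals.append(max(0.0, 1.0 - r))
        raw[name] = float(np.mean(vals))
    table = pd.DataFrame({"raw": pd.Series(raw)})
    table["pct"] = standardize_importance(table["raw"])
    return table


def standardize_importance(raw: pd.Series) -> pd.Series:
    """Map raw importances to percentages summing to 100 (proportional)."""
    if (raw < 0).any():
        raise ValueError("raw importances must be >= 0")
    total = raw.sum()
    if total == 0:
        return raw * 0.0
    return 100.0 * raw / total
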