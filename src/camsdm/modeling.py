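"""Supervised dataset assembly and tree-ensemble learner runs.

One "run" is a single fitted learner: one algorithm (boosted regression
trees or random forest), one pseudo-absence realization, one repeat.
Repeats differ by the train/test split seed and the learner seed, which
is what makes averaging over repeats informative.  Splits are 60/40 by
default and stratified by label so the engineered 1:1 presence:PA
balance is preserved in both partitions; all skill scores are computed
on the held-out fraction only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split

from . import evaluation
from .envelope import PARealization
from .grid import RasterLayer, RasterStack
from .occurrences import extract_predictors

__all__ = [
    "ALGORITHMS",
    "DEFAULT_HYPERPARAMETERS",
    "LearnerSpec",
    "ModelRun",
    "make_dataset",
    "split_train_test",
    "fit_and_score",
    "project_map",
]

ALGORITHMS = ("boosted_trees", "random_forest")

# Documented defaults, in the spirit of "use the package defaults":
# a moderately sized forest and a shallow, moderately long boosting run.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "boosted_trees": {"n_estimators": 250, "learning_rate": 0.1, "max_depth": 3},
    "random_forest": {"n_estimators": 500, "min_samples_leaf": 1},
}


@dataclass(frozen=True)
class LearnerSpec:
    algorithm: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")

    def build(self):
        params = {**DEFAULT_HYPERPARAMETERS[self.algorithm], **self.hyperparameters}
        if self.algorithm == "boosted_trees":
            return GradientBoostingClassifier(random_state=self.seed, **params)
        return RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)


@dataclass
class ModelRun:
    """One fitted learner with its held-out scores and projection handle."""

    learner: LearnerSpec
    pa_index: int
    repeat_index: int
    feature_names: list[str] = field(default_factory=list)
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    model: object | None = None
    scores: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Continuous suitability in [0, 1] for rows with predictor columns."""
        if self.model is None:
            raise RuntimeError("run has not been fitted")
        X = table[self.feature_names]
        return self.model.predict_proba(X)[:, 1]


def make_dataset(
    presence_rows: pd.DataFrame, pa: PARealization, stack: RasterStack
) -> pd.DataFrame:
    """Presence + pseudo-absence supervised table for one PA realization.

    ``presence_rows`` must already carry predictor columns (from
    :func:`camsdm.occurrences.extract_predictors`); PA predictor values
    are extracted here.  Rows with any nodata predictor are dropped and
    the resulting class imbalance recorded in ``table.attrs``.
    Columns: lon, lat, label (presence=1, PA=0), then predictors in stack
    order.
    """
    if presence_rows.empty or pa.points.empty:
        raise ValueError("both presences and pseudo-absences must be non-empty")
    pres = presence_rows[["lon", "lat", *stack.names]].copy()
    pres.insert(2, "label", 1)
    pa_rows, n_dropped_pa = extract_predictors(pa.points, stack)
    pa_rows = pa_rows[["lon", "lat", *stack.names]].copy()
    pa_rows.insert(2, "label", 0)
    table = pd.concat([pres, pa_rows], ignore_index=True)
    table.attrs["pa_index"] = pa.index
    table.attrs["n_dropped_pa"] = n_dropped_pa
    table.attrs["imbalance"] = int(len(pres) - len(pa_rows))
    return table


def split_train_test(
    table: pd.DataFrame, train_fraction: float = 0.6, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified row-index split; proportions hold within one row per class."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1) — both partitions non-empty")
    labels = table["label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 rows to split")
    if counts.min() < 5:
        raise ValueError("need at least 5 rows per class for a meaningful split")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def fit_and_score(
    run: ModelRun, table: pd.DataFrame, train_fraction: float = 0.6, split_seed: int = 0
) -> ModelRun:
    """Fit the run's learner and score it on the held-out rows.

    Populates ``run.scores`` with TSS, ROC AUC, sensitivity, specificity
    and the TSS-optimal cutoff, all from the held-out fraction.
    """
    feature_names = [c for c in table.columns if c not in ("lon", "lat", "label")]
    run.feature_names = feature_names
    run.train_idx, run.test_idx = split_train_test(table, train_fraction, split_seed)
    y = table["label"].to_numpy()
    if len(np.unique(y[run.train_idx])) < 2:
        raise ValueError("training labels are single-class")
    model = run.learner.build()
    model.fit(table.iloc[run.train_idx][feature_names], y[run.train_idx])
    run.model = model
    preds = run.predict(table.iloc[run.test_idx])
    y_test = y[run.test_idx]
    thr = evaluation.optimal_cutoff(preds, y_test)
    run.scores = {
        "tss": thr.tss,
        "roc_auc": evaluation.roc_auc(preds, y_test),
        "sensitivity": thr.sensitivity,
        "specificity": thr.specificity,
        "cutoff": thr.cutoff,
    }
    return run


def project_map(run: ModelRun, stack: RasterStack) -> RasterLayer:
    """Project a fitted run onto the stack: per-cell suitability in [0, 1]."""
    missing = [f for f in run.feature_names if f not in stack]
    if missing:
        raise KeyError(f"stack is missing layers {missing}")
    valid = stack.subset(run.feature_names).valid_mask
    rows, cols = np.nonzero(valid)
    X = stack.values_at_cells(rows, cols)[run.feature_names]
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = run.model.predict_proba(X)[:, 1]
    return RasterLayer(stack.grid, out, f"suitability_{run.learner.algorithm}_pa{run.pa_index}_rep{run.repeat_index}")
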