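"""Binary-skill evaluation: confusion counts, TSS, ROC AUC, optimal cutoff.

The true skill statistic, TSS = sensitivity + specificity - 1, is the
standard prevalence-insensitive skill score for presence/absence models;
ROC AUC is the probability that a random presence outranks a random
(pseudo-)absence under the model's continuous output (Mann–Whitney
formulation, ties counted one half).  The binary cutoff converting a
continuous suitability map into suitable/unsuitable is chosen to
maximise TSS, i.e. sensitivity + specificity.

Conventions fixed here and shared package-wide: a prediction exactly at
the cutoff counts as *positive*; candidate cutoffs are the midpoints
between adjacent distinct prediction values plus {0, 1}, which makes the
maximisation exact; cutoff ties resolve to the smallest cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "ThresholdResult", "confusion_at", "tss", "roc_auc", "optimal_cutoff"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.positives

    @property
    def specificity(self) -> float:
        return self.tn / self.negatives


@dataclass(frozen=True)
class ThresholdResult:
    cutoff: float
    tss: float
    sensitivity: float
    specificity: float


def _check_inputs(predictions, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.size < 1:
        raise ValueError("empty inputs")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0/1")
    return p, y.astype(int)


def confusion_at(predictions, labels, cutoff: float) -> ConfusionCounts:
    """Confusion counts at a cutoff; prediction >= cutoff is positive."""
    p, y = _check_inputs(predictions, labels)
    pred_pos = p >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & (y == 1))),
        fp=int(np.sum(pred_pos & (y == 0))),
        tn=int(np.sum(~pred_pos & (y == 0))),
        fn=int(np.sum(~pred_pos & (y == 1))),
    )


def tss(conf: ConfusionCounts) -> float:
    """True skill statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if conf.positives < 1 or conf.negatives < 1:
        raise ValueError("TSS needs at least one positive and one negative")
    return conf.sensitivity + conf.specificity - 1.0


def roc_auc(predictions, labels) -> float:
    """ROC AUC: P(random positive outranks random negative), ties = 1/2."""
    p, y = _check_inputs(predictions, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, p))


def optimal_cutoff(predictions, labels) -> ThresholdResult:
    """Cutoff maximising TSS over data-adaptive candidate thresholds.

    Candidates are midpoints between adjacent distinct sorted prediction
    values, plus 0 and 1.  Ties in TSS resolve to the smallest cutoff.
    """
    p, y = _check_inputs(predictions, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos < 1 or n_neg < 1:
        raise ValueError("optimal_cutoff needs both classes present")
    distinct = np.unique(p)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0]])
    candidates = np.unique(candidates)
    # vectorized confusion over all candidates
    pred_pos = p[None, :] >= candidates[:, None]
    tp = np.sum(pred_pos & (y == 1)[None, :], axis=1)
    tn = np.sum(~pred_pos & (y == 0)[None, :], axis=1)
    scores = tp / n_pos + tn / n_neg - 1.0
    best = int(np.argmax(scores))  # argmax takes the first (smallest) on ties
    sens = tp[best] / n_pos
    spec = tn[best] / n_neg
    return ThresholdResult(
        cutoff=float(candidates[best]),
        tss=float(sens + spec - 1.0),
        sensitivity=float(sens),
        specificity=float(spec),
    )
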