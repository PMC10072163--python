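"""ROC / Youden-index cutoff determination.

Used to set the copy-number threshold that separates polysomy from normal
copy number: samples are called positive when their MET copy number is at or
above a candidate threshold; the threshold maximising the Youden index
J = sensitivity + specificity - 1 is the cutoff. The AUC is computed by the
rank (Mann-Whitney) formulation with ties counted one half, and an optional
percentile bootstrap gives a confidence interval for it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EmptyDataError, ValidationError


@dataclass
class RocResult:
    """An ROC curve over candidate thresholds, with the Youden-optimal point.

    ``points`` is ordered by ascending threshold; candidate thresholds are
    the midpoints between consecutive sorted unique values plus one sentinel
    below and one above all values. When several thresholds achieve the
    maximal J, the smallest is returned (maximising sensitivity at equal J).
    """

    points: list[tuple[float, float, float]]
    auc: float
    best_threshold: float
    best_sensitivity: float
    best_specificity: float
    best_j: float
    ci_low: float | None = None
    ci_high: float | None = None

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"threshold": t, "sensitivity": se, "specificity": sp, "youden_j": se + sp - 1.0}
                for t, se, sp in self.points
            ]
        )


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    if not (0.0 <= sensitivity <= 1.0) or not (0.0 <= specificity <= 1.0):
        raise ValidationError("sensitivity and specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


def _split(values, labels, positive_label):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive_label]
    neg = values[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise EmptyDataError("ROC needs at least one positive and one negative sample")
    return pos, neg


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs with the
    positive value higher, ties counted one half."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_curve(values: Sequence[float], labels: Sequence, positive_label=True) -> RocResult:
    """ROC over candidate copy-number thresholds (positive when value >=
    threshold; positives are expected to have the higher values).

    ``labels`` may be booleans, 0/1, or strings — anything equal to
    ``positive_label`` counts as positive.
    """
    pos, neg = _split(values, labels, positive_label)
    uniq = np.unique(np.concatenate([pos, neg]))
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    points = []
    best = None  # (j, threshold, sens, spec); smallest threshold wins ties
    for t in thresholds:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        points.append((float(t), sens, spec))
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), sens, spec)
    return RocResult(
        points=points,
        auc=_rank_auc(pos, neg),
        best_threshold=best[1],
        best_sensitivity=best[2],
        best_specificity=best[3],
        best_j=best[0],
    )


def bootstrap_auc_ci(
    values: Sequence[float],
    labels: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
    positive_label=True,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the AUC (stratified resampling:
    positives and negatives are resampled within class, so every replicate
    keeps both classes). Deterministic under a fixed seed."""
    pos, neg = _split(values, labels, positive_label)
    if len(pos) < 2 or len(neg) < 2:
        raise EmptyDataError("bootstrap CI needs >= 2 samples in each class")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        n = rng.choice(neg, size=len(neg), replace=True)
        aucs[i] = _rank_auc(p, n)
    low, high = np.percentile(aucs, [2.5, 97.5])
    return float(low), float(high)
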