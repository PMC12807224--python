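"""Doublet-detection accuracy metrics and reporting statistics.

Doublet detectors emit a continuous score per droplet (higher = more
doublet-like).  The threshold-free accuracy summary is AUPRC with doublets
as the positive class.  Converting scores to binary calls requires a
doublet rate: the top ``ceil(n * rate)`` scores are called doublets, after
which true positive / true negative rates are defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score

__all__ = [
    "LabeledScores",
    "auprc",
    "call_doublets_at_rate",
    "tpr_tnr",
    "relative_improvement",
    "percentile_rank",
]


@dataclass
class LabeledScores:
    """Doublet scores paired with ground-truth labels (1 = doublet).

    ``doublet_rate`` is optional metadata: the fraction of droplets that are
    doublets, needed only to turn scores into binary calls.
    """

    scores: np.ndarray
    labels: np.ndarray
    doublet_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.ndim != 1 or self.labels.ndim != 1:
            raise ValueError("scores and labels must be one-dimensional")
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if self.scores.size < 1:
            raise ValueError("need at least one droplet")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (singlet) or 1 (doublet)")
        if self.doublet_rate is not None and not 0 < self.doublet_rate < 1:
            raise ValueError("doublet_rate must lie in the open interval (0, 1)")

    @property
    def n(self) -> int:
        return int(self.scores.size)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


def _both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError(
            "labels contain a single class; AUPRC/TPR/TNR are undefined"
        )


def auprc(data: LabeledScores) -> float:
    """Area under the precision-recall curve, doublets positive.

    Uses the average-precision convention: the sum over each positive-going
    recall increment of the precision at that threshold, with tied scores
    collapsed to a single threshold.  This makes the value exactly
    reproducible (no trapezoidal interpolation).
    """
    _both_classes(data.labels)
    return float(average_precision_score(data.labels, data.scores))


def call_doublets_at_rate(data: LabeledScores, rate: float) -> np.ndarray:
    """Binary doublet calls from scores at a user-specified doublet rate.

    Exactly ``k = ceil(n * rate)`` droplets are called doublets — those with
    the k highest scores.  Ties at the cutoff are broken by input order
    (earlier index called first), so the calls are deterministic.
    """
    if not 0 < rate < 1:
        raise ValueError(f"doublet rate must be in (0, 1), got {rate}")
    n = data.n
    k = math.ceil(n * rate)
    # stable sort on descending score keeps earlier indices first among ties
    order = np.argsort(-data.scores, kind="stable")
    calls = np.zeros(n, dtype=int)
    calls[order[:k]] = 1
    return calls


def tpr_tnr(calls: Sequence[int], labels: Sequence[int]) -> Tuple[float, float]:
    """True positive rate (over doublets) and true negative rate (singlets)."""
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    _both_classes(labels)
    pos = labels == 1
    tpr = float((calls[pos] == 1).mean())
    tnr = float((calls[~pos] == 0).mean())
    return tpr, tnr


def relative_improvement(optimum: float, default: float) -> float:
    """Signed relative improvement in percent: 100 * (opt - def) / def."""
    if default <= 0:
        raise ValueError("baseline (default) accuracy must be positive")
    return 100.0 * (optimum - default) / default


def percentile_rank(value: float, grid_values: Sequence[float]) -> Tuple[int, float]:
    """Rank of ``value`` inserted among grid values (rank 1 = best).

    Rank counts only grid values *strictly* greater than ``value``, so a tie
    with the grid maximum still ranks first.  Percentile = rank / grid size.
    """
    grid = np.asarray(grid_values, dtype=float)
    if grid.size == 0:
        raise ValueError("grid_values must be non-empty")
    rank = 1 + int((grid > value).sum())
    return rank, rank / grid.size
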