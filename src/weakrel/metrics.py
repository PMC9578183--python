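"""Ranking metrics and uncertainty intervals.

AUROC is the Mann-Whitney probability that a random positive outranks a
random negative, ties counted half.  AUPR is uninterpolated average
precision: the mean, over positives, of the precision at each positive's
rank in the score-descending ordering (ties broken by stable input order;
shuffle first under an experiment seed if randomized tie-breaking is
wanted).  Confidence intervals use the percentile bootstrap over resampled
means by default; plain run percentiles are also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import EvaluationError


@dataclass
class ScoredSet:
    """Aligned scores and binary labels (1 positive / 0 negative)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise EvaluationError("scores and labels must be aligned 1-D vectors")


def _coerce(scores, labels) -> ScoredSet:
    if isinstance(scores, ScoredSet):
        return scores
    return ScoredSet(scores, labels)


def auroc(scores, labels=None) -> float:
    """Area under the ROC curve (rank-sum form, half credit for ties)."""
    s = _coerce(scores, labels)
    pos = s.labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUROC needs both classes present")
    ranks = rankdata(s.scores)  # average ranks on ties -> half credit
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def aupr(scores, labels=None) -> float:
    """Average precision (uninterpolated area under the PR curve)."""
    s = _coerce(scores, labels)
    n_pos = int((s.labels == 1).sum())
    if n_pos == 0 or n_pos == len(s.labels):
        raise EvaluationError("AUPR needs both classes present")
    order = np.argsort(-s.scores, kind="stable")
    ranked = s.labels[order]
    cum_pos = np.cumsum(ranked)
    ranks = np.arange(1, len(ranked) + 1)
    return float((cum_pos[ranked == 1] / ranks[ranked == 1]).sum() / n_pos)


def bootstrap_ci(
    values, level: float = 0.95, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval of the mean; deterministic given seed."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EvaluationError("bootstrap_ci needs a nonempty vector")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    low, high = np.quantile(means, [lo, 1.0 - lo])
    return float(low), float(high)


def percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Plain percentile interval of the raw values (no resampling)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EvaluationError("percentile_ci needs a nonempty vector")
    lo = (1.0 - level) / 2.0
    low, high = np.quantile(values, [lo, 1.0 - lo])
    return float(low), float(high)
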