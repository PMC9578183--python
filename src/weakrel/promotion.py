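"""Edge promotion: from sentence scores to knowledge-graph edges.

Candidate scores are grouped by co-mention pair and max-aggregated — the
best-scoring sentence for a pair is the evidence the pair is a real edge.
A decision threshold is calibrated on a hand-labeled set at the equal error
rate (the threshold where false-positive and false-negative rates meet).
Pairs at or above the threshold are promoted: pairs already in the
reference graph count as *recalled*, the rest as *novel*.  Recall is
reported against two denominators: reference edges restricted to pairs
with at least one candidate sentence (the default — edges never mentioned
cannot be recalled by a sentence classifier) and the unrestricted edge
count, for transparency.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import CandidateSentence
from .errors import CalibrationError, ContractError
from .graph import ReferenceGraph
from .metrics import ScoredSet


@dataclass
class PairScore:
    """Max-aggregated score of one co-mention pair."""

    pair: tuple[str, str]
    metaedge: str
    score: float
    n_candidates: int


@dataclass
class EdgeReport:
    """Promotion outcome for one metaedge at one threshold."""

    metaedge: str
    threshold: float
    n_recalled: int
    n_reference: int  # reference edges with >= 1 candidate sentence
    recall_fraction: float
    n_novel: int
    n_reference_total: int = 0  # unrestricted reference edge count
    recall_fraction_total: float | None = None
    undefined_recall: bool = False

    def to_json(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        return json.dumps(payload, indent=2)


def aggregate_pair_scores(
    candidates: Sequence[CandidateSentence], scores: Sequence[float]
) -> list[PairScore]:
    """One :class:`PairScore` per distinct (pair, metaedge); the score is
    the max over the pair's candidates, order-independent."""
    if len(candidates) != len(scores):
        raise ContractError("scores must align with candidates")
    groups: dict[tuple[tuple[str, str], str], list[float]] = {}
    for cand, score in zip(candidates, scores):
        a, b = cand.pair_ids
        if cand.edge_type == "GiG" and b < a:
            a, b = b, a
        groups.setdefault(((a, b), cand.edge_type), []).append(float(score))
    return [
        PairScore(pair, metaedge, max(vals), len(vals))
        for (pair, metaedge), vals in sorted(groups.items())
    ]


def equal_error_threshold(calibration: ScoredSet) -> float:
    """The threshold minimizing |FPR - FNR| on the calibration set.

    Sweeps the midpoints between adjacent distinct scores (plus sentinels
    below the minimum and above the maximum) with the decision rule
    ``score >= threshold -> positive``; ties break toward the lower
    threshold.
    """
    labels = np.asarray(calibration.labels)
    scores = np.asarray(calibration.scores)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("calibration set must contain both classes")
    uniq = np.unique(scores)
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_t, best_gap = None, np.inf
    for t in thresholds:
        predicted = scores >= t
        fpr = float(predicted[labels == 0].mean())
        fnr = float((~predicted)[labels == 1].mean())
        gap = abs(fpr - fnr)
        if gap < best_gap:  # strict: ties keep the lower threshold
            best_t, best_gap = float(t), gap
    return best_t


def promote_and_score(
    pair_scores: Sequence[PairScore],
    threshold: float,
    graph: ReferenceGraph,
    metaedge: str,
) -> EdgeReport:
    """Count recalled reference edges and novel above-threshold pairs."""
    scored = [p for p in pair_scores if p.metaedge == metaedge]
    mentioned = {p.pair for p in scored}
    reference = set(graph.edges_of(metaedge))
    reference_with_candidates = reference & mentioned

    above = {p.pair for p in scored if p.score >= threshold}
    recalled = above & reference_with_candidates
    novel = above - reference

    n_ref = len(reference_with_candidates)
    report = EdgeReport(
        metaedge=metaedge,
        threshold=float(threshold),
        n_recalled=len(recalled),
        n_reference=n_ref,
        recall_fraction=(len(recalled) / n_ref) if n_ref else float("nan"),
        n_novel=len(novel),
        n_reference_total=len(reference),
        recall_fraction_total=(
            len(recalled) / len(reference) if reference else None
        ),
        undefined_recall=n_ref == 0,
    )
    return report


def write_novel_edges_tsv(
    pair_scores: Sequence[PairScore],
    threshold: float,
    graph: ReferenceGraph,
    metaedge: str,
    path,
    top_n: int | None = None,
) -> None:
    """Ranked novel-edge table (highest scoring candidate pairs first)."""
    novel = [
        p for p in pair_scores
        if p.metaedge == metaedge and p.score >= threshold
        and not graph.has_edge(p.pair, metaedge)
    ]
    novel.sort(key=lambda p: (-p.score, p.pair))
    if top_n is not None:
        novel = novel[:top_n]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source_id", "target_id", "metaedge", "score",
                         "n_candidates"])
        for p in novel:
            writer.writerow([p.pair[0], p.pair[1], p.metaedge,
                             f"{p.score:.10g}", p.n_candidates])
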