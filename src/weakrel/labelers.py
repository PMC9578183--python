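"""Label functions and the label matrix.

A label function (LF) is a small pure predicate that votes POSITIVE,
NEGATIVE or ABSTAIN on a candidate sentence.  Two families are provided:

* **database (DB)** functions — distant supervision against the reference
  graph: a positive voter that fires when the candidate's co-mention pair
  is a known edge, and a complementary negative voter that fires when it is
  not (kept separate so neither function labels every sentence);
* **text-pattern (TP)** functions — keyword cues, inter-mention token
  distance, verb presence, and dependency-path cluster matches.

Vote encoding: internally votes are signed integers (+1 positive,
-1 negative, 0 abstain) because the generative model's algebra needs signed
agreement with the latent class.  Serialized TSVs use the conventional
integers 1 (positive), 0 (negative) and -1 (abstain).
"""

from __future__ import annotations

import csv
import enum
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .corpus import CandidateSentence
from .errors import AnnotationError, ConfigurationError, ContractError
from .graph import ReferenceGraph

logger = logging.getLogger(__name__)


class LabelVote(enum.IntEnum):
    """Ternary vote; integer values are the internal signed encoding."""

    POSITIVE = 1
    NEGATIVE = -1
    ABSTAIN = 0

    def to_serialized(self) -> int:
        """The serialization integer: positive 1, negative 0, abstain -1."""
        return _TO_SERIALIZED[int(self)]


_TO_SERIALIZED = {1: 1, -1: 0, 0: -1}
_FROM_SERIALIZED = {1: 1, 0: -1, -1: 0}


@dataclass(frozen=True)
class LabelFunction:
    """A named pure predicate over candidate sentences."""

    id: str
    edge_type: str
    category: str  # "DB" | "TP"
    predicate: Callable[[CandidateSentence], LabelVote]

    def __call__(self, candidate: CandidateSentence) -> LabelVote:
        return self.predicate(candidate)


@dataclass
class LabelMatrix:
    """n candidates x m label functions of ternary votes.

    ``votes`` uses the internal signed encoding (+1/-1/0).
    """

    votes: np.ndarray
    candidate_ids: list[str]
    lf_ids: list[str]

    def __post_init__(self):
        self.votes = np.asarray(self.votes, dtype=np.int8)
        if self.votes.ndim != 2:
            raise ContractError("votes must be a 2-D array")
        n, m = self.votes.shape
        if n != len(self.candidate_ids) or m != len(self.lf_ids):
            raise ContractError("votes shape must match id lists")
        bad = set(np.unique(self.votes)) - {-1, 0, 1}
        if bad:
            raise ContractError(f"votes outside the ternary domain: {bad}")

    @property
    def n(self) -> int:
        return self.votes.shape[0]

    @property
    def m(self) -> int:
        return self.votes.shape[1]

    def column_subset(self, indices: Sequence[int]) -> "LabelMatrix":
        """Select columns (repeats allowed — supports sampling with
        replacement); duplicated columns get a draw-index suffix."""
        indices = list(indices)
        counts: dict[str, int] = {}
        new_ids = []
        for i in indices:
            base = self.lf_ids[i]
            k = counts.get(base, 0)
            counts[base] = k + 1
            new_ids.append(base if k == 0 else f"{base}#{k}")
        return LabelMatrix(self.votes[:, indices], list(self.candidate_ids), new_ids)

    @staticmethod
    def hstack(left: "LabelMatrix", right: "LabelMatrix") -> "LabelMatrix":
        if left.candidate_ids != right.candidate_ids:
            raise ContractError("cannot hstack matrices over different candidates")
        return LabelMatrix(
            np.hstack([left.votes, right.votes]),
            list(left.candidate_ids),
            list(left.lf_ids) + list(right.lf_ids),
        )

    # -- serialization ----------------------------------------------------
    def write_tsv(self, path, manifest_path=None, lf_manifest=None) -> None:
        """TSV of serialization integers plus an optional LF manifest."""
        ser = np.vectorize(_TO_SERIALIZED.__getitem__)(self.votes.astype(int))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["candidate_id", *self.lf_ids])
            for cid, row in zip(self.candidate_ids, ser):
                writer.writerow([cid, *row.tolist()])
        if manifest_path is not None and lf_manifest is not None:
            with open(manifest_path, "w", newline="") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(["lf_id", "edge_type", "category"])
                for lf in lf_manifest:
                    writer.writerow([lf.id, lf.edge_type, lf.category])

    @classmethod
    def read_tsv(cls, path) -> "LabelMatrix":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            lf_ids = header[1:]
            cids, rows = [], []
            for row in reader:
                cids.append(row[0])
                rows.append([_FROM_SERIALIZED[int(v)] for v in row[1:]])
        return cls(np.asarray(rows, dtype=np.int8), cids, lf_ids)


@dataclass
class DependencyClusterSet:
    """Named clusters of dependency-path patterns.

    A pattern is a sequence of ``(relation, lemma)`` constraints matched
    against the shortest dependency path between the two mentions; ``"*"``
    matches any relation or lemma.
    """

    clusters: dict[str, list[tuple[tuple[str, str], ...]]] = field(
        default_factory=dict
    )

    def all_patterns(self):
        for patterns in self.clusters.values():
            yield from patterns


# ---------------------------------------------------------------------------
# Database label functions
# ---------------------------------------------------------------------------

def make_db_positive_lf(
    graph: ReferenceGraph, metaedge: str, *, lf_id: str | None = None
) -> LabelFunction:
    """POSITIVE iff the candidate's pair is an edge of the graph."""

    def predicate(candidate: CandidateSentence) -> LabelVote:
        if graph.has_edge(candidate.pair_ids, metaedge):
            return LabelVote.POSITIVE
        return LabelVote.ABSTAIN

    return LabelFunction(lf_id or f"{metaedge}:db_pos", metaedge, "DB", predicate)


def make_db_negative_lf(
    graph: ReferenceGraph, metaedge: str, *, lf_id: str | None = None
) -> LabelFunction:
    """NEGATIVE iff the candidate's pair is absent from the graph."""

    def predicate(candidate: CandidateSentence) -> LabelVote:
        if graph.has_edge(candidate.pair_ids, metaedge):
            return LabelVote.ABSTAIN
        return LabelVote.NEGATIVE

    return LabelFunction(lf_id or f"{metaedge}:db_neg", metaedge, "DB", predicate)


# ---------------------------------------------------------------------------
# Text-pattern label functions
# ---------------------------------------------------------------------------

def make_keyword_lf(
    phrases: Iterable[str],
    polarity: LabelVote,
    scope: str = "sentence",
    *,
    edge_type: str = "DaG",
    lf_id: str | None = None,
) -> LabelFunction:
    """Emit ``polarity`` when any phrase occurs (case-insensitive) in the
    chosen scope (whole sentence or the tokens between the mentions);
    otherwise abstain — absence of a cue phrase is weak evidence."""
    phrase_list = sorted({p.lower() for p in phrases})
    if not phrase_list:
        raise ConfigurationError("keyword label function needs >= 1 phrase")
    if polarity not in (LabelVote.POSITIVE, LabelVote.NEGATIVE):
        raise ConfigurationError("polarity must be POSITIVE or NEGATIVE")
    if scope not in ("sentence", "between"):
        raise ConfigurationError(f"unknown scope {scope!r}")

    def predicate(candidate: CandidateSentence) -> LabelVote:
        if scope == "sentence":
            haystack = candidate.sentence_text.lower()
        else:
            haystack = " ".join(candidate.tokens_between_mentions()).lower()
        if any(p in haystack for p in phrase_list):
            return polarity
        return LabelVote.ABSTAIN

    name = lf_id or f"{edge_type}:kw_{'pos' if polarity > 0 else 'neg'}:" + \
        phrase_list[0].replace(" ", "_")
    return LabelFunction(name, edge_type, "TP", predicate)


def make_distance_lf(
    max_token_gap: int,
    polarity: LabelVote,
    *,
    edge_type: str = "DaG",
    lf_id: str | None = None,
) -> LabelFunction:
    """Emit ``polarity`` when the token count strictly between the mentions
    is <= ``max_token_gap`` (boundary inclusive); otherwise abstain."""
    if max_token_gap < 0:
        raise ConfigurationError("max_token_gap must be >= 0")

    def predicate(candidate: CandidateSentence) -> LabelVote:
        gap = len(candidate.tokens_between_mentions())
        return polarity if gap <= max_token_gap else LabelVote.ABSTAIN

    return LabelFunction(
        lf_id or f"{edge_type}:dist<={max_token_gap}", edge_type, "TP", predicate
    )


def make_verb_presence_lf(
    *, edge_type: str = "DaG", lf_id: str | None = None
) -> LabelFunction:
    """NEGATIVE when no POS tag starting with "VB" occurs (a verbless
    sentence is unlikely to assert a relationship); abstain otherwise."""

    def predicate(candidate: CandidateSentence) -> LabelVote:
        if candidate.pos_tags is None:
            raise AnnotationError(
                f"candidate {candidate.candidate_id} has no pos_tags"
            )
        if any(tag.startswith("VB") for tag in candidate.pos_tags):
            return LabelVote.ABSTAIN
        return LabelVote.NEGATIVE

    return LabelFunction(lf_id or f"{edge_type}:verb", edge_type, "TP", predicate)


def shortest_dependency_path(
    candidate: CandidateSentence,
) -> list[tuple[str, str]] | None:
    """The shortest path between the two mention head tokens.

    Returned as a list of ``(relation, token-lowercase)`` steps, one per
    edge traversed, labelling each step with the token arrived at.  ``None``
    when the mentions are disconnected in the dependency graph.
    """
    if candidate.dependency_edges is None:
        raise AnnotationError(
            f"candidate {candidate.candidate_id} has no dependency_edges"
        )
    (a_lo, a_hi), (b_lo, b_hi) = candidate.mention_token_spans()
    if a_hi == 0 or b_hi == 0:
        return None
    start, goal = a_lo, b_lo
    adj: dict[int, list[tuple[int, str]]] = {}
    for head, dep, rel in candidate.dependency_edges:
        adj.setdefault(head, []).append((dep, rel))
        adj.setdefault(dep, []).append((head, rel))
    # BFS for the shortest undirected path
    prev: dict[int, tuple[int, str]] = {start: (-1, "")}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if node == goal:
            break
        for nxt, rel in adj.get(node, []):
            if nxt not in prev:
                prev[nxt] = (node, rel)
                queue.append(nxt)
    if goal not in prev:
        return None
    path = []
    node = goal
    while node != start:
        parent, rel = prev[node]
        path.append((rel, candidate.tokens[node].lower()))
        node = parent
    return list(reversed(path))


def _pattern_matches(path, pattern) -> bool:
    if len(path) != len(pattern):
        return False
    for (rel, lemma), (p_rel, p_lemma) in zip(path, pattern):
        if p_rel != "*" and p_rel != rel:
            return False
        if p_lemma != "*" and p_lemma != lemma:
            return False
    return True


def make_dependency_cluster_lf(
    clusters: DependencyClusterSet,
    polarity: LabelVote = LabelVote.POSITIVE,
    *,
    edge_type: str = "DaG",
    lf_id: str | None = None,
) -> LabelFunction:
    """Emit ``polarity`` when the shortest dependency path between the
    mentions matches any cluster pattern; abstain otherwise (including
    when the mentions are disconnected, with a warning)."""
    patterns = list(clusters.all_patterns())

    def predicate(candidate: CandidateSentence) -> LabelVote:
        path = shortest_dependency_path(candidate)
        if path is None:
            logger.warning(
                "mentions disconnected in dependency graph (candidate=%s)",
                candidate.candidate_id,
            )
            return LabelVote.ABSTAIN
        if any(_pattern_matches(path, pat) for pat in patterns):
            return polarity
        return LabelVote.ABSTAIN

    return LabelFunction(lf_id or f"{edge_type}:dep_cluster", edge_type, "TP", predicate)


# ---------------------------------------------------------------------------
# Applying a pool
# ---------------------------------------------------------------------------

def apply_label_functions(
    candidates: Sequence[CandidateSentence],
    lfs: Sequence[LabelFunction],
) -> LabelMatrix:
    """Evaluate every LF on every candidate.

    A predicate raising an internal failure yields ABSTAIN for that cell;
    failures are counted and logged, never propagated.
    """
    if not lfs:
        raise ConfigurationError("need at least one label function")
    if not candidates:
        raise ConfigurationError("need at least one candidate")
    votes = np.zeros((len(candidates), len(lfs)), dtype=np.int8)
    failures = 0
    for j, lf in enumerate(lfs):
        for i, cand in enumerate(candidates):
            try:
                votes[i, j] = int(lf(cand))
            except Exception:  # noqa: BLE001 — cell-level containment
                failures += 1
                votes[i, j] = 0
    if failures:
        logger.warning("%d label-function evaluations failed (ABSTAIN)", failures)
    return LabelMatrix(
        votes,
        [c.candidate_id for c in candidates],
        [lf.id for lf in lfs],
    )
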