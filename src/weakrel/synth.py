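"""Synthetic inputs with known generative parameters.

Two generators make every downstream stage testable without any corpus
download:

* :func:`simulate_label_matrix` draws a label matrix directly from the
  generative model's own assumptions — latent Bernoulli class, per-function
  firing propensity, per-function accuracy — so the label model's parameter
  recovery can be checked against exact ground truth.
* :func:`generate_corpus` emits a template-based annotated corpus: each
  abstract holds one pre-segmented, pre-tagged sentence co-mentioning a
  typed entity pair.  Positive sentences embed a cue phrase from the edge
  type's positive vocabulary with probability ``cue_strength``; negative
  sentences embed negative cues, verbless filler, or (rarely) a misleading
  positive cue.  A synthetic reference graph covers a configurable fraction
  of the true-positive pairs and includes distractor edges (graph edges
  whose co-mentions are negative sentences) so distant supervision has
  false positives.  Cue vocabularies are disjoint across edge types unless
  a cross-edge overlap fraction is configured — the knob that makes
  label-function transfer work by construction.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import (
    EDGE_TYPE_SIGNATURES,
    METAEDGES,
    AnnotatedAbstract,
    CandidateSentence,
    EntityAnnotation,
    SplitAssignment,
    apply_splits,
    assign_splits,
)
from .errors import ConfigurationError
from .graph import ReferenceGraph
from .labelers import (
    DependencyClusterSet,
    LabelFunction,
    LabelMatrix,
    LabelVote,
    make_db_negative_lf,
    make_db_positive_lf,
    make_dependency_cluster_lf,
    make_keyword_lf,
)
from .seeding import child_seed

#: Database / text-pattern pool sizes per edge type used as defaults for
#: generated pools (the observed ratio of curated function counts).
DEFAULT_POOL_SIZES: dict[str, tuple[int, int]] = {
    "DaG": (7, 30),
    "CtD": (3, 22),
    "CbG": (9, 20),
    "GiG": (9, 28),
}

_ENTITY_PREFIX = {"Disease": "D", "Gene": "G", "Compound": "C"}


@dataclass(frozen=True)
class LFSpec:
    """Ground-truth parameters of one simulated label function."""

    id: str
    polarity: LabelVote
    accuracy: float
    propensity: float
    edge_type: str = "DaG"

    def __post_init__(self):
        if not 0.0 < self.accuracy <= 1.0:
            raise ConfigurationError(
                f"accuracy must lie in (0, 1], got {self.accuracy}"
            )
        if not 0.0 <= self.propensity <= 1.0:
            raise ConfigurationError(
                f"propensity must lie in [0, 1], got {self.propensity}"
            )
        if self.polarity not in (LabelVote.POSITIVE, LabelVote.NEGATIVE):
            raise ConfigurationError("polarity must be POSITIVE or NEGATIVE")


def simulate_label_matrix(
    n: int,
    specs: Sequence[LFSpec],
    class_balance: float,
    seed: int = 0,
) -> tuple[LabelMatrix, np.ndarray]:
    """Draw a label matrix from known generative parameters.

    The true label is Bernoulli(``class_balance``); each cell fires with its
    spec's propensity; a firing vote equals the truth-aligned vote (the true
    class for POSITIVE polarity, its flip for NEGATIVE polarity) with
    probability ``accuracy`` and the opposite vote otherwise.

    Returns the matrix and the true labels (1 positive / 0 negative).
    """
    if n < 1 or not specs:
        raise ConfigurationError("need n >= 1 and at least one spec")
    if not 0.0 < class_balance < 1.0:
        raise ConfigurationError("class_balance must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < class_balance).astype(np.int8)  # 1 / 0
    y_signed = np.where(y == 1, 1, -1).astype(np.int8)
    m = len(specs)
    acc = np.array([s.accuracy for s in specs])
    rho = np.array([s.propensity for s in specs])
    pol = np.array([int(s.polarity) for s in specs], dtype=np.int8)
    fires = rng.random((n, m)) < rho
    agrees = rng.random((n, m)) < acc
    aligned = y_signed[:, None] * pol[None, :]
    votes = np.where(fires, np.where(agrees, aligned, -aligned), 0).astype(np.int8)
    matrix = LabelMatrix(
        votes,
        [f"sim:{i}" for i in range(n)],
        [s.id for s in specs],
    )
    return matrix, y


# ---------------------------------------------------------------------------
# Synthetic corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    """Study conditions for the synthetic corpus.

    ``cross_edge_overlap`` maps unordered edge-type pairs to the fraction of
    the first type's cue phrases that also appear in the second type's
    vocabulary (symmetric; the default empty mapping means pairwise
    disjoint vocabularies).
    """

    n_abstracts: int | dict[str, int] = 500
    edge_types: tuple[str, ...] = METAEDGES
    class_balance: float = 0.3
    cue_strength: float = 0.9
    n_pos_cues: int = 40
    n_neg_cues: int = 16
    cross_edge_overlap: dict[frozenset, float] = field(default_factory=dict)
    reference_graph_coverage: float = 0.75
    distractor_rate: float = 0.1
    hand_label_size: int = 1000
    split_probabilities: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self):
        for name in ("class_balance", "cue_strength"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("reference_graph_coverage", "distractor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        overlap = {}
        for key, frac in self.cross_edge_overlap.items():
            pair = frozenset(key)
            if len(pair) != 2 or not pair <= set(self.edge_types):
                raise ConfigurationError(f"bad overlap pair {key!r}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"overlap fraction {frac} out of range")
            overlap[pair] = frac
        self.cross_edge_overlap = overlap
        unknown = set(self.edge_types) - set(EDGE_TYPE_SIGNATURES)
        if unknown:
            raise ConfigurationError(f"unknown edge types {sorted(unknown)}")

    def n_for(self, edge_type: str) -> int:
        if isinstance(self.n_abstracts, dict):
            return int(self.n_abstracts[edge_type])
        return int(self.n_abstracts)


@dataclass
class CorpusBundle:
    """Everything the downstream stages consume, per edge type."""

    config: CorpusConfig
    abstracts: dict[str, list[AnnotatedAbstract]]
    candidates: dict[str, list[CandidateSentence]]
    graph: ReferenceGraph
    vocabularies: dict[str, dict[str, list[str]]]
    tune_labeled: dict[str, list[CandidateSentence]]
    test_labeled: dict[str, list[CandidateSentence]]
    true_pairs: dict[str, list[tuple[str, str]]]
    splits: SplitAssignment
    lf_pools: dict[str, dict[str, list[LabelFunction]]] = field(
        default_factory=dict
    )

    def train_candidates(self, edge_type: str) -> list[CandidateSentence]:
        return [c for c in self.candidates[edge_type] if c.split == "train"]

    @staticmethod
    def gold_vector(candidates: Sequence[CandidateSentence]) -> np.ndarray:
        return np.array(
            [1 if c.gold_label == "positive" else 0 for c in candidates],
            dtype=int,
        )


def build_vocabularies(config: CorpusConfig) -> dict[str, dict[str, list[str]]]:
    """Per-edge positive/negative cue phrase lists with controlled overlap.

    Base vocabularies are disjoint synthetic word lists; for an overlap
    fraction f between (e1, e2), the first round(f * size) phrases of e1
    replace the tail of e2's list, so exactly that fraction of e1's phrases
    also appears in e2's vocabulary.
    """
    vocabs = {
        e: {
            "positive": [f"{e.lower()}relcue{i:02d}" for i in range(config.n_pos_cues)],
            "negative": [f"{e.lower()}negcue{i:02d}" for i in range(config.n_neg_cues)],
        }
        for e in config.edge_types
    }
    order = {e: i for i, e in enumerate(config.edge_types)}
    for pair, frac in sorted(
        config.cross_edge_overlap.items(), key=lambda kv: sorted(kv[0])
    ):
        e1, e2 = sorted(pair, key=order.__getitem__)
        for polarity in ("positive", "negative"):
            size = len(vocabs[e1][polarity])
            k = round(frac * size)
            if k:
                shared = vocabs[e1][polarity][:k]
                vocabs[e2][polarity] = vocabs[e2][polarity][: size - k] + shared
    return vocabs


def _make_pairs(edge_type: str, count: int, tag: str) -> list[tuple[str, str]]:
    type_a, type_b = EDGE_TYPE_SIGNATURES[edge_type]
    pa, pb = _ENTITY_PREFIX[type_a], _ENTITY_PREFIX[type_b]
    pairs = []
    for i in range(count):
        a = f"{pa}:{edge_type}:{tag}{i:04d}a"
        b = f"{pb}:{edge_type}:{tag}{i:04d}b"
        if type_a == type_b and b < a:
            a, b = b, a
        pairs.append((a, b))
    return pairs


# Sentence templates.  Each is (tokens, tags, deps) builders over
# (entity1, entity2, cue); mention token indices are fixed per template.
# Positive-cue sentences keep the mentions adjacent to the cue (small gap);
# negative templates spread them out, so inter-mention distance correlates
# with the relationship the way short assertive clauses do in abstracts.

def _pos_cue_sentence(e1, e2, cue):
    tokens = [e1, cue, e2, "in", "patients"]
    tags = ["NNP", "VBZ", "NNP", "IN", "NNS"]
    deps = [(1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "prep"), (3, 4, "pobj")]
    return tokens, tags, deps, 0, 2


def _neutral_sentence(e1, e2, _cue):
    tokens = [e1, "appears", "alongside", e2, "here"]
    tags = ["NNP", "VBZ", "RB", "NNP", "RB"]
    deps = [(1, 0, "nsubj"), (1, 2, "advmod"), (2, 3, "pobj"), (1, 4, "advmod")]
    return tokens, tags, deps, 0, 3


def _neg_cue_sentence(e1, e2, cue):
    tokens = [e1, "was", cue, "regarding", e2, "cohort"]
    tags = ["NNP", "VBD", "NN", "IN", "NNP", "NN"]
    deps = [(1, 0, "nsubj"), (1, 2, "attr"), (2, 3, "prep"), (3, 4, "pobj"),
            (4, 5, "appos")]
    return tokens, tags, deps, 0, 4


def _verbless_sentence(e1, e2, _cue):
    tokens = [e1, "cohort", "records", "regarding", "broad", "population", e2]
    tags = ["NNP", "NN", "NNS", "IN", "JJ", "NN", "NNP"]
    deps = [(2, 0, "nmod"), (2, 1, "compound"), (2, 3, "prep"), (3, 5, "pobj"),
            (5, 4, "amod"), (5, 6, "appos")]
    return tokens, tags, deps, 0, 6


def generate_corpus(config: CorpusConfig) -> CorpusBundle:
    """Generate abstracts, candidates, gold labels, graph and gold subsets."""
    for e in config.edge_types:
        if config.n_pos_cues < 1 or config.n_neg_cues < 1:
            raise ConfigurationError(f"empty cue vocabulary for edge type {e}")
    vocabs = build_vocabularies(config)
    graph = ReferenceGraph()
    abstracts: dict[str, list[AnnotatedAbstract]] = {}
    candidates: dict[str, list[CandidateSentence]] = {}
    true_pairs: dict[str, list[tuple[str, str]]] = {}

    for edge_type in config.edge_types:
        rng = np.random.default_rng(child_seed(config.seed, "corpus", edge_type))
        n = config.n_for(edge_type)
        n_pairs = max(5, n // 40)
        pos_pairs = _make_pairs(edge_type, n_pairs, "t")
        neg_pairs = _make_pairs(edge_type, n_pairs, "n")
        true_pairs[edge_type] = pos_pairs
        type_a, type_b = EDGE_TYPE_SIGNATURES[edge_type]
        for a, b in pos_pairs + neg_pairs:
            graph.add_node(a, type_a)
            graph.add_node(b, type_b)
        # reference edges: covered true pairs plus distractor negatives
        for a, b in pos_pairs:
            if rng.random() < config.reference_graph_coverage:
                graph.add_edge(a, b, edge_type)
        for a, b in neg_pairs:
            if rng.random() < config.distractor_rate:
                graph.add_edge(a, b, edge_type)

        pos_vocab = vocabs[edge_type]["positive"]
        neg_vocab = vocabs[edge_type]["negative"]
        docs, cands = [], []
        for i in range(n):
            positive = rng.random() < config.class_balance
            if positive:
                pair = pos_pairs[rng.integers(len(pos_pairs))]
                if rng.random() < config.cue_strength:
                    builder = _pos_cue_sentence
                    cue = pos_vocab[rng.integers(len(pos_vocab))]
                else:
                    builder, cue = _neutral_sentence, ""
            else:
                pair = neg_pairs[rng.integers(len(neg_pairs))]
                u = rng.random()
                if u < 1.0 - config.cue_strength:
                    builder = _pos_cue_sentence  # misleading cue: LF noise
                    cue = pos_vocab[rng.integers(len(pos_vocab))]
                elif u < 1.0 - config.cue_strength / 2.0:
                    builder = _neg_cue_sentence
                    cue = neg_vocab[rng.integers(len(neg_vocab))]
                else:
                    builder, cue = _verbless_sentence, ""
            tokens, tags, deps, i1, i2 = builder(pair[0], pair[1], cue)
            sentence = " ".join(tokens)
            doc_id = f"{edge_type}-{i:06d}"
            starts = []
            cursor = 0
            for tok in tokens:
                starts.append(cursor)
                cursor += len(tok) + 1
            mentions = []
            for idx, (ent_id, ent_type) in (
                (i1, (pair[0], type_a)), (i2, (pair[1], type_b))
            ):
                mentions.append(
                    EntityAnnotation(
                        doc_id, starts[idx], starts[idx] + len(tokens[idx]),
                        tokens[idx], ent_type, ent_id,
                    )
                )
            cands.append(
                CandidateSentence(
                    candidate_id=f"{doc_id}:{edge_type}:0",
                    document_id=doc_id,
                    sentence_text=sentence,
                    tokens=list(tokens),
                    pos_tags=list(tags),
                    dependency_edges=list(deps),
                    mention_pair=(mentions[0], mentions[1]),
                    edge_type=edge_type,
                    gold_label="positive" if positive else "negative",
                )
            )
            title = "Synthetic abstract"
            offset = len(title) + 1
            docs.append(
                AnnotatedAbstract(
                    doc_id, title, sentence,
                    [
                        EntityAnnotation(
                            doc_id, m.start + offset, m.end + offset,
                            m.surface_text, m.entity_type, m.normalized_id,
                        )
                        for m in mentions
                    ],
                )
            )
        abstracts[edge_type] = docs
        candidates[edge_type] = cands

    all_doc_ids = [
        d.document_id for docs in abstracts.values() for d in docs
    ]
    splits = assign_splits(
        all_doc_ids, config.split_probabilities,
        seed=child_seed(config.seed, "splits"),
    )
    tune_labeled, test_labeled = {}, {}
    for edge_type in config.edge_types:
        apply_splits(candidates[edge_type], splits)
        tune = [c for c in candidates[edge_type] if c.split == "tune"]
        test = [c for c in candidates[edge_type] if c.split == "test"]
        tune_labeled[edge_type] = tune[: config.hand_label_size]
        test_labeled[edge_type] = test[: config.hand_label_size]

    bundle = CorpusBundle(
        config=config,
        abstracts=abstracts,
        candidates=candidates,
        graph=graph,
        vocabularies=vocabs,
        tune_labeled=tune_labeled,
        test_labeled=test_labeled,
        true_pairs=true_pairs,
        splits=splits,
    )
    for edge_type in config.edge_types:
        bundle.lf_pools[edge_type] = generate_lf_pool(
            edge_type, graph, vocabs,
            seed=child_seed(config.seed, "pool", edge_type),
        )
    return bundle


# ---------------------------------------------------------------------------
# Label-function pools
# ---------------------------------------------------------------------------

def _make_db_subset_lf(graph, metaedge, fraction, seed, lf_id) -> LabelFunction:
    """A positive distant-supervision voter over a random edge subset —
    emulates consulting one of several partially overlapping databases."""
    edges = graph.edges_of(metaedge)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(edges)) < fraction
    subset = {e for e, k in zip(edges, keep) if k}

    def predicate(candidate):
        a, b = candidate.pair_ids
        if metaedge == "GiG" and b < a:
            a, b = b, a
        return LabelVote.POSITIVE if (a, b) in subset else LabelVote.ABSTAIN

    return LabelFunction(lf_id, metaedge, "DB", predicate)


def _make_gated_distance_lf(cue_window, max_gap, edge_type, lf_id) -> LabelFunction:
    """Distance pattern grounded in a cue-vocabulary window: fires only when
    one of its cues is present AND the mentions are close."""
    phrases = [p.lower() for p in cue_window]

    def predicate(candidate):
        text = candidate.sentence_text.lower()
        if not any(p in text for p in phrases):
            return LabelVote.ABSTAIN
        gap = len(candidate.tokens_between_mentions())
        return LabelVote.POSITIVE if gap <= max_gap else LabelVote.ABSTAIN

    return LabelFunction(lf_id, edge_type, "TP", predicate)


def generate_lf_pool(
    edge_type: str,
    graph: ReferenceGraph,
    vocabularies: dict[str, dict[str, list[str]]],
    counts: tuple[int, int] | None = None,
    seed: int = 0,
) -> dict[str, list[LabelFunction]]:
    """A database pool and a text-pattern pool for one edge type.

    ``counts`` is (n_db, n_tp), defaulting to :data:`DEFAULT_POOL_SIZES`.
    The DB pool is the positive/negative distant-supervision pair plus
    random graph-subset variants; the TP pool cycles keyword (positive and
    negative), dependency-cluster and vocabulary-gated distance factories
    over sliding cue-vocabulary windows.
    """
    n_db, n_tp = counts if counts is not None else DEFAULT_POOL_SIZES[edge_type]
    if n_db < 0 or n_tp < 0:
        raise ConfigurationError("pool counts must be nonnegative")
    pos_vocab = vocabularies[edge_type]["positive"]
    neg_vocab = vocabularies[edge_type]["negative"]
    max_tp = 2 * len(pos_vocab) + len(neg_vocab)
    if n_tp > max_tp:
        raise ConfigurationError(
            f"requested {n_tp} text-pattern functions; only {max_tp} are "
            f"constructible from the {edge_type} vocabulary"
        )

    db: list[LabelFunction] = []
    if n_db >= 1:
        db.append(make_db_positive_lf(graph, edge_type))
    if n_db >= 2:
        db.append(make_db_negative_lf(graph, edge_type))
    for k in range(max(0, n_db - 2)):
        db.append(
            _make_db_subset_lf(
                graph, edge_type, 0.6, child_seed(seed, "db_sub", k),
                f"{edge_type}:db_sub{k}",
            )
        )

    tp: list[LabelFunction] = []
    kinds = ("kw_pos", "kw_pos", "kw_neg", "dep", "dist")
    window = 3
    counters = {k: 0 for k in kinds}
    for i in range(n_tp):
        kind = kinds[i % len(kinds)]
        j = counters[kind]
        counters[kind] += 1
        if kind == "kw_pos":
            lo = (j * window) % len(pos_vocab)
            phrases = [pos_vocab[(lo + t) % len(pos_vocab)] for t in range(window)]
            tp.append(
                make_keyword_lf(
                    phrases, LabelVote.POSITIVE, edge_type=edge_type,
                    lf_id=f"{edge_type}:kw_pos{i}",
                )
            )
        elif kind == "kw_neg":
            lo = (j * window) % len(neg_vocab)
            phrases = [neg_vocab[(lo + t) % len(neg_vocab)] for t in range(window)]
            tp.append(
                make_keyword_lf(
                    phrases, LabelVote.NEGATIVE, edge_type=edge_type,
                    lf_id=f"{edge_type}:kw_neg{i}",
                )
            )
        elif kind == "dep":
            lo = (j * window) % len(pos_vocab)
            cues = [pos_vocab[(lo + t) % len(pos_vocab)] for t in range(window)]
            clusters = DependencyClusterSet(
                {f"theme{i}": [(("nsubj", cue), ("dobj", "*")) for cue in cues]}
            )
            tp.append(
                make_dependency_cluster_lf(
                    clusters, LabelVote.POSITIVE, edge_type=edge_type,
                    lf_id=f"{edge_type}:dep{i}",
                )
            )
        else:  # dist
            lo = (j * window) % len(pos_vocab)
            cues = [pos_vocab[(lo + t) % len(pos_vocab)] for t in range(window)]
            tp.append(
                _make_gated_distance_lf(
                    cues, 2, edge_type, f"{edge_type}:dist{i}"
                )
            )
    return {"DB": db, "TP": tp}
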