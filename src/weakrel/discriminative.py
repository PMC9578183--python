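"""Discriminative stage: a classifier over the label model's annotations.

The shipped representation is a hashed sparse bag of unigrams/bigrams (with
the two entity mentions replaced by type placeholders) plus an
inter-mention distance bucket, feeding a logistic model trained with the
adaptive-moment (Adam) optimizer on probability-weighted cross-entropy —
the label model's posterior probabilities act as soft targets, so hard 0/1
annotations reduce exactly to standard cross-entropy.  A transformer
encoder with a frozen body and trained classification head satisfies the
same :class:`TextClassifier` protocol and can be plugged in where GPU-scale
representations are wanted; the training contract (10 epochs, Adam,
learning rate 0.001) is representation-independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy import sparse
from scipy.special import expit

from .corpus import CandidateSentence
from .errors import ConfigurationError, ContractError
from .label_model import TrainingAnnotation


@dataclass
class DiscriminativeConfig:
    epochs: int = 10
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    dim: int = 2**16
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.learning_rate <= 0:
            raise ConfigurationError("epochs and learning_rate must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FeatureVector:
    """Sparse hashed features of one candidate."""

    candidate_id: str
    indices: dict[int, float] = field(default_factory=dict)
    dim: int = 2**16


class TextClassifier(Protocol):
    """Plugin point: anything that scores feature vectors in [0, 1]."""

    def predict_proba(self, features: Sequence[FeatureVector]) -> np.ndarray: ...


def _hash_feature(token: str, dim: int) -> int:
    digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % dim


def _placeholder_tokens(candidate: CandidateSentence) -> list[str]:
    (a_lo, a_hi), (b_lo, b_hi) = candidate.mention_token_spans()
    spans = sorted(
        [
            (a_lo, a_hi, candidate.mention_pair[0].entity_type),
            (b_lo, b_hi, candidate.mention_pair[1].entity_type),
        ]
    )
    out, i = [], 0
    while i < len(candidate.tokens):
        placed = False
        for lo, hi, etype in spans:
            if i == lo and hi > lo:
                out.append(f"__{etype.upper()}__")
                i = hi
                placed = True
                break
        if not placed:
            out.append(candidate.tokens[i].lower())
            i += 1
    return out


def featurize(
    candidates: Sequence[CandidateSentence], dim: int = 2**16
) -> list[FeatureVector]:
    """Hashed unigrams + bigrams over placeholder-substituted tokens, plus
    a bucketed inter-mention token distance.  Deterministic; two sentences
    differing only in entity surface text featurize identically."""
    vectors = []
    for cand in candidates:
        toks = _placeholder_tokens(cand)
        feats: dict[int, float] = {}
        for tok in toks:
            feats[_hash_feature(f"u:{tok}", dim)] = 1.0
        for a, b in zip(toks, toks[1:]):
            feats[_hash_feature(f"b:{a}|{b}", dim)] = 1.0
        gap = len(cand.tokens_between_mentions())
        bucket = min(gap // 3, 5)
        feats[_hash_feature(f"d:{bucket}", dim)] = 1.0
        # unit-norm rows so sentence length does not bias the score scale
        norm = float(np.sqrt(sum(v * v for v in feats.values())))
        feats = {k: v / norm for k, v in feats.items()}
        vectors.append(FeatureVector(cand.candidate_id, feats, dim))
    return vectors


def stack_features(vectors: Sequence[FeatureVector]) -> sparse.csr_matrix:
    if not vectors:
        raise ConfigurationError("no feature vectors to stack")
    dim = vectors[0].dim
    rows, cols, vals = [], [], []
    for i, fv in enumerate(vectors):
        if fv.dim != dim:
            raise ContractError("mixed feature dimensionalities")
        for j, v in fv.indices.items():
            if not (0 <= j < dim) or not np.isfinite(v):
                raise ContractError("feature index/value out of contract")
            rows.append(i)
            cols.append(j)
            vals.append(v)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(vectors), dim), dtype=np.float64
    )


@dataclass
class LinearTextClassifier:
    """Logistic model over the hashed feature space."""

    weights: np.ndarray
    bias: float
    config: DiscriminativeConfig

    def predict_proba(self, features: Sequence[FeatureVector]) -> np.ndarray:
        if not features:
            return np.zeros(0)
        x = stack_features(features)
        if x.shape[1] != self.weights.size:
            raise ContractError(
                f"feature dim {x.shape[1]} != classifier dim {self.weights.size}"
            )
        return expit(x @ self.weights + self.bias)

    def save(self, blob_path, meta_path) -> None:
        np.savez(blob_path, weights=self.weights, bias=self.bias)
        with open(meta_path, "w") as fh:
            json.dump(
                {
                    "format_version": 1,
                    "dim": int(self.weights.size),
                    "epochs": self.config.epochs,
                    "learning_rate": self.config.learning_rate,
                    "optimizer": self.config.optimizer,
                    "seed": self.config.seed,
                },
                fh, indent=2,
            )

    @classmethod
    def load(cls, blob_path, meta_path) -> "LinearTextClassifier":
        with np.load(blob_path) as blob:
            weights, bias = blob["weights"], float(blob["bias"])
        with open(meta_path) as fh:
            meta = json.load(fh)
        cfg = DiscriminativeConfig(
            epochs=meta["epochs"], learning_rate=meta["learning_rate"],
            dim=meta["dim"], seed=meta["seed"],
        )
        return cls(weights, bias, cfg)


def train_discriminative(
    features: Sequence[FeatureVector],
    annotations: Sequence[TrainingAnnotation],
    config: DiscriminativeConfig | None = None,
) -> LinearTextClassifier:
    """Minimize soft-label cross-entropy with mini-batch Adam.

    ``annotations`` must align one-to-one (by candidate id) with
    ``features``; probabilities are the soft targets.  Deterministic given
    the config seed.
    """
    cfg = config if config is not None else DiscriminativeConfig()
    if len(features) != len(annotations):
        raise ContractError("features and annotations must align")
    for fv, ann in zip(features, annotations):
        if fv.candidate_id != ann.candidate_id:
            raise ContractError(
                f"misaligned ids: {fv.candidate_id} vs {ann.candidate_id}"
            )
        if not 0.0 <= ann.probability <= 1.0:
            raise ContractError("annotation probability outside [0, 1]")

    x = stack_features(features)
    targets = np.array([a.probability for a in annotations])
    n, dim = x.shape
    w = np.zeros(dim)
    b = 0.0
    m_w = np.zeros(dim); v_w = np.zeros(dim)
    m_b = 0.0; v_b = 0.0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    rng = np.random.default_rng(cfg.seed)
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = x[idx]
            p = expit(xb @ w + b)
            resid = p - targets[idx]
            g_w = xb.T @ resid / len(idx)
            g_b = float(resid.mean())
            step += 1
            m_w = beta1 * m_w + (1 - beta1) * g_w
            v_w = beta2 * v_w + (1 - beta2) * g_w**2
            m_b = beta1 * m_b + (1 - beta1) * g_b
            v_b = beta2 * v_b + (1 - beta2) * g_b**2
            bc1 = 1 - beta1**step
            bc2 = 1 - beta2**step
            w -= cfg.learning_rate * (m_w / bc1) / (np.sqrt(v_w / bc2) + eps)
            b -= cfg.learning_rate * (m_b / bc1) / (np.sqrt(v_b / bc2) + eps)
    return LinearTextClassifier(w, float(b), cfg)


def predict_scores(
    classifier: TextClassifier, features: Sequence[FeatureVector]
) -> np.ndarray:
    """One probability per candidate (empty in, empty out)."""
    return np.asarray(classifier.predict_proba(features), dtype=float)
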