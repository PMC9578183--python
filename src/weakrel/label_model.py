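"""Noise-aware generative label model.

The true class :math:`Y \\in \\{+1, -1\\}` of each candidate is latent; the
m label functions are assumed conditionally independent noisy voters.  Each
function j contributes two log-linear factors to :math:`P(\\Lambda, Y)`:

* a **labeling** factor, weight :math:`\\beta_j`, firing whenever the vote
  is not ABSTAIN (models the function's propensity to label at all);
* an **accuracy** factor, weight :math:`\\alpha_j`, contributing
  :math:`+\\alpha_j` when the vote agrees with Y (POSITIVE with Y=+1,
  NEGATIVE with Y=-1) and :math:`-\\alpha_j` when it disagrees;

plus a class-prior factor with weight :math:`\\gamma`.  With the signed vote
encoding :math:`v_{ij} \\in \\{+1,-1,0\\}` the per-function normalizer is
:math:`z_j = 1 + 2 e^{\\beta_j} \\cosh\\alpha_j` (identical for both classes),
so the marginal negative log-likelihood of a row and the posterior

.. math:: P(Y=+1 \\mid \\Lambda_i) = \\sigma\\bigl(2(\\gamma + v_i^T \\alpha)\\bigr)

are closed-form.  Training minimizes the l2-penalized mean marginal NLL by
seeded mini-batch gradient descent at the fixed learning rate 1e-3 for 250
epochs; the penalty covers accuracy and propensity weights but not the
class prior.  A function's implied accuracy is
:math:`\\mathrm{logistic}(2\\alpha_j)`, used for diagnostics and recovery
tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    EvaluationError,
    TrainingError,
)
from .labelers import LabelMatrix
from . import metrics

_INIT_WEIGHT = 0.1  # small positive start: accuracy semantics above coin-flip


@dataclass
class LabelModelParams:
    """Hyperparameters plus (after fitting) learned weights.

    ``accuracy_weights`` and ``propensity_weights`` align with ``lf_ids``.
    """

    l2: float = 0.0
    learning_rate: float = 1e-3
    epochs: int = 250
    batch_size: int = 64
    seed: int = 0
    accuracy_weights: np.ndarray | None = None
    propensity_weights: np.ndarray | None = None
    class_prior_weight: float = 0.0
    lf_ids: list[str] | None = None
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.l2 < 0:
            raise ConfigurationError("l2 must be nonnegative")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ConfigurationError("epochs and batch_size must be positive")

    def estimated_accuracies(self) -> np.ndarray:
        """Implied per-function accuracy, logistic(2 * accuracy weight)."""
        return expit(2.0 * np.asarray(self.accuracy_weights))

    def estimated_propensities(self) -> np.ndarray:
        """Implied per-function firing probability under the model."""
        a = np.asarray(self.accuracy_weights)
        b = np.asarray(self.propensity_weights)
        fire = 2.0 * np.exp(b) * np.cosh(a)
        return fire / (1.0 + fire)

    def class_prior(self) -> float:
        """P(Y = positive) with no votes observed."""
        return float(expit(2.0 * self.class_prior_weight))


@dataclass
class TrainingAnnotation:
    """Posterior positive-class probability for one candidate."""

    candidate_id: str
    probability: float
    discretized: str | None = None  # "positive" | "negative"


def params_from_truth(
    accuracies: Sequence[float],
    propensities: Sequence[float],
    class_balance: float,
    lf_ids: Sequence[str] | None = None,
) -> LabelModelParams:
    """Exact model weights for known generative parameters.

    Inverts the weight -> (accuracy, propensity, prior) maps so posterior
    probabilities under these parameters equal the conditionally
    independent Bayes posterior of the generating process.
    """
    acc = np.asarray(accuracies, dtype=float)
    rho = np.asarray(propensities, dtype=float)
    alpha = 0.5 * logit(acc)
    with np.errstate(divide="ignore"):
        # solve 2 e^beta cosh(alpha) / (1 + 2 e^beta cosh(alpha)) = rho
        beta = np.log(rho / np.maximum(1.0 - rho, 1e-300)) - np.log(
            2.0 * np.cosh(alpha)
        )
    gamma = 0.5 * logit(class_balance)
    return LabelModelParams(
        accuracy_weights=alpha,
        propensity_weights=beta,
        class_prior_weight=float(gamma),
        lf_ids=list(lf_ids) if lf_ids is not None else None,
    )


def _nll(votes, labeled, alpha, beta, gamma, l2):
    """Mean marginal negative log-likelihood plus the l2 penalty."""
    t = votes @ alpha
    c = labeled @ beta
    logz = np.log1p(2.0 * np.exp(beta) * np.cosh(alpha)).sum()
    ll = c + _log2cosh(gamma + t) - logz - _log2cosh(np.asarray(gamma))
    return float(-ll.mean() + l2 * (alpha @ alpha + beta @ beta))


def _log2cosh(x):
    x = np.abs(x)
    return x + np.log1p(np.exp(-2.0 * x))


def fit_label_model(
    matrix: LabelMatrix, template: LabelModelParams | None = None, **overrides
) -> LabelModelParams:
    """Fit the generative model to a label matrix (no gold labels).

    ``template`` supplies hyperparameters (l2, learning rate, epochs, batch
    size, seed); keyword overrides win.  Deterministic given the seed: two
    fits with identical inputs produce bitwise-identical weight and loss
    histories.  Raises :class:`DegenerateInputError` on an all-ABSTAIN
    matrix and :class:`TrainingError` (naming the epoch) if the loss goes
    non-finite.
    """
    hp = template if template is not None else LabelModelParams()
    if overrides:
        hp = replace(hp, **overrides)
    votes = matrix.votes.astype(np.float64)
    labeled = np.abs(votes)
    n, m = votes.shape
    if m < 1:
        raise ConfigurationError("need at least one label function")
    if not labeled.any():
        raise DegenerateInputError("label matrix is entirely ABSTAIN")

    alpha = np.full(m, _INIT_WEIGHT)
    beta = np.full(m, _INIT_WEIGHT)
    gamma = 0.0
    rng = np.random.default_rng(hp.seed)
    lr = hp.learning_rate
    loss_history = []
    # The class-prior weight is frozen for the first half of training: if it
    # moves while the accuracy weights are still near their symmetric init,
    # the prior absorbs the majority vote polarity and drags the fit into a
    # one-class solution (a poor local optimum of the marginal likelihood);
    # orienting the accuracy weights first avoids that basin.
    warmup = hp.epochs // 2
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, hp.batch_size):
            idx = order[lo : lo + hp.batch_size]
            vb, ab = votes[idx], labeled[idx]
            t = vb @ alpha
            tanh_s = np.tanh(gamma + t)
            eb = np.exp(beta)
            z = 1.0 + 2.0 * eb * np.cosh(alpha)
            g_alpha = (
                -(vb * tanh_s[:, None]).mean(axis=0)
                + 2.0 * eb * np.sinh(alpha) / z
                + 2.0 * hp.l2 * alpha
            )
            g_beta = (
                -ab.mean(axis=0) + 2.0 * eb * np.cosh(alpha) / z + 2.0 * hp.l2 * beta
            )
            alpha -= lr * g_alpha
            beta -= lr * g_beta
            if epoch >= warmup:
                g_gamma = -(tanh_s.mean() - np.tanh(gamma))
                gamma -= lr * g_gamma
        loss = _nll(votes, labeled, alpha, beta, gamma, hp.l2)
        if not np.isfinite(loss):
            raise TrainingError("non-finite training loss", epoch=epoch)
        loss_history.append(loss)

    return LabelModelParams(
        l2=hp.l2,
        learning_rate=hp.learning_rate,
        epochs=hp.epochs,
        batch_size=hp.batch_size,
        seed=hp.seed,
        accuracy_weights=alpha,
        propensity_weights=beta,
        class_prior_weight=float(gamma),
        lf_ids=list(matrix.lf_ids),
        loss_history=loss_history,
    )


def posterior_probability(
    params: LabelModelParams, matrix: LabelMatrix
) -> list[TrainingAnnotation]:
    """P(Y = positive | row votes) for every candidate.

    All-ABSTAIN rows receive the model's class prior.  The matrix must
    carry the same label functions, in the same order, as the parameters.
    """
    if params.accuracy_weights is None:
        raise ConfigurationError("parameters are not trained or set")
    if params.lf_ids is not None and list(params.lf_ids) != list(matrix.lf_ids):
        raise AlignmentError("lf_ids of params and matrix do not align")
    alpha = np.asarray(params.accuracy_weights, dtype=float)
    probs = expit(2.0 * (params.class_prior_weight + matrix.votes @ alpha))
    return [
        TrainingAnnotation(cid, float(p))
        for cid, p in zip(matrix.candidate_ids, probs)
    ]


def probabilities(annotations: Sequence[TrainingAnnotation]) -> np.ndarray:
    return np.asarray([a.probability for a in annotations], dtype=float)


def discretize(
    annotations: Sequence[TrainingAnnotation], threshold: float = 0.5
) -> list[TrainingAnnotation]:
    """Threshold probabilities into classes; positive iff p >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError("threshold must lie in (0, 1)")
    return [
        replace(
            a,
            discretized="positive" if a.probability >= threshold else "negative",
        )
        for a in annotations
    ]


def default_l2_grid() -> np.ndarray:
    """Five evenly spaced l2 values, endpoints 0.01 and 5 inclusive."""
    return np.linspace(0.01, 5.0, 5)


def grid_search_l2(
    matrix: LabelMatrix,
    dev_matrix: LabelMatrix,
    dev_labels: Sequence[int],
    template: LabelModelParams | None = None,
    grid: Sequence[float] | None = None,
) -> LabelModelParams:
    """Fit one model per l2 value; return the fit with the best dev AUROC.

    ``dev_labels`` are gold binary labels (1 positive / 0 negative) aligned
    to ``dev_matrix`` rows; both classes must be present.
    """
    y = np.asarray(dev_labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise EvaluationError("dev set must contain both classes")
    if grid is None:
        grid = default_l2_grid()
    best, best_auroc = None, -np.inf
    for l2 in grid:
        fitted = fit_label_model(matrix, template, l2=float(l2))
        scores = probabilities(posterior_probability(fitted, dev_matrix))
        score = metrics.auroc(scores, y)
        if score > best_auroc:
            best, best_auroc = fitted, score
    return best


def write_annotations(annotations: Sequence[TrainingAnnotation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["candidate_id", "probability", "discretized"])
        for a in annotations:
            writer.writerow([a.candidate_id, f"{a.probability:.10g}",
                             a.discretized or ""])


def write_params(params: LabelModelParams, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["lf_id", "accuracy_weight", "propensity_weight",
                         "implied_accuracy"])
        acc = params.estimated_accuracies()
        ids = params.lf_ids or [str(j) for j in range(len(acc))]
        for lf_id, aw, pw, ia in zip(
            ids, params.accuracy_weights, params.propensity_weights, acc
        ):
            writer.writerow([lf_id, f"{aw:.10g}", f"{pw:.10g}", f"{ia:.10g}"])
        writer.writerow(["__class_prior__", f"{params.class_prior_weight:.10g}",
                         "", f"{params.class_prior():.10g}"])
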