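"""Generative label model: posterior, fitting, grid search, discretization."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from weakrel import (
    LabelModelParams,
    LabelVote,
    LFSpec,
    default_l2_grid,
    discretize,
    fit_label_model,
    grid_search_l2,
    params_from_truth,
    posterior_probability,
    probabilities,
    simulate_label_matrix,
)
from weakrel.errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    EvaluationError,
)
from weakrel.labelers import LabelMatrix


def bayes_posterior(votes_row, accuracies, propensities, balance):
    """Independent oracle: closed-form conditionally-independent posterior."""
    num, den = balance, 1.0 - balance
    for v, a, r in zip(votes_row, accuracies, propensities):
        if v == 0:
            pp = pn = 1.0 - r
        elif v == 1:
            pp, pn = r * a, r * (1.0 - a)
        else:
            pp, pn = r * (1.0 - a), r * a
        num *= pp
        den *= pn
    return num / (num + den)


def _matrix(rows, ids=None):
    rows = np.asarray(rows, dtype=np.int8)
    return LabelMatrix(
        rows,
        [f"c{i}" for i in range(rows.shape[0])],
        ids or [f"lf{j}" for j in range(rows.shape[1])],
    )


class TestPosterior:
    def test_single_function_accuracy_09_prior_half(self):
        params = params_from_truth([0.9], [0.7], 0.5, lf_ids=["lf0"])
        ann = posterior_probability(params, _matrix([[1], [-1], [0]]))
        probs = probabilities(ann)
        assert probs[0] == pytest.approx(0.9, abs=1e-9)
        assert probs[1] == pytest.approx(0.1, abs=1e-9)
        assert probs[2] == pytest.approx(0.5, abs=1e-9)  # abstain -> prior

    def test_all_abstain_row_gets_class_prior(self):
        params = params_from_truth([0.8, 0.7], [0.5, 0.5], 0.3)
        probs = probabilities(posterior_probability(params, _matrix([[0, 0]])))
        assert probs[0] == pytest.approx(0.3, abs=1e-9)

    def test_matches_closed_form_on_all_patterns_m3(self, rng):
        acc = rng.uniform(0.55, 0.95, 3)
        rho = rng.uniform(0.3, 0.9, 3)
        balance = 0.4
        params = params_from_truth(acc, rho, balance)
        patterns = list(itertools.product((-1, 0, 1), repeat=3))
        probs = probabilities(
            posterior_probability(params, _matrix(patterns))
        )
        for row, p in zip(patterns, probs):
            assert p == pytest.approx(
                bayes_posterior(row, acc, rho, balance), abs=1e-6
            )

    def test_vote_flip_symmetry(self):
        params = params_from_truth([0.8, 0.9], [0.5, 0.5], 0.5)
        rows = [[1, -1], [1, 1], [0, 1]]
        flipped = [[-v for v in r] for r in rows]
        p = probabilities(posterior_probability(params, _matrix(rows)))
        q = probabilities(posterior_probability(params, _matrix(flipped)))
        assert np.allclose(p, 1.0 - q, atol=1e-12)

    def test_lf_id_mismatch_is_alignment_error(self):
        params = params_from_truth([0.9], [0.5], 0.5, lf_ids=["a"])
        with pytest.raises(AlignmentError):
            posterior_probability(params, _matrix([[1]], ids=["b"]))


class TestFit:
    def test_perfect_function_dominates_noisy_one(self):
        specs = [
            LFSpec("perfect", LabelVote.POSITIVE, 0.999, 1.0),
            LFSpec("noisy", LabelVote.POSITIVE, 0.6, 1.0),
        ]
        matrix, _ = simulate_label_matrix(3000, specs, 0.5, seed=1)
        fit = fit_label_model(matrix, seed=0)
        acc = fit.estimated_accuracies()
        assert acc[0] > acc[1]
        assert fit.accuracy_weights[0] > 0

    def test_recovers_known_accuracies(self):
        accs, rho = (0.9, 0.8, 0.7), 0.7
        specs = [
            LFSpec(f"lf{j}", LabelVote.POSITIVE, a, rho)
            for j, a in enumerate(accs)
        ]
        matrix, _ = simulate_label_matrix(10_000, specs, 0.5, seed=2)
        fit = fit_label_model(matrix, seed=0)
        est = fit.estimated_accuracies()
        assert np.all(np.abs(est - np.array(accs)) < 0.05)

    def test_same_seed_bitwise_identical(self):
        specs = [LFSpec("a", LabelVote.POSITIVE, 0.8, 0.6)]
        matrix, _ = simulate_label_matrix(500, specs, 0.5, seed=3)
        f1 = fit_label_model(matrix, seed=5)
        f2 = fit_label_model(matrix, seed=5)
        assert f1.loss_history == f2.loss_history
        assert np.array_equal(f1.accuracy_weights, f2.accuracy_weights)

    def test_column_permutation_permutes_weights(self):
        specs = [
            LFSpec("a", LabelVote.POSITIVE, 0.9, 0.8),
            LFSpec("b", LabelVote.POSITIVE, 0.6, 0.4),
        ]
        matrix, _ = simulate_label_matrix(2000, specs, 0.5, seed=4)
        perm = matrix.column_subset([1, 0])
        f = fit_label_model(matrix, seed=0, batch_size=2000)
        g = fit_label_model(perm, seed=0, batch_size=2000)
        assert np.allclose(f.accuracy_weights, g.accuracy_weights[::-1])

    def test_all_abstain_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_label_model(_matrix([[0, 0], [0, 0]]))

    def test_loss_history_decreases(self):
        specs = [LFSpec("a", LabelVote.POSITIVE, 0.85, 0.7)]
        matrix, _ = simulate_label_matrix(2000, specs, 0.5, seed=6)
        fit = fit_label_model(matrix, seed=0)
        assert fit.loss_history[-1] < fit.loss_history[0]

    def test_probabilities_always_in_unit_interval(self):
        specs = [
            LFSpec(f"l{j}", LabelVote.POSITIVE, 0.7, 0.5) for j in range(4)
        ]
        matrix, _ = simulate_label_matrix(1000, specs, 0.3, seed=7)
        fit = fit_label_model(matrix, seed=0)
        p = probabilities(posterior_probability(fit, matrix))
        assert np.all((p >= 0) & (p <= 1))


class TestGridSearch:
    def test_default_grid_values(self):
        assert np.allclose(
            default_l2_grid(), [0.01, 1.2575, 2.505, 3.7525, 5.0]
        )

    def test_single_value_grid_returns_that_fit(self):
        specs = [LFSpec("a", LabelVote.POSITIVE, 0.9, 0.8)]
        matrix, y = simulate_label_matrix(1000, specs, 0.5, seed=8)
        dev, dy = simulate_label_matrix(300, specs, 0.5, seed=9)
        fit = grid_search_l2(matrix, dev, dy, grid=[0.25])
        assert fit.l2 == 0.25

    def test_selection_stable_under_fixed_seed(self):
        specs = [
            LFSpec(f"l{j}", LabelVote.POSITIVE, 0.8, 0.6) for j in range(3)
        ]
        matrix, _ = simulate_label_matrix(1500, specs, 0.5, seed=10)
        dev, dy = simulate_label_matrix(400, specs, 0.5, seed=11)
        t = LabelModelParams(seed=3)
        a = grid_search_l2(matrix, dev, dy, template=t)
        b = grid_search_l2(matrix, dev, dy, template=t)
        assert a.l2 == b.l2

    def test_one_class_dev_set_rejected(self):
        specs = [LFSpec("a", LabelVote.POSITIVE, 0.9, 0.8)]
        matrix, _ = simulate_label_matrix(100, specs, 0.5, seed=12)
        with pytest.raises(EvaluationError):
            grid_search_l2(matrix, matrix, np.ones(100, dtype=int))


class TestDiscretize:
    def test_boundary_is_positive(self):
        from weakrel.label_model import TrainingAnnotation

        anns = [TrainingAnnotation("c", 0.5)]
        assert discretize(anns, 0.5)[0].discretized == "positive"

    def test_extremes(self):
        from weakrel.label_model import TrainingAnnotation

        anns = [TrainingAnnotation("a", 0.0), TrainingAnnotation("b", 1.0)]
        out = discretize(anns)
        assert [a.discretized for a in out] == ["negative", "positive"]

    def test_monotone_in_threshold(self, rng):
        from weakrel.label_model import TrainingAnnotation

        anns = [
            TrainingAnnotation(f"c{i}", float(p))
            for i, p in enumerate(rng.random(50))
        ]
        low = {a.candidate_id for a in discretize(anns, 0.3)
               if a.discretized == "positive"}
        high = {a.candidate_id for a in discretize(anns, 0.7)
                if a.discretized == "positive"}
        assert high <= low

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            discretize([], threshold=1.0)
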