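"""Weighted fusion, cross-entropy cost and the genetic algorithm."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from levelk_eeg.fusion import (EnsembleWeights, GAParams, ce_cost,
                               equal_weight_baseline, ga_optimize, mean_cost,
                               weighted_predict)
from levelk_eeg.pipeline import (PipelineConfig, build_epochs,
                                 compute_features, compute_oof_predictions,
                                 fuse_and_evaluate)


def _random_triples(rng, n_ch, m):
    t = rng.uniform(size=(n_ch, m, 3))
    return t / t.sum(axis=2, keepdims=True)


def _one_hot(idx, m):
    out = np.zeros((m, 3))
    out[np.arange(m), idx] = 1.0
    return out


class TestWeightedPredict:
    def test_degenerate_weight_selects_single_channel(self):
        rng = np.random.default_rng(0)
        triples = _random_triples(rng, 6, 1)[:, 0, :]
        w = EnsembleWeights(np.array([1.0, 0, 0, 0, 0, 0]))
        assert np.allclose(weighted_predict(triples, w), triples[0])

    def test_equal_weights_average_two_channels(self):
        triples = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        out = weighted_predict(triples, np.array([1.0, 1.0]))
        assert np.allclose(out, [0.5, 0.5, 0.0])

    def test_output_is_convex_combination(self):
        rng = np.random.default_rng(1)
        triples = _random_triples(rng, 6, 20)
        out = weighted_predict(triples, rng.uniform(0.1, 1.0, 6))
        assert np.allclose(out.sum(axis=1), 1.0)
        assert np.all(out <= triples.max(axis=0) + 1e-12)
        assert np.all(out >= triples.min(axis=0) - 1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            EnsembleWeights(np.zeros(6))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    seed=st.integers(min_value=0, max_value=2**20),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_weight_scale_invariance(seed, scale):
    """Multiplying every channel weight by c > 0 leaves the fused output
    unchanged (the combination is normalised by the weight sum)."""
    rng = np.random.default_rng(seed)
    triples = _random_triples(rng, 6, 5)
    w = rng.uniform(0.05, 1.0, 6)
    assert np.allclose(
        weighted_predict(triples, w), weighted_predict(triples, scale * w),
        atol=1e-10,
    )


class TestCost:
    def test_perfect_prediction_costs_zero(self):
        assert ce_cost(np.array([1.0, 0, 0]), np.array([1, 0, 0])) == pytest.approx(0.0)

    def test_uniform_prediction_costs_ln3(self):
        cost = ce_cost(np.array([1 / 3, 1 / 3, 1 / 3]), np.array([0, 1, 0]))
        assert cost == pytest.approx(np.log(3.0))

    def test_quarter_probability_costs_ln4(self):
        cost = ce_cost(np.array([0.5, 0.25, 0.25]), np.array([0, 1, 0]))
        assert cost == pytest.approx(np.log(4.0))

    def test_non_one_hot_label_rejected(self):
        with pytest.raises(ValueError, match="one-hot"):
            ce_cost(np.array([0.5, 0.25, 0.25]), np.array([0.5, 0.5, 0]))

    def test_mean_cost_is_arithmetic_mean(self):
        triples = np.stack([
            np.array([[1 / 3, 1 / 3, 1 / 3], [1.0, 0.0, 0.0]]),
        ])
        labels = _one_hot(np.array([0, 0]), 2)
        j = mean_cost(np.ones(1), triples, labels)
        assert j == pytest.approx(np.log(3.0) / 2)

    def test_mean_cost_matches_per_example_summation_oracle(self):
        rng = np.random.default_rng(3)
        triples = _random_triples(rng, 4, 50)
        labels = _one_hot(rng.integers(0, 3, 50), 50)
        w = rng.uniform(0.1, 1.0, 4)
        j = mean_cost(w, triples, labels)
        oracle = np.mean([
            ce_cost(weighted_predict(triples[:, i, :], w), labels[i])
            for i in range(50)
        ])
        assert j == pytest.approx(oracle, abs=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            mean_cost(np.ones(2), np.zeros((2, 0, 3)), np.zeros((0, 3)))


class TestGAParams:
    def test_segment_sizes_must_sum_to_population(self):
        with pytest.raises(ValueError, match="population_size"):
            GAParams(population_size=100, n_keep=50, n_crossover=30, n_mutation=30)

    def test_full_scale_defaults_preserve_study_ratios(self):
        p = GAParams()
        assert (p.population_size, p.n_keep, p.n_crossover, p.n_mutation) == \
            (50_000, 15_000, 20_000, 15_000)
        t = GAParams.test_scale()
        assert t.n_keep / t.population_size == p.n_keep / p.population_size


class TestGAOptimize:
    def test_flat_landscape_any_weights_optimal(self):
        rng = np.random.default_rng(4)
        one = _random_triples(rng, 1, 30)
        triples = np.repeat(one, 6, axis=0)  # identical channels
        labels = _one_hot(rng.integers(0, 3, 30), 30)
        w, _ = ga_optimize(triples, labels, GAParams.test_scale(n_generations=5))
        assert mean_cost(w, triples, labels) == pytest.approx(
            mean_cost(equal_weight_baseline(6), triples, labels)
        )

    def test_best_cost_trace_is_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        triples = _random_triples(rng, 6, 40)
        labels = _one_hot(rng.integers(0, 3, 40), 40)
        _, trace = ga_optimize(triples, labels, GAParams.test_scale(n_generations=25))
        assert np.all(np.diff(trace) <= 1e-15)

    def test_two_channel_solution_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(6)
        triples = _random_triples(rng, 2, 20)
        labels = _one_hot(rng.integers(0, 3, 20), 20)
        w, _ = ga_optimize(triples, labels, GAParams.test_scale(n_generations=40))
        grid = np.linspace(0.0, 1.0, 101)
        grid_best = min(
            mean_cost(np.array([t, 1.0 - t]), triples, labels)
            for t in grid if 0.0 < t or t < 1.0
        )
        assert mean_cost(w, triples, labels) <= grid_best + 1e-3

    def test_ga_cost_never_exceeds_equal_weight_baseline(self):
        rng = np.random.default_rng(7)
        triples = _random_triples(rng, 6, 60)
        labels = _one_hot(rng.integers(0, 3, 60), 60)
        w, _ = ga_optimize(triples, labels, GAParams.test_scale(n_generations=30))
        assert mean_cost(w, triples, labels) <= mean_cost(
            equal_weight_baseline(6), triples, labels) + 1e-12

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError, match="one-hot"):
            ga_optimize(np.zeros((2, 5, 3)), np.zeros((4, 3)),
                        GAParams.test_scale(n_generations=2))


class TestEqualWeightBaseline:
    def test_six_equal_weights(self):
        w = equal_weight_baseline(6)
        assert np.allclose(w.normalized(), np.full(6, 1 / 6))

    def test_single_channel(self):
        assert np.allclose(equal_weight_baseline(1).values, [1.0])

    def test_baseline_prediction_is_unweighted_mean(self):
        rng = np.random.default_rng(8)
        triples = _random_triples(rng, 6, 10)
        out = weighted_predict(triples, equal_weight_baseline(6))
        assert np.allclose(out, triples.mean(axis=0))


def test_ga_concentrates_weight_on_informative_channel_pair():
    """When only F3/F4 carry task signal, the optimised weights on that pair
    should exceed the sum over the four silent channels (several seeds)."""
    silent = {"Fp1": 0.0, "Fp2": 0.0, "F7": 0.0, "F8": 0.0, "F3": 1.0, "F4": 1.0}
    wins = 0
    for seed in range(3):
        cfg = PipelineConfig(seed=200 + seed)
        cfg = cfg.model_copy(update={
            "design": cfg.design.model_copy(update={"n_participants": 2}),
            "signatures": {
                cond: {"channel_snr_profile": silent}
                for cond in ("resting", "picking", "coordination")
            },
        })
        epochs = build_epochs(cfg)
        feats = compute_features(cfg, epochs)
        oof = compute_oof_predictions(cfg, feats, epochs.labels)
        report = fuse_and_evaluate(cfg, oof, epochs.labels, epochs.channels)
        w = report["fused"]["weights"]
        if w["F3"] + w["F4"] > w["Fp1"] + w["Fp2"] + w["F7"] + w["F8"]:
            wins += 1
    assert wins >= 2
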