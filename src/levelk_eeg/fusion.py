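"""Weighted multi-channel fusion optimised by a genetic algorithm.

The ensemble prediction is a weighted average of the per-channel probability
triples,

    M_a(x) = sum_i a_i * M_i(x_i) / sum_i a_i,        a_i >= 0,

scored by the mean cross-entropy between fused prediction and one-hot label,

    J(a) = (1/m) * sum_k -log( M_a(x_k)[true class of x_k] ),

and minimised over the channel weights ``a`` with a genetic algorithm:
uniform random initial population, elitist selection of the best solutions,
arithmetic-blend crossover between fitness-ranked parents, and mutation that
perturbs one weight multiplicatively by 10-50%.  The equal-weights ensemble
serves as the baseline the optimiser must beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnsembleWeights",
    "GAParams",
    "weighted_predict",
    "ce_cost",
    "mean_cost",
    "ga_optimize",
    "equal_weight_baseline",
]

PROB_FLOOR = 1e-12  # floor inside log: confident wrong predictions stay finite


@dataclass
class EnsembleWeights:
    """One non-negative weight per channel; scale-invariant under Eq-style
    normalisation, so only the direction matters."""

    values: np.ndarray
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(self.values < 0):
            raise ValueError("weights must be non-negative")
        if self.values.sum() <= 0:
            raise ValueError("at least one weight must be positive")
        if self.channels and len(self.channels) != len(self.values):
            raise ValueError("channel names do not match weight vector length")

    def normalized(self) -> np.ndarray:
        return self.values / self.values.sum()

    def as_dict(self) -> dict[str, float]:
        names = self.channels or tuple(f"ch{i}" for i in range(len(self.values)))
        return {n: float(v) for n, v in zip(names, self.normalized())}


@dataclass
class GAParams:
    """Genetic-algorithm configuration.

    The full-scale defaults (population 50,000 split 15,000 kept / 20,000
    crossover / 15,000 mutation) match the study-scale search;
    ``test_scale`` shrinks the population 250-fold at the same 50:15:20:15
    ratio for fast runs.
    """

    population_size: int = 50_000
    n_keep: int = 15_000
    n_crossover: int = 20_000
    n_mutation: int = 15_000
    mutation_range: tuple[float, float] = (0.10, 0.50)
    n_generations: int = 50
    stagnation_generations: int = 10
    stagnation_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_keep + self.n_crossover + self.n_mutation != self.population_size:
            raise ValueError(
                "n_keep + n_crossover + n_mutation must equal population_size"
            )
        lo, hi = self.mutation_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("mutation_range must lie within (0, 1]")
        if min(self.n_keep, self.n_crossover, self.n_mutation) <= 0:
            raise ValueError("all population segments must be positive")

    @classmethod
    def test_scale(cls, seed: int = 0, n_generations: int = 50) -> "GAParams":
        return cls(population_size=200, n_keep=60, n_crossover=80, n_mutation=60,
                   n_generations=n_generations, seed=seed)


def weighted_predict(channel_triples: np.ndarray, weights: EnsembleWeights | np.ndarray) -> np.ndarray:
    """Fused probability triple(s): weighted average over channels.

    ``channel_triples``: (n_channels, 3) for a single example or
    (n_channels, m, 3) for a batch; returns (3,) or (m, 3).
    """
    if not isinstance(weights, EnsembleWeights):
        weights = EnsembleWeights(np.asarray(weights, dtype=float))
    triples = np.asarray(channel_triples, dtype=float)
    if triples.shape[0] != len(weights.values):
        raise ValueError("first axis of channel_triples must index channels")
    a = weights.normalized()
    return np.tensordot(a, triples, axes=(0, 0))


def _check_one_hot(label: np.ndarray) -> int:
    lab = np.asarray(label, dtype=float)
    if lab.shape != (3,) or not np.all((lab == 0) | (lab == 1)) or lab.sum() != 1:
        raise ValueError(f"label must be one-hot over 3 classes, got {label}")
    return int(np.argmax(lab))


def ce_cost(prediction: np.ndarray, label: np.ndarray) -> float:
    """Cross-entropy of one prediction against its one-hot label:
    -log(probability assigned to the true class), floored to stay finite."""
    pred = np.asarray(prediction, dtype=float)
    if pred.shape != (3,) or np.any(pred < 0) or abs(pred.sum() - 1.0) > 1e-6:
        raise ValueError(f"prediction must be a probability triple, got {prediction}")
    true = _check_one_hot(label)
    return float(-np.log(max(pred[true], PROB_FLOOR)))


def mean_cost(
    weights: EnsembleWeights | np.ndarray,
    channel_triples: np.ndarray,
    one_hot_labels: np.ndarray,
) -> float:
    """Mean cross-entropy J(a) of the fused model over the dataset.

    ``channel_triples``: (n_channels, m, 3); ``one_hot_labels``: (m, 3).
    """
    labels = np.asarray(one_hot_labels, dtype=float)
    if labels.ndim != 2 or labels.shape[1] != 3:
        raise ValueError("labels must be (m, 3) one-hot")
    m = labels.shape[0]
    if m == 0:
        raise ValueError("dataset must contain at least one example")
    fused = weighted_predict(channel_triples, weights)   # (m, 3)
    true_idx = np.argmax(labels, axis=1)
    p_true = fused[np.arange(m), true_idx]
    return float(-np.log(np.maximum(p_true, PROB_FLOOR)).mean())


def _population_costs(pop: np.ndarray, triples: np.ndarray, true_idx: np.ndarray) -> np.ndarray:
    """J(a) for every candidate row of ``pop`` (n_candidates, n_channels),
    evaluated in chunks to bound memory."""
    m = triples.shape[1]
    p_true_per_channel = triples[:, np.arange(m), true_idx]   # (n_channels, m)
    out = np.empty(len(pop))
    chunk = max(1, 4_000_000 // max(m, 1))
    sums = pop.sum(axis=1)
    for i in range(0, len(pop), chunk):
        block = pop[i:i + chunk]
        fused = block @ p_true_per_channel / sums[i:i + chunk, None]
        out[i:i + chunk] = -np.log(np.maximum(fused, PROB_FLOOR)).mean(axis=1)
    return out


def ga_optimize(
    channel_triples: np.ndarray,
    one_hot_labels: np.ndarray,
    params: GAParams | None = None,
    channels: tuple[str, ...] = (),
) -> tuple[EnsembleWeights, np.ndarray]:
    """Minimise J(a) over channel weights with the genetic algorithm.

    Returns the best weights found and the per-generation best-cost trace
    (non-increasing thanks to elitist selection).
    """
    params = params if params is not None else GAParams()
    triples = np.asarray(channel_triples, dtype=float)
    labels = np.asarray(one_hot_labels, dtype=float)
    if triples.ndim != 3 or triples.shape[2] != 3:
        raise ValueError("channel_triples must be (n_channels, m, 3)")
    if labels.shape != (triples.shape[1], 3):
        raise ValueError("labels must be (m, 3) one-hot, matching the triples")
    if triples.shape[1] == 0:
        raise ValueError("dataset must contain at least one example")
    n_channels = triples.shape[0]
    true_idx = np.argmax(labels, axis=1)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(0x6A01,)))

    pop = rng.uniform(0.0, 1.0, size=(params.population_size, n_channels))
    pop = np.maximum(pop, 1e-9)  # keep every candidate a valid weight vector
    trace: list[float] = []
    stagnant = 0
    for _gen in range(params.n_generations):
        costs = _population_costs(pop, triples, true_idx)
        order = np.argsort(costs, kind="stable")
        kept = pop[order[:params.n_keep]]
        best_cost = costs[order[0]]
        if trace and trace[-1] - best_cost < params.stagnation_tol:
            stagnant += 1
        else:
            stagnant = 0
        trace.append(float(min(best_cost, trace[-1] if trace else best_cost)))
        if stagnant >= params.stagnation_generations:
            break

        # crossover: arithmetic blend of two rank-selected parents
        ranks = np.arange(len(kept), 0, -1).astype(float)
        p_select = ranks / ranks.sum()
        pa = kept[rng.choice(len(kept), size=params.n_crossover, p=p_select)]
        pb = kept[rng.choice(len(kept), size=params.n_crossover, p=p_select)]
        lam = rng.uniform(0.0, 1.0, size=(params.n_crossover, 1))
        offspring = lam * pa + (1.0 - lam) * pb

        # mutation: multiply one uniformly chosen weight by 1 +/- U(10%, 50%)
        mut = kept[rng.integers(len(kept), size=params.n_mutation)].copy()
        which = rng.integers(n_channels, size=params.n_mutation)
        lo, hi = params.mutation_range
        magnitude = rng.uniform(lo, hi, size=params.n_mutation)
        sign = rng.choice([-1.0, 1.0], size=params.n_mutation)
        mut[np.arange(params.n_mutation), which] *= 1.0 + sign * magnitude
        mut = np.maximum(mut, 1e-9)

        pop = np.concatenate([kept, offspring, mut])

    costs = _population_costs(pop, triples, true_idx)
    best = pop[np.argmin(costs)]
    final_best = float(min(costs.min(), trace[-1] if trace else np.inf))
    if not trace or final_best < trace[-1]:
        trace.append(final_best)
    return EnsembleWeights(best, channels=tuple(channels)), np.asarray(trace)


def equal_weight_baseline(n_channels: int, channels: tuple[str, ...] = ()) -> EnsembleWeights:
    """The unweighted ensemble: equal weight on every channel."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    return EnsembleWeights(np.full(n_channels, 1.0 / n_channels), channels=tuple(channels))
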