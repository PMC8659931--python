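"""Optimise channel-fusion weights with the genetic algorithm.

Six channels emit probability triples; one (planted) channel is far more
informative than the rest.  The fused prediction is the weight-normalised
average of the channel triples, scored by mean cross-entropy J(a), and the
GA (selection / arithmetic crossover / 10-50% single-weight mutation)
minimises J over the weights.  It should concentrate the mass on the
informative channel and beat the equal-weights baseline.
"""

import numpy as np

from levelk_eeg import GAParams, equal_weight_baseline, ga_optimize, mean_cost

rng = np.random.default_rng(1)
m = 120
true_idx = rng.integers(0, 3, m)
labels = np.eye(3)[true_idx]

noisy = rng.uniform(size=(5, m, 3))
noisy /= noisy.sum(axis=2, keepdims=True)          # five uninformative channels
good = 0.15 * np.full((m, 3), 1 / 3) + 0.85 * labels  # one mostly-correct channel
triples = np.concatenate([good[None], noisy])

weights, trace = ga_optimize(triples, labels, GAParams.test_scale(n_generations=40))
baseline = equal_weight_baseline(6)

print(f"GA generations run: {len(trace)}, best J per generation is non-increasing")
print(f"J(GA weights)    = {mean_cost(weights, triples, labels):.4f}")
print(f"J(equal weights) = {mean_cost(baseline, triples, labels):.4f}")
print("normalised weights:", np.round(weights.normalized(), 3))
# The first entry (informative channel) should hold most of the mass.
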