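"""Decode the reasoning condition from single channels, out of fold.

Scalograms are embedded with the frozen surrogate backend; per channel,
three one-vs-all sigmoid heads are trained with class-balanced binary
cross-entropy under stratified 4-fold cross-validation.  Accuracy should
beat the 33.3% chance level on every channel, highest at F3/F4 (strongest
task signal) and lowest at F7/F8.
"""

import numpy as np

from levelk_eeg.pipeline import (PipelineConfig, build_epochs,
                                 compute_features, compute_oof_predictions)

config = PipelineConfig(seed=1)
config = config.model_copy(update={
    "design": config.design.model_copy(update={"n_participants": 3}),
})
epochs = build_epochs(config)
features = compute_features(config, epochs)
oof = compute_oof_predictions(config, features, epochs.labels)

print(f"{epochs.m} epochs, {len(epochs.channels)} channels, chance = 33.3%")
for name in epochs.channels:
    acc = 100 * np.mean(oof[name]["predicted"] == epochs.labels)
    n_correct = int(np.sum(oof[name]["predicted"] == epochs.labels))
    print(f"  {name:>4}: {acc:5.1f}%  ({n_correct}/{epochs.m} correct)")
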