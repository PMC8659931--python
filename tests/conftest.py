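import pytest

from levelk_eeg.pipeline import (PipelineConfig, build_epochs, compute_features,
                                 compute_oof_predictions)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline state at the default design (10 participants, 840 epochs):
    simulated + preprocessed epochs, surrogate-embedded features, and
    out-of-fold one-vs-all predictions for every channel."""
    cfg = PipelineConfig(seed=11)
    epochs = build_epochs(cfg)
    features = compute_features(cfg, epochs)
    oof = compute_oof_predictions(cfg, features, epochs.labels)
    return {"config": cfg, "epochs": epochs, "features": features, "oof": oof}
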