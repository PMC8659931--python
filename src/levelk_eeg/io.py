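"""File formats for pipeline artifacts.

Arrays live in ``.npz`` containers with named datasets; event tables, epoch
labels and out-of-fold predictions are TSV; models, weights and reports are
JSON.  Everything round-trips bit-exactly for float64 payloads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import BinaryHead, ChannelModel
from .preprocess import EpochSet
from .synthetic import Event, RawRecording

__all__ = [
    "save_recording", "load_recording",
    "save_epochs", "load_epochs",
    "save_features", "load_features",
    "save_channel_models", "load_channel_models",
    "write_json", "read_json",
]


def save_recording(rec: RawRecording, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        prefix.with_suffix(".npz"),
        signal=rec.signal,
        sampling_rate=np.array(rec.sampling_rate),
        channels=np.array(rec.channels),
        participant_id=np.array(rec.participant_id),
    )
    events = pd.DataFrame(
        [(e.onset, e.condition, e.trial) for e in rec.events],
        columns=["onset_sample", "condition", "trial"],
    )
    events.to_csv(prefix.parent / f"{prefix.name}_events.tsv", sep="\t", index=False)


def load_recording(prefix: Path) -> RawRecording:
    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as data:
        signal = data["signal"]
        rate = float(data["sampling_rate"])
        channels = tuple(str(c) for c in data["channels"])
        pid = int(data["participant_id"])
    events_df = pd.read_csv(prefix.parent / f"{prefix.name}_events.tsv", sep="\t")
    events = [
        Event(int(r.onset_sample), str(r.condition), int(r.trial))
        for r in events_df.itertuples()
    ]
    return RawRecording(participant_id=pid, signal=signal, sampling_rate=rate,
                        channels=channels, events=events)


def save_epochs(es: EpochSet, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        prefix.with_suffix(".npz"),
        epochs=es.epochs,
        participant_ids=es.participant_ids,
        channels=np.array(es.channels),
        epoch_rate=np.array(es.epoch_rate),
    )
    labels = pd.DataFrame({
        "epoch": np.arange(es.m),
        "label": es.labels.astype(str),
        "participant": es.participant_ids,
    })
    labels.to_csv(prefix.parent / f"{prefix.name}_labels.tsv", sep="\t", index=False)


def load_epochs(prefix: Path) -> EpochSet:
    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as data:
        epochs = data["epochs"]
        pids = data["participant_ids"]
        channels = tuple(str(c) for c in data["channels"])
        rate = float(data["epoch_rate"])
    labels_df = pd.read_csv(prefix.parent / f"{prefix.name}_labels.tsv", sep="\t")
    return EpochSet(epochs=epochs, labels=labels_df["label"].to_numpy(dtype=object),
                    participant_ids=pids, channels=channels, epoch_rate=rate)


def save_features(features: dict[str, np.ndarray], path: Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"ch_{name}": mat for name, mat in features.items()}
    if meta:
        arrays["_meta"] = np.array(json.dumps(meta, sort_keys=True))
    np.savez(path, **arrays)


def load_features(path: Path) -> tuple[dict[str, np.ndarray], dict]:
    features, meta = {}, {}
    with np.load(Path(path)) as data:
        for key in data.files:
            if key == "_meta":
                meta = json.loads(str(data[key]))
            elif key.startswith("ch_"):
                features[key[3:]] = data[key]
    return features, meta


def save_channel_models(models: dict[str, ChannelModel], path: Path,
                        backend_fingerprint: str = "") -> None:
    payload = {"backend_fingerprint": backend_fingerprint, "channels": {}}
    for name, model in models.items():
        payload["channels"][name] = {
            "feature_mean": None if model.feature_mean is None else model.feature_mean.tolist(),
            "feature_scale": None if model.feature_scale is None else model.feature_scale.tolist(),
            "heads": {
                cls: {
                    "weights": head.weights.tolist(),
                    "bias": head.bias,
                    "target_class": head.target_class,
                }
                for cls, head in model.heads.items()
            },
        }
    write_json(payload, path)


def load_channel_models(path: Path) -> tuple[dict[str, ChannelModel], str]:
    payload = read_json(path)
    models = {}
    for name, entry in payload["channels"].items():
        heads = {
            cls: BinaryHead(weights=np.array(h["weights"]), bias=float(h["bias"]),
                            target_class=h["target_class"])
            for cls, h in entry["heads"].items()
        }
        models[name] = ChannelModel(
            heads=heads,
            channel=name,
            feature_mean=None if entry["feature_mean"] is None else np.array(entry["feature_mean"]),
            feature_scale=None if entry["feature_scale"] is None else np.array(entry["feature_scale"]),
        )
    return models, payload.get("backend_fingerprint", "")


def write_json(obj, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Path):
    return json.loads(Path(path).read_text())
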