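"""End-to-end orchestration: simulate -> preprocess -> featurize -> embed ->
train -> fuse -> evaluate, from one validated config with fixed seeds.

A single master seed fans out into named substreams (simulation, embedding,
fold assignment, GA) so stages can be rerun independently without disturbing
each other; under the surrogate embedding backend the whole run is
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import io as lkio
from .classifiers import (cross_validated_predictions, renormalize_triples,
                          train_channel_model)
from .cwt import SUPPORTED_ORDERS, cwt_scalograms
from .embedding import SurrogateBackend, embed_dataset, make_backend
from .fusion import (EnsembleWeights, GAParams, equal_weight_baseline,
                     ga_optimize, mean_cost, weighted_predict)
from .metrics import (channel_comparison, class_metrics, confusion,
                      first_order_errors_only, format_percent)
from .preprocess import assemble_dataset, preprocess_recording, EpochSet
from .synthetic import (CONDITIONS, DEFAULT_CHANNELS, ConditionSignature,
                        ExperimentDesign, default_signatures, generate_dataset)

__all__ = ["PipelineConfig", "run_pipeline", "wavelet_grid", "load_config"]

log = logging.getLogger("levelk")


# ---------------------------------------------------------------------------
# configuration

class DesignConfig(BaseModel):
    n_participants: int = 10
    n_trials_per_condition: int = 12
    rs_duration: float = 120.0
    rs_epoch_window: tuple[float, float] = (30.0, 90.0)
    standby_interval: tuple[float, float] = (2.0, 2.5)
    trial_max_duration: float = 8.0
    sampling_rate: int = 512
    channels: tuple[str, ...] = DEFAULT_CHANNELS


class FilterConfig(BaseModel):
    low: float = 1.0
    high: float = 32.0


class EmbeddingConfig(BaseModel):
    backend: str = "surrogate"
    input_size: tuple[int, int] = (32, 64)


class GAConfig(BaseModel):
    scale: str = "test"  # "test" (population 200) or "full" (population 50,000)
    n_generations: int = 50

    @field_validator("scale")
    @classmethod
    def _known_scale(cls, v: str) -> str:
        if v not in ("test", "full"):
            raise ValueError("ga.scale must be 'test' or 'full'")
        return v

    def params(self, seed: int) -> GAParams:
        if self.scale == "full":
            return GAParams(n_generations=self.n_generations, seed=seed)
        return GAParams.test_scale(seed=seed, n_generations=self.n_generations)


class PipelineConfig(BaseModel):
    """Everything one run needs; YAML-serialisable and hashable."""

    seed: int = 0
    design: DesignConfig = Field(default_factory=DesignConfig)
    signatures: dict[str, dict] = Field(default_factory=dict)  # per-condition overrides
    filter: FilterConfig = Field(default_factory=FilterConfig)
    wavelet_order: int = 6
    embedding: EmbeddingConfig = Field(default_factory=EmbeddingConfig)
    folds: int = 4
    ga: GAConfig = Field(default_factory=GAConfig)

    @field_validator("wavelet_order")
    @classmethod
    def _valid_order(cls, v: int) -> int:
        if v not in SUPPORTED_ORDERS:
            raise ValueError(f"wavelet_order must be one of {SUPPORTED_ORDERS}")
        return v

    def experiment_design(self) -> ExperimentDesign:
        return ExperimentDesign(seed=self.substream("simulate"), **self.design.model_dump())

    def condition_signatures(self) -> dict[str, ConditionSignature]:
        sigs = default_signatures()
        for cond, overrides in self.signatures.items():
            if cond not in sigs:
                raise ValueError(f"unknown condition '{cond}' in signature overrides")
            fixed = {
                k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
            }
            sigs[cond] = replace(sigs[cond], **fixed)
        return sigs

    def substream(self, name: str) -> int:
        """Deterministic integer sub-seed for a named stage."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# in-memory stages

def build_epochs(config: PipelineConfig) -> EpochSet:
    """Simulate the full dataset and run the preprocessing pipeline."""
    design = config.experiment_design()
    recordings = generate_dataset(design, config.condition_signatures())
    epoch_sets = [
        preprocess_recording(rec, low=config.filter.low, high=config.filter.high,
                             rs_window=design.rs_epoch_window)
        for rec in recordings
    ]
    return assemble_dataset(epoch_sets)


def compute_features(config: PipelineConfig, epochs: EpochSet,
                     wavelet_order: int | None = None) -> dict[str, np.ndarray]:
    """Scalograms + frozen embedding -> one (m, d) matrix per channel name."""
    order = wavelet_order if wavelet_order is not None else config.wavelet_order
    stack = cwt_scalograms(epochs.epochs, wavelet_order=order)
    backend = make_backend(config.embedding.backend, seed=config.substream("embedding"),
                           input_size=config.embedding.input_size)
    by_index = embed_dataset(stack, backend)
    return {name: by_index[i] for i, name in enumerate(epochs.channels)}


def compute_oof_predictions(config: PipelineConfig, features: dict[str, np.ndarray],
                            labels: np.ndarray) -> dict[str, dict]:
    """Out-of-fold sigmoid triples and argmax labels for every channel."""
    seed = config.substream("folds")
    out = {}
    for name, mat in features.items():
        raw, pred, folds = cross_validated_predictions(
            mat, labels, k=config.folds, seed=seed, channel=name
        )
        out[name] = {"raw_triples": raw, "predicted": pred, "folds": folds}
    return out


def fuse_and_evaluate(config: PipelineConfig, oof: dict[str, dict],
                      labels: np.ndarray, channels: Sequence[str]) -> dict:
    """GA-weighted fusion of the per-channel triples, with the equal-weights
    baseline, and the full metrics report."""
    channels = list(channels)
    labels = np.asarray(labels)
    one_hot = np.zeros((len(labels), len(CONDITIONS)))
    for j, c in enumerate(CONDITIONS):
        one_hot[labels == c, j] = 1.0
    triples = np.stack([renormalize_triples(oof[name]["raw_triples"]) for name in channels])

    ga_weights, trace = ga_optimize(
        triples, one_hot, params=config.ga.params(config.substream("ga")),
        channels=tuple(channels),
    )
    baseline = equal_weight_baseline(len(channels), channels=tuple(channels))

    report = {
        "m": int(len(labels)),
        "label_counts": {c: int(np.sum(labels == c)) for c in CONDITIONS},
        "per_channel": {},
        "fused": _evaluate_weights(ga_weights, triples, one_hot, labels),
        "baseline": _evaluate_weights(baseline, triples, one_hot, labels),
        "ga_trace": [float(v) for v in trace],
    }
    for name in channels:
        pred = oof[name]["predicted"]
        cm = confusion(labels, pred)
        stats = class_metrics(cm)
        report["per_channel"][name] = {
            "accuracy_pct": format_percent(stats["accuracy"]),
            "n_correct": stats["n_correct"],
            "confusion": cm.counts.tolist(),
        }
    report["channel_gap"] = channel_comparison({
        name: (entry["accuracy_pct"], entry["n_correct"])
        for name, entry in report["per_channel"].items()
    })
    return report


def _evaluate_weights(weights: EnsembleWeights, triples: np.ndarray,
                      one_hot: np.ndarray, labels: np.ndarray) -> dict:
    fused = weighted_predict(triples, weights)           # (m, 3)
    pred = np.array([CONDITIONS[i] for i in np.argmax(fused, axis=1)], dtype=object)
    cm = confusion(labels, pred)
    stats = class_metrics(cm)
    per_class = {
        label: {k: format_percent(v) for k, v in vals.items()}
        for label, vals in stats["per_class"].items()
    }
    return {
        "weights": weights.as_dict(),
        "mean_ce_cost": mean_cost(weights, triples, one_hot),
        "accuracy_pct": format_percent(stats["accuracy"]),
        "n_correct": stats["n_correct"],
        "per_class_pct": per_class,
        "confusion": cm.counts.tolist(),
        "first_order_errors_only": first_order_errors_only(cm),
    }


# ---------------------------------------------------------------------------
# persistent pipeline

def run_pipeline(config: PipelineConfig, out_dir: Path) -> dict:
    """Execute every stage, persisting intermediates under ``out_dir``.

    Returns the final report (also written to ``report.json`` /
    ``report.txt``); reruns with the same config and seed reproduce the
    report bit-identically under the surrogate backend.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulate: %d participants", config.design.n_participants)
    design = config.experiment_design()
    recordings = generate_dataset(design, config.condition_signatures())
    for rec in recordings:
        lkio.save_recording(rec, out / "recordings" / f"participant_{rec.participant_id:02d}")

    log.info("preprocess: band-pass (%g, %g) Hz, downsample to 64 Hz",
             config.filter.low, config.filter.high)
    epochs = assemble_dataset([
        preprocess_recording(rec, low=config.filter.low, high=config.filter.high,
                             rs_window=design.rs_epoch_window)
        for rec in recordings
    ])
    lkio.save_epochs(epochs, out / "epochs")

    log.info("featurize + embed: sym%d scalograms, %s backend",
             config.wavelet_order, config.embedding.backend)
    backend = make_backend(config.embedding.backend, seed=config.substream("embedding"),
                           input_size=config.embedding.input_size)
    features = compute_features(config, epochs)
    lkio.save_features(features, out / "features.npz", meta={
        "backend_id": backend.backend_id,
        "backend_fingerprint": backend.weight_fingerprint,
        "wavelet_order": config.wavelet_order,
    })

    log.info("train: %d-fold CV, one-vs-all heads per channel", config.folds)
    oof = compute_oof_predictions(config, features, epochs.labels)
    _save_oof(oof, epochs.labels, out / "oof_predictions.tsv")
    models = {
        name: train_channel_model(features[name], epochs.labels, channel=name,
                                  seed=config.substream("folds"))
        for name in epochs.channels
    }
    lkio.save_channel_models(models, out / "channel_models.json",
                             backend_fingerprint=backend.weight_fingerprint)

    log.info("fuse: GA over channel weights (%s scale)", config.ga.scale)
    report = fuse_and_evaluate(config, oof, epochs.labels, epochs.channels)

    lkio.write_json(report["fused"]["weights"], out / "fusion_weights.json")
    pd.DataFrame(
        sorted(report["fused"]["weights"].items()), columns=["channel", "weight"]
    ).to_csv(out / "fusion_weights.csv", index=False)
    pd.DataFrame(
        report["fused"]["confusion"], index=list(CONDITIONS), columns=list(CONDITIONS)
    ).to_csv(out / "confusion_matrix.csv")
    lkio.write_json(report, out / "report.json")
    (out / "report.txt").write_text(render_report(report))
    lkio.write_json({
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "substreams": {n: config.substream(n) for n in ("simulate", "embedding", "folds", "ga")},
        "backend_fingerprint": backend.weight_fingerprint,
    }, out / "manifest.json")
    return report


def _save_oof(oof: dict[str, dict], labels: np.ndarray, path: Path) -> None:
    rows = []
    for name, entry in oof.items():
        raw = entry["raw_triples"]
        for i in range(len(labels)):
            rows.append({
                "epoch_id": i, "channel": name,
                "p_rest": raw[i, 0], "p_pick": raw[i, 1], "p_coord": raw[i, 2],
                "true": labels[i], "predicted": entry["predicted"][i],
                "fold": int(entry["folds"][i]),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def render_report(report: dict) -> str:
    lines = [
        f"epochs: {report['m']}  ({report['label_counts']})",
        "",
        "per-channel out-of-fold accuracy:",
    ]
    for name, entry in report["per_channel"].items():
        lines.append(f"  {name:>4}: {entry['accuracy_pct']:6.2f}%  ({entry['n_correct']} correct)")
    gap = report["channel_gap"]
    lines += [
        f"best {gap['best_channel']} vs worst {gap['worst_channel']}: "
        f"{gap['gap_percentage_points']:.2f} points ({gap['gap_correct_counts']} epochs)",
        "",
        f"fused (GA weights): accuracy {report['fused']['accuracy_pct']:.2f}% "
        f"({report['fused']['n_correct']}/{report['m']}), "
        f"mean CE cost {report['fused']['mean_ce_cost']:.4f}",
        f"baseline (equal weights): accuracy {report['baseline']['accuracy_pct']:.2f}%, "
        f"mean CE cost {report['baseline']['mean_ce_cost']:.4f}",
        f"GA weights: {report['fused']['weights']}",
        f"first-order errors only: {report['fused']['first_order_errors_only']}",
        "",
    ]
    return "\n".join(lines)


def wavelet_grid(config: PipelineConfig,
                 orders: Sequence[int] = SUPPORTED_ORDERS) -> pd.DataFrame:
    """Mean CE cost of the GA-optimal fusion for each Symlet order.

    The epochs are built once; featurization, training and fusion rerun per
    order.  The row with the lowest cost is flagged best.
    """
    for order in orders:
        if order not in SUPPORTED_ORDERS:
            raise ValueError(f"unsupported wavelet order {order}")
    epochs = build_epochs(config)
    rows = []
    for order in orders:
        features = compute_features(config, epochs, wavelet_order=order)
        oof = compute_oof_predictions(config, features, epochs.labels)
        report = fuse_and_evaluate(config, oof, epochs.labels, epochs.channels)
        rows.append({
            "wavelet_order": order,
            "mean_ce_cost": report["fused"]["mean_ce_cost"],
            "fused_accuracy_pct": report["fused"]["accuracy_pct"],
        })
    table = pd.DataFrame(rows)
    table["best"] = table["mean_ce_cost"] == table["mean_ce_cost"].min()
    return table
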