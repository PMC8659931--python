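"""Per-channel one-vs-all classification of embedding features.

Each channel gets three binary heads (one affine unit + sigmoid per class),
trained with class-balanced binary cross-entropy by deterministic full-batch
gradient descent.  The three raw sigmoid outputs are combined by argmax into
a 3-class prediction; for the fusion stage they are renormalised into a
probability triple.  Out-of-fold predictions come from stratified 4-fold
cross-validation, so every epoch is predicted by a model never trained on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .synthetic import CONDITIONS

__all__ = [
    "BinaryHead",
    "ChannelModel",
    "balanced_class_weights",
    "train_binary_head",
    "train_channel_model",
    "ova_predict",
    "renormalize_triples",
    "fold_assignment",
    "cross_validated_predictions",
]


@dataclass
class BinaryHead:
    """Single affine unit + sigmoid for one target class."""

    weights: np.ndarray
    bias: float
    target_class: str
    n_iterations: int = 0
    final_loss: float = np.nan

    def decision(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weights + self.bias

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision(features))


@dataclass
class ChannelModel:
    """Three one-vs-all heads for one channel, plus its feature scaler."""

    heads: dict[str, BinaryHead]
    channel: str = ""
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if set(self.heads) != set(CONDITIONS):
            raise ValueError(f"need exactly one head per class {CONDITIONS}")

    def _scale(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if self.feature_mean is not None:
            features = (features - self.feature_mean) / self.feature_scale
        return features

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Raw sigmoid outputs, one column per class in CONDITIONS order."""
        scaled = self._scale(features)
        return np.column_stack([self.heads[c].predict_proba(scaled) for c in CONDITIONS])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def balanced_class_weights(binary_labels: np.ndarray) -> np.ndarray:
    """Per-class weights inversely proportional to class frequency,
    normalised to mean 1 over the two classes; returned as (w_neg, w_pos)."""
    y = np.asarray(binary_labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both binary classes must be present")
    inv = np.array([1.0 / n_neg, 1.0 / n_pos])
    return inv / inv.mean()


def _weighted_bce(p: np.ndarray, y: np.ndarray, sw: np.ndarray) -> float:
    eps = 1e-12
    ll = y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)
    return float(-(sw * ll).mean())


def train_binary_head(
    features: np.ndarray,
    binary_labels: np.ndarray,
    class_weights: np.ndarray | str = "balanced",
    target_class: str = "",
    learning_rate: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> BinaryHead:
    """Fit one sigmoid unit by deterministic full-batch gradient descent.

    The step size is halved whenever a step would increase the loss, so the
    recorded loss sequence is non-increasing.  Initialisation is a seeded
    near-zero draw; identical inputs give identical heads.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(binary_labels, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (m, d) matching labels")
    if len(y) == 0 or y.min() == y.max():
        raise ValueError("training set contains a single class")
    if isinstance(class_weights, str):
        if class_weights != "balanced":
            raise ValueError(f"unknown class_weights '{class_weights}'")
        class_weights = balanced_class_weights(y)
    w_neg, w_pos = class_weights
    sw = np.where(y == 1.0, w_pos, w_neg)

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x1EAD,)))
    w = rng.normal(0.0, 1e-3, size=X.shape[1])
    b = float(rng.normal(0.0, 1e-3))

    lr = learning_rate
    p = _sigmoid(X @ w + b)
    loss = _weighted_bce(p, y, sw)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        resid = sw * (p - y) / len(y)
        grad_w = X.T @ resid
        grad_b = float(resid.sum())
        while True:
            w_new = w - lr * grad_w
            b_new = b - lr * grad_b
            p_new = _sigmoid(X @ w_new + b_new)
            loss_new = _weighted_bce(p_new, y, sw)
            if loss_new <= loss or lr < 1e-12:
                break
            lr *= 0.5
        improvement = loss - loss_new
        w, b, p, loss = w_new, b_new, p_new, loss_new
        if 0 <= improvement < tol:
            break
    return BinaryHead(weights=w, bias=b, target_class=target_class,
                      n_iterations=n_iter, final_loss=loss)


def train_channel_model(
    features: np.ndarray,
    labels: np.ndarray,
    channel: str = "",
    seed: int = 0,
    standardize: bool = True,
    **gd_kwargs,
) -> ChannelModel:
    """Train the three one-vs-all heads for one channel's feature matrix."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-12] = 1.0
        Xs = (X - mean) / scale
    else:
        mean = scale = None
        Xs = X
    heads = {}
    for c in CONDITIONS:
        heads[c] = train_binary_head(
            Xs, (labels == c).astype(float), target_class=c, seed=seed, **gd_kwargs
        )
    return ChannelModel(heads=heads, channel=channel,
                        feature_mean=mean, feature_scale=scale)


def ova_predict(model: ChannelModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw sigmoid triples and argmax labels for one or more feature vectors.

    Ties resolve to the first class in the fixed order
    (resting < picking < coordination).
    """
    triples = model.predict_proba(features)
    labels = np.array([CONDITIONS[i] for i in np.argmax(triples, axis=1)], dtype=object)
    return triples, labels


def renormalize_triples(raw_triples: np.ndarray) -> np.ndarray:
    """Turn raw sigmoid triples into probability vectors summing to 1.

    An all-zero triple maps to the uniform distribution.
    """
    raw = np.atleast_2d(np.asarray(raw_triples, dtype=float))
    sums = raw.sum(axis=1, keepdims=True)
    out = np.where(sums > 0, raw / np.where(sums > 0, sums, 1.0), 1.0 / raw.shape[1])
    return out


def fold_assignment(labels: np.ndarray, k: int = 4, seed: int = 0) -> np.ndarray:
    """Stratified fold index per epoch (0..k-1), seeded."""
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError(f"need at least k={k} epochs, got {len(labels)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for fold, (_train, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[test] = fold
    return folds


def cross_validated_predictions(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 4,
    seed: int = 0,
    channel: str = "",
    **gd_kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Out-of-fold raw sigmoid triples for every epoch.

    Returns ``(raw_triples (m, 3), predicted labels (m,), fold index (m,))``;
    each epoch is predicted exactly once, by a model trained on the other
    k-1 folds.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    folds = fold_assignment(labels, k=k, seed=seed)
    triples = np.empty((len(labels), len(CONDITIONS)))
    predicted = np.empty(len(labels), dtype=object)
    for fold in range(k):
        train = folds != fold
        test = ~train
        missing = set(CONDITIONS) - set(np.unique(labels[train]))
        if missing:
            raise ValueError(
                f"fold {fold}: classes {sorted(missing)} absent from the training split"
            )
        model = train_channel_model(X[train], labels[train], channel=channel,
                                    seed=seed, **gd_kwargs)
        t, p = ova_predict(model, X[test])
        triples[test] = t
        predicted[test] = p
    return triples, predicted, folds
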