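"""Frozen image-embedding backends for scalogram features.

The classifier heads never see raw scalograms; they see fixed-length vectors
produced by a frozen feature extractor.  Two backends satisfy the same
contract:

* ``SurrogateBackend`` -- a seeded random convolution bank (32 filters of
  3x3x3), ReLU, and global average pooling.  Deterministic, dependency-free,
  and Lipschitz in the input, which makes it the default for testing and
  offline runs.
* ``PretrainedCNNBackend`` -- a placeholder for an ImageNet-pretrained
  convolutional network whose last pooling layer supplies the features.  It
  requires a deep-learning runtime with downloaded weights and raises a
  clear error here directing users to the surrogate.

Backends are pure functions of their weights: the weight fingerprint ties
cached features to the exact extractor that produced them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmbeddingBackend", "SurrogateBackend", "PretrainedCNNBackend",
           "make_backend", "embed_dataset"]


class EmbeddingBackend:
    """Contract: ``embed(image) -> (output_dim,)`` vector, frozen weights."""

    backend_id: str
    input_size: tuple[int, int]
    output_dim: int

    @property
    def weight_fingerprint(self) -> str:
        raise NotImplementedError

    def embed(self, image: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class SurrogateBackend(EmbeddingBackend):
    """Random 3x3 convolution bank + ReLU + regional average pooling.

    Responses are averaged within an ``pool_grid`` grid of image regions
    (default 8 scale-bands x 4 time-bins) rather than globally: a scalogram's
    class signature lives in *where* energy concentrates along the scale and
    time axes, which a global average would erase.

    With bounded weights the map is Lipschitz: a perturbation of the input
    bounded by eps in max-norm changes each output coordinate by at most
    ``lipschitz_bound() * eps``.
    """

    seed: int = 0
    input_size: tuple[int, int] = (32, 64)
    n_filters: int = 32
    pool_grid: tuple[int, int] = (8, 4)
    backend_id: str = field(default="surrogate", init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(0xE3BD,)))
        self.filters = rng.uniform(-1.0, 1.0, size=(self.n_filters, 3, 3, 3))
        self.biases = rng.uniform(-0.5, 0.5, size=self.n_filters)
        self.output_dim = self.n_filters * self.pool_grid[0] * self.pool_grid[1]

    @property
    def weight_fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(b"surrogate:conv3x3-relu-gap:")
        h.update(self.filters.tobytes())
        h.update(self.biases.tobytes())
        return h.hexdigest()[:16]

    def lipschitz_bound(self) -> float:
        """max-norm Lipschitz constant per output coordinate."""
        return float(np.max(np.sum(np.abs(self.filters), axis=(1, 2, 3))))

    def _check(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != (*self.input_size, 3):
            raise ValueError(
                f"image shape {image.shape} does not match backend input "
                f"{(*self.input_size, 3)}"
            )
        return image

    def embed(self, image: np.ndarray) -> np.ndarray:
        return self.embed_batch(self._check(image)[None])[0]

    def embed_batch(self, images: np.ndarray) -> np.ndarray:
        """(batch, H, W, 3) -> (batch, n_filters); valid convolution."""
        images = np.asarray(images, dtype=float)
        if images.ndim != 4 or images.shape[1:] != (*self.input_size, 3):
            raise ValueError(
                f"batch shape {images.shape} does not match backend input "
                f"(n, {self.input_size[0]}, {self.input_size[1]}, 3)"
            )
        # windows: (b, H-2, W-2, C, 3, 3); flatten each patch and use BLAS
        windows = np.lib.stride_tricks.sliding_window_view(images, (3, 3), axis=(1, 2))
        h, w = windows.shape[1], windows.shape[2]
        n_pos = h * w
        filt = self.filters.transpose(1, 2, 3, 0).reshape(27, self.n_filters)  # (c,i,j,f)
        rows = np.array_split(np.arange(h), self.pool_grid[0])
        cols = np.array_split(np.arange(w), self.pool_grid[1])
        out = np.empty((len(images), self.output_dim))
        step = max(1, 4_000_000 // max(n_pos, 1))
        for i in range(0, len(images), step):
            win = windows[i:i + step]
            patches = np.ascontiguousarray(win).reshape(win.shape[0], n_pos, 27)
            resp = np.maximum(patches @ filt + self.biases, 0.0)   # ReLU
            resp = resp.reshape(win.shape[0], h, w, self.n_filters)
            pooled = [
                resp[:, rb][:, :, cb].mean(axis=(1, 2))            # regional average
                for rb in rows for cb in cols
            ]
            out[i:i + step] = np.concatenate(pooled, axis=1)
        return out


@dataclass
class PretrainedCNNBackend(EmbeddingBackend):
    """ImageNet-pretrained convolutional feature extractor (last pooling layer).

    Needs a deep-learning runtime (e.g. torch or tensorflow) plus downloaded
    weights, neither of which this package ships; constructing it raises with
    guidance to use the surrogate.  The fingerprint would record the
    architecture, the weight hash and the pooling layer tapped.
    """

    architecture: str = "vgg16"
    input_size: tuple[int, int] = (224, 224)
    backend_id: str = field(default="pretrained-cnn", init=False)

    def __post_init__(self) -> None:
        raise RuntimeError(
            f"pretrained backend '{self.architecture}' is unavailable: no deep-"
            "learning runtime with ImageNet weights is installed. Use the "
            "'surrogate' backend (SurrogateBackend / backend: surrogate in the "
            "config), which needs no downloads."
        )


def make_backend(backend_id: str, seed: int = 0,
                 input_size: tuple[int, int] = (32, 64)) -> EmbeddingBackend:
    if backend_id == "surrogate":
        return SurrogateBackend(seed=seed, input_size=tuple(input_size))
    if backend_id == "pretrained-cnn":
        return PretrainedCNNBackend(input_size=tuple(input_size))
    raise ValueError(f"unknown backend '{backend_id}'")


def embed_dataset(scalogram_stack: np.ndarray, backend: EmbeddingBackend,
                  target_size: tuple[int, int] | None = None) -> dict[int, np.ndarray]:
    """Embed every epoch-channel scalogram.

    ``scalogram_stack``: (m, n_channels, 32, 64) magnitudes.  Returns one
    (m, output_dim) matrix per channel index, rows in epoch order.
    """
    from .cwt import scalogram_to_image

    stack = np.asarray(scalogram_stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("scalogram stack must be (m, n_channels, scales, samples)")
    m, n_ch = stack.shape[:2]
    size = tuple(target_size) if target_size is not None else backend.input_size
    features: dict[int, np.ndarray] = {}
    for c in range(n_ch):
        if m == 0:
            features[c] = np.zeros((0, backend.output_dim))
            continue
        images = np.stack([scalogram_to_image(stack[i, c], size) for i in range(m)])
        if isinstance(backend, SurrogateBackend):
            features[c] = backend.embed_batch(images)
        else:
            features[c] = np.stack([backend.embed(img) for img in images])
    return features
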