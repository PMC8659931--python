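"""Continuous wavelet transform scalograms with Symlet wavelets.

Each 64-sample epoch-channel becomes a 32 x 64 image: row *s* holds the
magnitude of the CWT coefficients at integer scale *s* (s = 1..32).  Larger
scales correspond to lower frequencies.  Symlets are discrete orthogonal
wavelets, so the transform is computed directly: the mother wavelet is
sampled from its compact support (via PyWavelets' ``wavefun``), rescaled to
each scale with 1/sqrt(s) normalisation, and convolved with the
symmetrically padded signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import map_coordinates

__all__ = [
    "SUPPORTED_ORDERS",
    "N_SCALES",
    "Scalogram",
    "wavelet_kernel",
    "cwt_scalogram",
    "cwt_scalograms",
    "scalogram_to_image",
]

SUPPORTED_ORDERS = (2, 4, 6, 8, 10)
N_SCALES = 32
EPOCH_SAMPLES = 64


@dataclass
class Scalogram:
    """32-scale x 64-sample CWT magnitude image for one epoch-channel."""

    values: np.ndarray                  # (32, 64), non-negative
    wavelet_order: int
    channel: str = ""
    epoch_index: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SCALES, EPOCH_SAMPLES):
            raise ValueError(f"scalogram must be {(N_SCALES, EPOCH_SAMPLES)}, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("scalogram magnitudes must be non-negative")

    @property
    def scales(self) -> np.ndarray:
        return np.arange(1, N_SCALES + 1)


@lru_cache(maxsize=None)
def _mother_wavelet(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled Symlet mother wavelet psi(x) on its support grid."""
    if order not in SUPPORTED_ORDERS:
        raise ValueError(f"wavelet order must be one of {SUPPORTED_ORDERS}, got {order}")
    wavelet = pywt.Wavelet(f"sym{order}")
    _phi, psi, x = wavelet.wavefun(level=10)
    return np.asarray(x), np.asarray(psi)


@lru_cache(maxsize=None)
def wavelet_kernel(order: int, scale: int) -> np.ndarray:
    """The sampled wavelet at integer ``scale``: psi(k/s)/sqrt(s) on the
    integer grid covering the scaled support."""
    x, psi = _mother_wavelet(order)
    support = x[-1] - x[0]
    n = max(int(np.floor(support * scale)) + 1, 2)
    grid = x[0] + np.arange(n) / scale
    return np.interp(grid, x, psi) / np.sqrt(scale)


def _cwt_rows(epochs: np.ndarray, order: int) -> np.ndarray:
    """CWT magnitudes for a batch of signals.  ``epochs``: (batch, 64)."""
    batch, n = epochs.shape
    max_kernel = len(wavelet_kernel(order, N_SCALES))
    pad = min(max_kernel // 2 + 1, n - 1)
    # symmetric (reflective) padding: edge effects matter at large scales
    padded = np.concatenate(
        [epochs[:, :pad][:, ::-1], epochs, epochs[:, -pad:][:, ::-1]], axis=1
    )
    out = np.empty((batch, N_SCALES, n))
    for s in range(1, N_SCALES + 1):
        kernel = wavelet_kernel(order, s)[::-1]  # correlation with psi
        conv = sps.fftconvolve(padded, kernel[None, :], mode="same", axes=1)
        out[:, s - 1, :] = np.abs(conv[:, pad:pad + n])
    return out


def cwt_scalogram(epoch_channel: np.ndarray, wavelet_order: int = 6,
                  channel: str = "", epoch_index: int = -1) -> Scalogram:
    """Scalogram of one 64-sample epoch-channel at integer scales 1..32."""
    x = np.asarray(epoch_channel, dtype=float)
    if x.shape != (EPOCH_SAMPLES,):
        raise ValueError(f"epoch must have exactly {EPOCH_SAMPLES} samples, got {x.shape}")
    values = _cwt_rows(x[None, :], wavelet_order)[0]
    return Scalogram(values=values, wavelet_order=wavelet_order,
                     channel=channel, epoch_index=epoch_index)


def cwt_scalograms(epochs: np.ndarray, wavelet_order: int = 6) -> np.ndarray:
    """Vectorised scalograms for a stack of epochs.

    ``epochs``: (m, n_channels, 64) -> (m, n_channels, 32, 64) magnitudes.
    Identical (up to FFT round-off batching) to per-epoch ``cwt_scalogram``.
    """
    epochs = np.asarray(epochs, dtype=float)
    m, n_ch, n = epochs.shape
    if n != EPOCH_SAMPLES:
        raise ValueError(f"epochs must have {EPOCH_SAMPLES} samples, got {n}")
    flat = epochs.reshape(m * n_ch, n)
    out = _cwt_rows(flat, wavelet_order)
    return out.reshape(m, n_ch, N_SCALES, n)


def scalogram_to_image(scalogram: Scalogram | np.ndarray,
                       target_size: tuple[int, int] = (N_SCALES, EPOCH_SAMPLES)) -> np.ndarray:
    """Min-max normalise a scalogram to [0, 1], bilinearly resize, and
    replicate to 3 identical channels -> (H, W, 3) float image.

    A constant scalogram (zero dynamic range) maps to the all-zero image.
    """
    values = scalogram.values if isinstance(scalogram, Scalogram) else np.asarray(scalogram, float)
    h, w = target_size
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {target_size}")
    lo, hi = values.min(), values.max()
    norm = np.zeros_like(values) if hi == lo else (values - lo) / (hi - lo)
    if norm.shape != (h, w):
        # align-corners bilinear interpolation on the source grid
        rows = np.linspace(0, norm.shape[0] - 1, h)
        cols = np.linspace(0, norm.shape[1] - 1, w)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        norm = map_coordinates(norm, [rr, cc], order=1, mode="nearest")
    return np.repeat(norm[:, :, None], 3, axis=2)


def save_scalogram_png(scalogram: Scalogram, path) -> None:
    """Render a scalogram to PNG for visual inspection (time on x, scale on y)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 2.5))
    ax.imshow(scalogram.values, aspect="auto", origin="lower",
              extent=(0, 1, 1, N_SCALES), cmap="viridis")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("CWT scale")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
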