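"""Preprocessing: FIR band-pass, average reference, decimation, epoching.

The pipeline order is fixed: band-pass filter (1-32 Hz), artifact-removal
hook, average re-reference, downsample 512 -> 64 Hz, then baseline-corrected
1-s epoch extraction.  Task epochs start at trial onsets; resting epochs tile
the 30-90 s window of the resting block, giving 60 per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .synthetic import CONDITIONS, Event, RawRecording

__all__ = [
    "EpochSet",
    "bandpass_fir",
    "design_bandpass",
    "rereference_average",
    "downsample",
    "extract_task_epochs",
    "extract_rs_epochs",
    "assemble_dataset",
    "preprocess_recording",
]

EPOCH_SAMPLES = 64      # 1 s at the 64 Hz analysis rate
ANALYSIS_RATE = 64.0


@dataclass
class EpochSet:
    """Labeled 1-s epochs: the unit of all downstream computation."""

    epochs: np.ndarray              # (m, n_channels, 64)
    labels: np.ndarray              # (m,) strings from CONDITIONS
    participant_ids: np.ndarray     # (m,) ints
    channels: tuple[str, ...]
    epoch_rate: float = ANALYSIS_RATE

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        self.participant_ids = np.asarray(self.participant_ids)
        if self.epochs.ndim != 3 or self.epochs.shape[2] != EPOCH_SAMPLES:
            raise ValueError(
                f"epochs must be (m, n_channels, {EPOCH_SAMPLES}), got {self.epochs.shape}"
            )
        if len(self.labels) != len(self.epochs) or len(self.participant_ids) != len(self.epochs):
            raise ValueError("labels/participant_ids length mismatch")
        unknown = set(np.unique(self.labels)) - set(CONDITIONS) if len(self.labels) else set()
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")

    @property
    def m(self) -> int:
        """Dataset size (number of observations)."""
        return self.epochs.shape[0]

    def label_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CONDITIONS}

    def one_hot(self) -> np.ndarray:
        """(m, 3) one-hot labels in the fixed (resting, picking, coordination) order."""
        out = np.zeros((self.m, len(CONDITIONS)))
        for j, c in enumerate(CONDITIONS):
            out[self.labels == c, j] = 1.0
        return out

    @classmethod
    def empty(cls, channels: Sequence[str]) -> "EpochSet":
        return cls(
            epochs=np.zeros((0, len(channels), EPOCH_SAMPLES)),
            labels=np.array([], dtype=object),
            participant_ids=np.array([], dtype=int),
            channels=tuple(channels),
        )


# ---------------------------------------------------------------------------
# filtering

def design_bandpass(rate: float, low: float = 1.0, high: float = 32.0) -> np.ndarray:
    """Linear-phase Hamming windowed-sinc band-pass with ~1 Hz transitions.

    Cutoffs sit half a transition width outside [low, high] so the passband
    itself stays flat; a single pass reaches the Hamming stopband (~-53 dB)
    at DC and beyond high + 1 Hz, and the forward-backward application below
    doubles that.
    """
    nyq = rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band edges ({low}, {high}) must satisfy 0 < low < high < {nyq}")
    transition = 1.0
    numtaps = int(np.ceil(3.3 * rate / transition))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    return sps.firwin(
        numtaps,
        [max(low - transition / 2.0, 1e-3), high + transition / 2.0],
        pass_zero=False,
        window="hamming",
        fs=rate,
    )


def _filtfilt_fir(h: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Zero-phase FIR filtering (forward-backward) along the last axis,
    with reflective edge padding, FFT-based for long kernels."""
    n = x.shape[-1]
    pad = min(len(h), n - 1)
    xp = np.concatenate(
        [x[..., 1:pad + 1][..., ::-1], x, x[..., -pad - 1:-1][..., ::-1]], axis=-1
    )
    shape = (1,) * (x.ndim - 1) + (len(h),)
    y = sps.fftconvolve(xp, h.reshape(shape), mode="same", axes=-1)
    y = sps.fftconvolve(y[..., ::-1], h.reshape(shape), mode="same", axes=-1)[..., ::-1]
    return y[..., pad:pad + n]


def bandpass_fir(recording: RawRecording, low: float = 1.0, high: float = 32.0) -> RawRecording:
    """Apply the 1-32 Hz zero-phase FIR band-pass to every channel."""
    h = design_bandpass(recording.sampling_rate, low, high)
    return RawRecording(
        participant_id=recording.participant_id,
        signal=_filtfilt_fir(h, recording.signal),
        sampling_rate=recording.sampling_rate,
        channels=recording.channels,
        events=list(recording.events),
    )


def remove_artifacts(recording: RawRecording,
                     method: Callable[[np.ndarray], np.ndarray] | None = None) -> RawRecording:
    """Artifact-removal hook.

    Synthetic recordings are artifact-free, so the default is a pass-through;
    ``method`` may supply a shape-preserving cleaner (e.g. an ICA-based one)
    for real data.
    """
    cleaned = recording.signal if method is None else method(recording.signal)
    if cleaned.shape != recording.signal.shape:
        raise ValueError("artifact removal must preserve the signal shape")
    return RawRecording(
        participant_id=recording.participant_id,
        signal=np.asarray(cleaned, dtype=float),
        sampling_rate=recording.sampling_rate,
        channels=recording.channels,
        events=list(recording.events),
    )


def rereference_average(recording: RawRecording) -> RawRecording:
    """Subtract the instantaneous mean across channels (average reference)."""
    if recording.signal.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    sig = recording.signal - recording.signal.mean(axis=0, keepdims=True)
    return RawRecording(
        participant_id=recording.participant_id,
        signal=sig,
        sampling_rate=recording.sampling_rate,
        channels=recording.channels,
        events=list(recording.events),
    )


def downsample(recording: RawRecording, target_rate: float = ANALYSIS_RATE) -> RawRecording:
    """Integer decimation; assumes the signal is already band-limited below
    the new Nyquist (the 32 Hz band-pass serves as the anti-alias filter)."""
    factor = recording.sampling_rate / target_rate
    if factor != int(factor):
        raise ValueError(
            f"sampling rate {recording.sampling_rate} not an integer multiple "
            f"of target {target_rate}"
        )
    factor = int(factor)
    events = [
        Event(int(round(e.onset / factor)), e.condition, e.trial)
        for e in recording.events
    ]
    return RawRecording(
        participant_id=recording.participant_id,
        signal=recording.signal[:, ::factor].copy(),
        sampling_rate=target_rate,
        channels=recording.channels,
        events=events,
    )


# ---------------------------------------------------------------------------
# epoching

def _baseline_correct(epoch: np.ndarray) -> np.ndarray:
    # Per-epoch, per-channel mean subtraction: the only baseline uniformly
    # applicable to both task and resting epochs (no pre-stimulus interval).
    return epoch - epoch.mean(axis=-1, keepdims=True)


def extract_task_epochs(recording: RawRecording) -> EpochSet:
    """One baseline-corrected 1-s epoch per picking/coordination trial onset.

    Epochs are half-open [onset, onset + 1 s): samples onset .. onset+63.
    """
    n = int(round(recording.sampling_rate))
    if n != EPOCH_SAMPLES:
        raise ValueError("extract_task_epochs expects a recording at 64 Hz")
    epochs, labels = [], []
    for e in recording.events:
        if e.condition == "resting":
            continue
        if e.onset + EPOCH_SAMPLES > recording.n_samples:
            raise ValueError(
                f"trial {e.trial} ({e.condition}) at sample {e.onset} extends "
                "past the end of the recording"
            )
        epochs.append(_baseline_correct(recording.signal[:, e.onset:e.onset + EPOCH_SAMPLES]))
        labels.append(e.condition)
    if not epochs:
        return EpochSet.empty(recording.channels)
    return EpochSet(
        epochs=np.stack(epochs),
        labels=np.array(labels, dtype=object),
        participant_ids=np.full(len(epochs), recording.participant_id),
        channels=recording.channels,
    )


def extract_rs_epochs(
    recording: RawRecording,
    window: tuple[float, float] = (30.0, 90.0),
) -> EpochSet:
    """Contiguous, non-overlapping 1-s resting epochs tiling ``window``
    (seconds relative to the resting-block onset); the default 30-90 s window
    yields 60 epochs."""
    if int(round(recording.sampling_rate)) != EPOCH_SAMPLES:
        raise ValueError("extract_rs_epochs expects a recording at 64 Hz")
    rest_events = recording.events_of("resting")
    if len(rest_events) != 1:
        raise ValueError(f"expected exactly 1 resting block, found {len(rest_events)}")
    start_s, stop_s = window
    if stop_s <= start_s:
        raise ValueError("window stop must exceed start")
    base = rest_events[0].onset
    start = base + int(round(start_s * EPOCH_SAMPLES))
    stop = base + int(round(stop_s * EPOCH_SAMPLES))
    if stop > recording.n_samples:
        raise ValueError(
            f"resting block too short: window needs samples up to {stop}, "
            f"recording has {recording.n_samples}"
        )
    starts = range(start, stop, EPOCH_SAMPLES)
    epochs = np.stack([
        _baseline_correct(recording.signal[:, s:s + EPOCH_SAMPLES]) for s in starts
    ])
    return EpochSet(
        epochs=epochs,
        labels=np.array(["resting"] * len(epochs), dtype=object),
        participant_ids=np.full(len(epochs), recording.participant_id),
        channels=recording.channels,
    )


def assemble_dataset(epoch_sets: Sequence[EpochSet]) -> EpochSet:
    """Concatenate per-participant epoch sets, preserving epoch order."""
    epoch_sets = [es for es in epoch_sets]
    if not epoch_sets:
        raise ValueError("cannot assemble an empty list of epoch sets")
    channels = epoch_sets[0].channels
    for es in epoch_sets:
        if es.channels != channels:
            raise ValueError(
                f"inconsistent channel sets: {es.channels} vs {channels}"
            )
    return EpochSet(
        epochs=np.concatenate([es.epochs for es in epoch_sets]),
        labels=np.concatenate([es.labels for es in epoch_sets]),
        participant_ids=np.concatenate([es.participant_ids for es in epoch_sets]),
        channels=channels,
    )


def preprocess_recording(
    recording: RawRecording,
    low: float = 1.0,
    high: float = 32.0,
    target_rate: float = ANALYSIS_RATE,
    rs_window: tuple[float, float] = (30.0, 90.0),
    artifact_method: Callable[[np.ndarray], np.ndarray] | None = None,
) -> EpochSet:
    """Full per-recording pipeline: filter -> artifact hook -> re-reference ->
    downsample -> baseline-corrected epoching (task + resting)."""
    rec = bandpass_fir(recording, low, high)
    rec = remove_artifacts(rec, artifact_method)
    rec = rereference_average(rec)
    rec = downsample(rec, target_rate)
    return assemble_dataset([extract_rs_epochs(rec, rs_window), extract_task_epochs(rec)])
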