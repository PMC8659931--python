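"""Synthetic multi-channel EEG with a tacit-coordination task structure.

Generates artifact-free recordings that follow the experimental design the
decoding pipeline assumes: a 120 s eyes-open resting block, then twelve
"picking" trials (free choice, shallow reasoning) and twelve "coordination"
trials (strategic choice, deeper reasoning), each preceded by a short standby
interval.  The three conditions differ in their time-frequency signature:

* resting     -- 1/f background with an alpha (8-12 Hz) bump, nothing else;
* picking     -- a single Gabor transient ~330 ms after trial onset;
* coordination-- several Gabor transients spread over the first second plus
                 elevated beta-band (13-30 Hz) power.

Channels carry the task signal at different signal-to-noise ratios, symmetric
across homologous left/right pairs, with F3/F4 strongest and F7/F8 weakest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "DEFAULT_CHANNELS",
    "HOMOLOGOUS_PAIRS",
    "ExperimentDesign",
    "ConditionSignature",
    "Event",
    "RawRecording",
    "default_signatures",
    "simulate_recording",
    "generate_dataset",
]

CONDITIONS = ("resting", "picking", "coordination")
DEFAULT_CHANNELS = ("Fp1", "F7", "Fp2", "F8", "F3", "F4")
HOMOLOGOUS_PAIRS = (("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"))

#: Relative task-signal gain per electrode.  Homologous pairs are equal;
#: mid-frontal F3/F4 carry the strongest signal and lateral F7/F8 the weakest.
DEFAULT_SNR_PROFILE: Mapping[str, float] = {
    "Fp1": 0.75, "Fp2": 0.75,
    "F7": 0.5, "F8": 0.5,
    "F3": 1.0, "F4": 1.0,
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial counts, timing and montage of one recording session."""

    n_participants: int = 10
    n_trials_per_condition: int = 12
    rs_duration: float = 120.0          # seconds of resting-state recording
    rs_epoch_window: tuple[float, float] = (30.0, 90.0)  # [start, stop) in s
    standby_interval: tuple[float, float] = (2.0, 2.5)   # U(a, b) seconds
    trial_max_duration: float = 8.0     # seconds; trials end on button press
    sampling_rate: int = 512            # Hz
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rs_epoch_window
        if not (0.0 <= lo < hi <= self.rs_duration):
            raise ValueError(
                f"rs_epoch_window {self.rs_epoch_window} must lie inside "
                f"[0, {self.rs_duration}] with start < stop"
            )
        if not self.channels:
            raise ValueError("channel list must be non-empty")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        a, b = self.standby_interval
        if a > b:
            raise ValueError("standby_interval lower bound exceeds upper bound")
        if self.n_participants < 1 or self.n_trials_per_condition < 0:
            raise ValueError("participant/trial counts must be positive")
        if self.trial_max_duration < 1.0:
            raise ValueError("trials must allow at least the 1 s analysis epoch")


@dataclass(frozen=True)
class ConditionSignature:
    """Time-frequency fingerprint of one experimental condition.

    ``transient_times`` are epoch-relative (seconds after trial onset); for
    conditions with ``n_random_transients > 0`` that many additional transient
    times are drawn uniformly over [0, 1) s independently per trial.
    """

    one_over_f_exponent: float = 1.0
    alpha_bump_amplitude: float = 1.0   # relative bump height at ~10 Hz
    background_rms: float = 10.0        # microvolt RMS of the background
    transient_times: tuple[float, ...] = ()
    n_random_transients: int = 0
    transient_width: float = 0.12       # seconds (Gaussian ~4 sigma width)
    transient_freq: float = 10.0        # Gabor carrier frequency, Hz
    transient_amplitude: float = 0.0    # microvolt peak, before channel gain
    beta_gain: float = 1.0              # multiplicative 13-30 Hz power gain
    channel_snr_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SNR_PROFILE)
    )

    @property
    def n_transients(self) -> int:
        return len(self.transient_times) + self.n_random_transients


def default_signatures() -> dict[str, ConditionSignature]:
    """Per-condition signatures used throughout tests and examples."""
    base = ConditionSignature()
    return {
        "resting": base,
        "picking": replace(
            base,
            transient_times=(0.33,),
            transient_amplitude=30.0,
        ),
        "coordination": replace(
            base,
            n_random_transients=3,
            transient_amplitude=30.0,
            beta_gain=2.5,
        ),
    }


def validate_signatures(signatures: Mapping[str, ConditionSignature]) -> None:
    missing = set(CONDITIONS) - set(signatures)
    if missing:
        raise ValueError(f"signatures missing for conditions: {sorted(missing)}")
    rest = signatures["resting"]
    if rest.n_transients != 0 or rest.beta_gain != 1.0:
        raise ValueError("resting signature must have no transients and beta_gain 1")
    pick = signatures["picking"]
    if pick.n_transients != 1 or tuple(pick.transient_times) != (0.33,):
        raise ValueError("picking signature must have exactly one transient at 0.33 s")
    coord = signatures["coordination"]
    if coord.n_transients < 2 or coord.beta_gain <= 1.0:
        raise ValueError("coordination signature needs >= 2 transients and beta_gain > 1")
    for sig in signatures.values():
        for a, b in HOMOLOGOUS_PAIRS:
            ga, gb = sig.channel_snr_profile.get(a), sig.channel_snr_profile.get(b)
            if ga is not None and gb is not None and ga != gb:
                raise ValueError(f"homologous pair ({a}, {b}) must have equal gains")


@dataclass(frozen=True)
class Event:
    onset: int          # sample index into the recording
    condition: str      # one of CONDITIONS
    trial: int          # 0-based trial index; -1 for the resting block


@dataclass
class RawRecording:
    """Continuous multi-channel signal plus its event table."""

    participant_id: int
    signal: np.ndarray          # (n_channels, n_samples), microvolts
    sampling_rate: float
    channels: tuple[str, ...]
    events: list[Event]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def events_of(self, condition: str) -> list[Event]:
        return [e for e in self.events if e.condition == condition]

    def validate(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError("signal must be (n_channels, n_samples)")
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        horizon = self.n_samples - int(round(self.sampling_rate))
        for e in self.events:
            if e.condition != "resting" and e.onset > horizon:
                raise ValueError(
                    f"trial {e.trial} ({e.condition}) onset {e.onset} leaves "
                    "less than 1 s of signal"
                )


# ---------------------------------------------------------------------------
# signal-building blocks

def _background_amplitude(freqs: np.ndarray, sig: ConditionSignature) -> np.ndarray:
    """Target amplitude spectrum: 1/f^(e/2) plus a Gaussian alpha bump."""
    f = np.maximum(freqs, 0.5)  # flatten below 0.5 Hz to avoid a DC blow-up
    amp = f ** (-sig.one_over_f_exponent / 2.0)
    amp = amp + sig.alpha_bump_amplitude * np.exp(-((freqs - 10.0) ** 2) / (2 * 2.0**2))
    amp[freqs == 0.0] = 0.0
    return amp


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  sig: ConditionSignature) -> np.ndarray:
    """Gaussian noise spectrally shaped to the background spectrum, unit-free
    until scaled to ``background_rms``."""
    if sig.background_rms == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaped = np.fft.irfft(spec * _background_amplitude(freqs, sig), n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped * (sig.background_rms / rms)


def _beta_band_rms_fraction(fs: float, sig: ConditionSignature) -> float:
    """Fraction of background RMS residing in the 13-30 Hz band (analytic,
    from the imposed amplitude spectrum)."""
    freqs = np.linspace(0.0, fs / 2.0, 4096)
    amp2 = _background_amplitude(freqs, sig) ** 2
    band = (freqs >= 13.0) & (freqs <= 30.0)
    total = np.trapezoid(amp2, freqs)
    if total == 0.0:
        return 0.0
    return float(np.sqrt(np.trapezoid(amp2[band], freqs[band]) / total))


def _beta_noise(rng: np.random.Generator, n: int, fs: float, target_rms: float) -> np.ndarray:
    """Band-limited (13-30 Hz) Gaussian noise with the requested RMS."""
    if target_rms <= 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < 13.0) | (freqs > 30.0)] = 0.0
    band = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(band**2))
    if rms == 0.0:
        return np.zeros(n)
    return band * (target_rms / rms)


def _gabor(t: np.ndarray, center: float, sig: ConditionSignature,
           phase: float = 0.0) -> np.ndarray:
    sigma = sig.transient_width / 4.0
    env = np.exp(-((t - center) ** 2) / (2 * sigma**2))
    carrier = np.cos(2 * np.pi * sig.transient_freq * (t - center) + phase)
    return sig.transient_amplitude * env * carrier


# ---------------------------------------------------------------------------
# public generators

def _participant_rng(seed: int, participant_id: int) -> np.random.Generator:
    # Counter-based substream: stream i depends only on (seed, i), so adding
    # participants never perturbs existing recordings.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(participant_id,)))


def simulate_recording(
    design: ExperimentDesign,
    signatures: Mapping[str, ConditionSignature] | None = None,
    participant_id: int = 0,
) -> RawRecording:
    """Simulate one participant's full session (resting, picking, coordination).

    Deterministic given ``(design.seed, participant_id)``.
    """
    signatures = dict(signatures) if signatures is not None else default_signatures()
    validate_signatures(signatures)
    fs = float(design.sampling_rate)
    rng = _participant_rng(design.seed, participant_id)
    n_ch = len(design.channels)

    # --- lay out the session timeline -------------------------------------
    events: list[Event] = [Event(0, "resting", -1)]
    cursor = int(round(design.rs_duration * fs))
    segments: list[tuple[int, str, int, float]] = []  # (onset, cond, trial, dur_s)
    for condition in ("picking", "coordination"):
        for trial in range(design.n_trials_per_condition):
            standby = rng.uniform(*design.standby_interval)
            cursor += int(round(standby * fs))
            duration = rng.uniform(1.5, design.trial_max_duration)
            segments.append((cursor, condition, trial, duration))
            events.append(Event(cursor, condition, trial))
            cursor += int(round(duration * fs))
    n_samples = cursor + int(round(fs))  # 1 s tail so the last epoch fits

    # --- background noise, independent per channel ------------------------
    rest_sig = signatures["resting"]
    signal = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        signal[c] = _shaped_noise(rng, n_samples, fs, rest_sig)

    beta_base_rms = rest_sig.background_rms * _beta_band_rms_fraction(fs, rest_sig)

    # --- per-trial task signal --------------------------------------------
    for onset, condition, _trial, duration in segments:
        sig = signatures[condition]
        gains = np.array([
            sig.channel_snr_profile.get(name, 1.0) for name in design.channels
        ])
        times = list(sig.transient_times)
        times += list(rng.uniform(0.0, 1.0, size=sig.n_random_transients))
        n_trial = int(round(duration * fs))
        t = np.arange(n_trial) / fs
        # Transient envelopes and timing are shared across the montage (one
        # underlying evoked response); the carrier phase varies per channel,
        # as electrodes see the source through different projections.  This
        # keeps the signal from being annihilated by average re-referencing.
        task = np.zeros((n_ch, n_trial))
        for center in times:
            phases = rng.uniform(0.0, 2 * np.pi, size=n_ch)
            for c in range(n_ch):
                task[c] += _gabor(t, center, sig, phase=phases[c])
        if sig.beta_gain > 1.0:
            extra = beta_base_rms * np.sqrt(sig.beta_gain - 1.0)
            for c in range(n_ch):
                task[c] += _beta_noise(rng, n_trial, fs, extra)
        signal[:, onset:onset + n_trial] += gains[:, None] * task

    rec = RawRecording(
        participant_id=participant_id,
        signal=signal,
        sampling_rate=fs,
        channels=tuple(design.channels),
        events=events,
    )
    rec.validate()
    return rec


def generate_dataset(
    design: ExperimentDesign,
    signatures: Mapping[str, ConditionSignature] | None = None,
) -> list[RawRecording]:
    """One recording per participant, each from its own random substream."""
    return [
        simulate_recording(design, signatures, participant_id=pid)
        for pid in range(design.n_participants)
    ]
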