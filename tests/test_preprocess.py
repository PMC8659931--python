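"""Filtering, referencing, decimation and epoching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from levelk_eeg.preprocess import (EpochSet, assemble_dataset, bandpass_fir,
                                   design_bandpass, downsample,
                                   extract_rs_epochs, extract_task_epochs,
                                   preprocess_recording, rereference_average)
from levelk_eeg.synthetic import (Event, ExperimentDesign, RawRecording,
                                  simulate_recording)

FS = 512.0


def _recording(signal: np.ndarray, rate: float = FS, events=None) -> RawRecording:
    channels = tuple(f"ch{i}" for i in range(signal.shape[0]))
    return RawRecording(participant_id=0, signal=signal, sampling_rate=rate,
                       channels=channels, events=events or [])


def _sine(freq: float, duration: float = 10.0, rate: float = FS) -> np.ndarray:
    t = np.arange(int(duration * rate)) / rate
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_designed_frequency_response_meets_band_spec(self):
        h = design_bandpass(FS)
        freqs, resp = sps.freqz(h, worN=16384, fs=FS)
        mag = np.abs(resp) ** 2          # forward-backward => squared response
        passband = (freqs >= 1.0) & (freqs <= 32.0)
        ripple_db = -20 * np.log10(np.clip(mag[passband].min(), 1e-30, None))
        assert ripple_db < 1.0
        assert 20 * np.log10(mag[0] + 1e-30) < -20.0            # DC
        stop = freqs >= 48.0
        assert 20 * np.log10(mag[stop].max() + 1e-30) < -20.0   # high stopband

    def test_passband_sinusoid_amplitude_preserved(self):
        rec = _recording(np.vstack([_sine(10.0), _sine(10.0)]))
        out = bandpass_fir(rec)
        mid = out.signal[0, 1000:-1000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_stopband_sinusoid_attenuated(self):
        x = _sine(60.0)
        rec = _recording(np.vstack([x, x]))
        out = bandpass_fir(rec)
        rms_ratio = np.std(out.signal[0]) / np.std(x)
        assert rms_ratio < 0.1

    def test_dc_offset_rejected(self):
        rec = _recording(np.full((2, 5120), 7.5))
        out = bandpass_fir(rec)
        assert np.max(np.abs(out.signal)) < 0.1

    def test_band_edges_outside_nyquist_rejected(self):
        rec = _recording(np.zeros((2, 1024)))
        with pytest.raises(ValueError, match="band edges"):
            bandpass_fir(rec, low=1.0, high=300.0)


class TestRereference:
    def test_mean_across_channels_is_zero(self):
        rng = np.random.default_rng(0)
        rec = _recording(rng.normal(size=(6, 2048)))
        out = rereference_average(rec)
        assert np.max(np.abs(out.signal.mean(axis=0))) < 1e-10

    def test_identical_channels_become_zero(self):
        x = _sine(5.0, duration=1.0)
        out = rereference_average(_recording(np.vstack([x, x, x])))
        assert np.max(np.abs(out.signal)) < 1e-12

    def test_antisymmetric_pair_unchanged(self):
        x = _sine(5.0, duration=1.0)
        out = rereference_average(_recording(np.vstack([x, -x])))
        assert np.allclose(out.signal, np.vstack([x, -x]))

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            rereference_average(_recording(np.zeros((1, 100))))


class TestDownsample:
    def test_512_to_64_sample_count_and_event_rescaling(self):
        rec = _recording(np.zeros((2, 512)), events=[Event(256, "picking", 0)])
        out = downsample(rec, 64.0)
        assert out.signal.shape[1] == 64
        assert out.sampling_rate == 64.0
        assert out.events[0].onset == 32

    def test_band_limited_sinusoid_preserved(self):
        rec = _recording(np.vstack([_sine(8.0)] * 2))
        out = downsample(rec, 64.0)
        t = np.arange(out.signal.shape[1]) / 64.0
        oracle = np.sin(2 * np.pi * 8.0 * t)   # same sinusoid sampled at 64 Hz
        assert np.max(np.abs(out.signal[0] - oracle)) < 0.05

    def test_identity_when_target_equals_source(self):
        rec = _recording(np.random.default_rng(1).normal(size=(2, 512)))
        out = downsample(rec, FS)
        assert np.array_equal(out.signal, rec.signal)

    def test_non_integer_factor_rejected(self):
        rec = _recording(np.zeros((2, 512)))
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(rec, 60.0)


def _recording_64(n_seconds: int = 200, seed: int = 0, events=None) -> RawRecording:
    rng = np.random.default_rng(seed)
    sig = rng.normal(size=(6, n_seconds * 64))
    rec = _recording(sig, rate=64.0, events=events)
    return rec


class TestEpoching:
    def test_task_epoch_counts_and_labels(self):
        events = [Event(0, "resting", -1)]
        events += [Event(7000 + 100 * i, "picking", i) for i in range(12)]
        events += [Event(9000 + 100 * i, "coordination", i) for i in range(12)]
        es = extract_task_epochs(_recording_64(events=events))
        assert es.m == 24
        assert es.label_counts() == {"resting": 0, "picking": 12, "coordination": 12}
        assert es.epochs.shape == (24, 6, 64)

    def test_no_events_gives_empty_epochset(self):
        es = extract_task_epochs(_recording_64(events=[]))
        assert es.m == 0

    def test_constant_signal_epochs_are_zero_after_baseline(self):
        rec = _recording(np.full((6, 64 * 100), 3.3), rate=64.0,
                         events=[Event(640, "picking", 0)])
        es = extract_task_epochs(rec)
        assert np.max(np.abs(es.epochs)) < 1e-12

    def test_onset_too_close_to_end_names_the_trial(self):
        rec = _recording_64(n_seconds=10, events=[Event(620, "picking", 7)])
        with pytest.raises(ValueError, match="trial 7"):
            extract_task_epochs(rec)

    def test_resting_window_yields_60_tiling_epochs(self):
        rec = _recording_64(events=[Event(0, "resting", -1)])
        es = extract_rs_epochs(rec)
        assert es.m == 60
        assert set(es.labels) == {"resting"}
        # epochs tile [30, 90) s: start samples 30*64, 31*64, ...
        for k in range(60):
            expected = rec.signal[:, (30 + k) * 64:(31 + k) * 64]
            expected = expected - expected.mean(axis=1, keepdims=True)
            assert np.allclose(es.epochs[k], expected)

    def test_one_second_window_yields_single_epoch(self):
        rec = _recording_64(events=[Event(0, "resting", -1)])
        es = extract_rs_epochs(rec, window=(30.0, 31.0))
        assert es.m == 1

    def test_short_resting_block_rejected(self):
        rec = _recording_64(n_seconds=50, events=[Event(0, "resting", -1)])
        with pytest.raises(ValueError, match="too short"):
            extract_rs_epochs(rec)


class TestAssemble:
    def test_single_participant_default_design_gives_84_epochs(self):
        rec = simulate_recording(ExperimentDesign(n_participants=1, seed=21))
        es = preprocess_recording(rec)
        assert es.m == 84
        assert es.label_counts() == {"resting": 60, "picking": 12, "coordination": 12}

    def test_inconsistent_channel_sets_rejected(self):
        a = EpochSet.empty(("F3", "F4"))
        b = EpochSet.empty(("F3", "Cz"))
        with pytest.raises(ValueError, match="channel"):
            assemble_dataset([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_dataset([])


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    n_trials=st.integers(min_value=1, max_value=6),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_epoch_extraction_is_count_exact_and_baseline_corrected(n_trials, seed):
    """For any valid design, epoching preserves labels and counts, and every
    epoch-channel is mean-subtracted."""
    design = ExperimentDesign(
        n_participants=1, n_trials_per_condition=n_trials, rs_duration=95.0,
        seed=seed,
    )
    es = preprocess_recording(simulate_recording(design))
    assert es.label_counts() == {
        "resting": 60, "picking": n_trials, "coordination": n_trials
    }
    assert np.max(np.abs(es.epochs.mean(axis=2))) < 1e-9
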