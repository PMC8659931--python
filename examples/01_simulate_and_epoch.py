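"""Simulate one participant's session and cut it into labeled 1-s epochs.

The recording holds a 120 s resting block, then 12 picking and 12
coordination trials at 512 Hz on six frontal/prefrontal electrodes.
Preprocessing (1-32 Hz FIR band-pass, average reference, downsampling to
64 Hz, per-epoch baseline correction) turns it into 84 labeled epochs:
60 resting (tiling the 30-90 s window), 12 picking, 12 coordination.
"""

from levelk_eeg import ExperimentDesign, preprocess_recording, simulate_recording

design = ExperimentDesign(n_participants=1, seed=1)
recording = simulate_recording(design, participant_id=0)
print(f"recording: {recording.signal.shape[0]} channels x "
      f"{recording.signal.shape[1]} samples ({recording.duration:.1f} s at "
      f"{recording.sampling_rate:.0f} Hz), {len(recording.events)} events")

epochs = preprocess_recording(recording)
print(f"epochs: {epochs.m} x {epochs.epochs.shape[1]} channels x "
      f"{epochs.epochs.shape[2]} samples at {epochs.epoch_rate:.0f} Hz")
print(f"label counts: {epochs.label_counts()}")
# Each epoch is one classification example; the 60/12/12 split is the
# 5:1 resting-to-task imbalance the class-balanced training corrects for.
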