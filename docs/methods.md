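# Methods

This note records the models, defaults and numerical choices behind
`levelk-eeg`, and what the synthetic benchmark does and does not establish.

## Synthetic EEG model

The generator emulates a three-condition tacit-coordination session per
participant: a 120 s eyes-open resting block, then 12 picking and 12
coordination trials, each preceded by a standby interval drawn from
U(2, 2.5) s, with trial durations drawn from U(1.5, 8) s (participants end a
trial with a button press; only the first second after onset is analysed).
Sampling rate 512 Hz; montage Fp1, F7, Fp2, F8, F3, F4.

**Background.** Each channel carries independent Gaussian noise spectrally
shaped to 1/f (exponent 1.0) with a Gaussian alpha bump at 10 Hz (σ = 2 Hz,
relative height 1.0), scaled to 10 µV RMS — the standard stand-in for
task-free EEG. The spectrum is flattened below 0.5 Hz to avoid a DC
singularity.

**Condition signatures.**

* *Resting*: background only.
* *Picking*: one Gabor atom (Gaussian-windowed 10 Hz cosine, width 0.12 s
  ≈ 4σ, 30 µV peak) centred 330 ms after trial onset.
* *Coordination*: three Gabor atoms at per-trial uniform times in [0, 1) s,
  plus band-limited 13–30 Hz noise raising beta power by a factor of 2.5.

Transient *envelopes and timings* are shared across channels (one
underlying evoked response) but the carrier phase is drawn per channel:
electrodes see a cortical source through different projections, and a
perfectly phase-coherent signal would be almost entirely removed by average
re-referencing. The per-channel beta noise is likewise independent.

**Channel SNR profile.** Task components are scaled per electrode:
F3/F4 × 1.0, Fp1/Fp2 × 0.75, F7/F8 × 0.5, equal within each homologous
left/right pair. Together with the amplitudes above, this puts every
channel's single-channel decodability well above chance with a clear
F3/F4 > Fp1/Fp2 > F7/F8 ordering — the qualitative regime the pipeline is
designed for. The absolute accuracy level is a property of the surrogate
embedding and these SNRs, not a physiological claim.

**Seeding.** A master seed fans out to one substream per participant via
`SeedSequence(seed, spawn_key=(participant,))`, so adding participants
never changes existing recordings, and identical (design, signatures, seed)
give bit-identical output.

What the generator deliberately omits: ocular/muscle artifacts (the
artifact-removal stage is a pass-through hook), electrode drift and
impedance changes, inter-participant variability beyond independent noise
draws, volume-conduction correlations between channels, and any behavioural
model of which word is chosen. Passing tests on this benchmark therefore
demonstrate the correctness and sensitivity of the *pipeline*, not
real-data performance.

## Preprocessing

Order: FIR band-pass → artifact hook → average reference → decimation →
baseline correction → epoching.

* **Band-pass 1–32 Hz**: Hamming windowed-sinc, ~1 Hz transition width
  (3381 taps at 512 Hz), cutoffs placed half a transition outside the band
  so the passband stays flat (< 1 dB ripple); applied forward-backward via
  FFT convolution for exactly zero phase, so the 330 ms transient is not
  shifted. DC and ≥ 48 Hz are attenuated by > 20 dB (in practice ≫ 40 dB).
* **Downsampling** is integer decimation 512 → 64 Hz; the 32 Hz band edge
  equals the new Nyquist frequency, so the band-pass doubles as the
  anti-alias filter. Event onsets are rescaled by the same factor
  (rounded; worst-case jitter ~8 ms at 64 Hz).
* **Baseline correction** is per-epoch, per-channel mean subtraction.
  Resting epochs have no pre-stimulus interval, so a whole-epoch mean is
  the only uniformly applicable baseline; every emitted epoch-channel has
  |mean| < 1e−9.
* **Epochs** are half-open [onset, onset + 1 s), i.e. samples
  onset…onset+63. Resting epochs tile [30, 90) s of the resting block.

## CWT scalograms

Symlets are compactly supported orthogonal wavelets without a closed-form
continuous transform, so the CWT is computed directly: the mother wavelet
is sampled densely from `pywt`'s `wavefun`, rescaled to each integer scale
s = 1…32 as ψ(k/s)/√s, and correlated with the symmetrically padded
64-sample epoch (FFT-based). Row s of the image stores coefficient
magnitudes — sign is discarded, matching how scalograms are rendered and
consumed as images. Symmetric padding matters because at scale 32 the
kernel (~352 samples) is far longer than the epoch; edge rows are dominated
by boundary handling and are treated as features like any other. Images
are min-max normalised *per image* (a constant image maps to zero),
bilinearly resized if requested (align-corners grid), and replicated to
three identical colour channels.

## Embedding backends

The classifier consumes fixed-length vectors from a frozen extractor
behind a small contract (`embed: image → vector`, fingerprinted weights).
The default **surrogate** uses 32 random 3×3×3 filters (uniform [−1, 1],
seeded), ReLU, and average pooling over an 8 × 4 grid of image regions →
1024 features. Regional rather than global pooling is deliberate: the
class signal lives in *where* scalogram energy concentrates along the
scale and time axes, and a global average erases exactly that (empirically
dropping the weakest channels to chance). Bounded weights make each output
coordinate Lipschitz in the input with constant ≤ max-filter L1 norm,
which the tests verify. A pretrained-CNN backend (last pooling layer of an
ImageNet network) satisfies the same contract but requires a deep-learning
runtime and downloaded weights; constructing it without them raises an
error that points at the surrogate.

## Classification

Per channel, three one-vs-all heads (one affine unit + sigmoid each) are
trained on standardised features (per-fold mean/variance, variance floored
at 1e−12) by deterministic full-batch gradient descent on class-weighted
binary cross-entropy. Class weights are inverse class frequencies
normalised to mean 1 (a 5:1 imbalance gives 1:5 weights). The step size
starts at 1.0 and halves whenever a step would increase the loss, making
the loss sequence provably non-increasing; iteration stops at 500 steps or
a loss change < 1e−8. Initialisation is a seeded N(0, 1e−3) draw, so
training is bit-reproducible. The channel label is the argmax of the three
raw sigmoid outputs, ties broken by the fixed class order (resting <
picking < coordination). Cross-validation is stratified 4-fold, seeded;
every epoch is predicted exactly once by a model never trained on it
(840 epochs → 210-epoch test folds).

## Fusion and the genetic algorithm

For fusion the three sigmoid outputs are renormalised to sum to one
(all-zero triples map to uniform), since the weighted ensemble and its
cross-entropy cost operate on probability vectors. The fused prediction is
the weight-normalised average of channel triples — invariant to scaling all
weights — and the cost is J(a), the mean of −log p(true class) with a
1e−12 probability floor. The printed form of the cost lacks a minus sign
in some treatments; the implemented sign makes minimisation well-posed.

GA configuration: population 50,000 (15,000 kept by elitist selection,
20,000 arithmetic-blend crossovers of rank-selected parents, 15,000
mutants that multiply one uniformly chosen weight by 1 ± U(0.10, 0.50)).
Initial weights are i.i.d. uniform [0, 1]; stopping is 50 generations or
10 without > 1e−6 improvement. Elitism makes the best-cost trace
non-increasing. The default *test scale* shrinks the population 250× at
the same 50:15:20:15 ratio, which suffices for the ≤ 6-dimensional,
scale-invariant landscapes here (verified against simplex grid searches at
0.01–0.05 resolution). The GA optimises on out-of-fold predictions — the
only prediction set covering all m epochs without leakage. Note that J and
0/1 accuracy are different objectives: the optimiser is guaranteed not to
exceed the equal-weights baseline's *cost* (the baseline is in its search
space), but its accuracy can occasionally sit slightly below the
baseline's; reports show both.

## Metrics

Per class, PPV = diag/column, TPR = diag/row, FNR = 1 − TPR,
FDR = 1 − PPV; accuracy = trace/total. A class never predicted has
undefined (null) PPV/FDR, never zero. Percentages are formatted at two
decimals with round-half-even by default and truncation as an option —
published tables mix both conventions (89/120 appears as 74.16 only under
truncation). A report flag records whether errors occur only between
adjacent reasoning depths (resting never confused with coordination).

## Problem sizes used in tests

The full-design checks (840 epochs, 10 participants) run once as a shared
fixture. Stochastic ordering properties (F3/F4 vs F7/F8; GA weight
concentration when only F3/F4 carry signal) use 2-participant datasets
across 3–5 seeds, sized so the whole suite runs comfortably on one CPU.
The wavelet-order grid and CLI tests use 1 participant and reduced trial
counts.

## Known limitations

* The surrogate embedding is far weaker than a deep pretrained CNN;
  absolute accuracies on synthetic data (≈ 50–70% per channel) are
  benchmarks of pipeline sensitivity, not of the method's ceiling.
* ICA-based artifact removal is a hook, not an implementation.
* The generator's amplitudes and SNRs are choices, not fitted quantities;
  no claim of spectral realism beyond the 1/f + alpha + beta structure.
* EDF export is not provided; recordings are stored as `.npz` + TSV.
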