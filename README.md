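# levelk-eeg

Decoding the **depth of strategic reasoning** from frontal EEG. In tacit
coordination experiments a player either rests (no task), *picks* a word
freely (level-k = 0 reasoning), or tries to *coordinate* the choice with an
unseen partner (level-k > 0). `levelk-eeg` implements a complete, tested
pipeline that classifies 1-second EEG epochs into these three conditions,
together with a synthetic-data generator that reproduces the experimental
design, so every stage runs and is testable without any recorded human data.

## Method

Six frontal/prefrontal channels (Fp1, F7, Fp2, F8, F3, F4) sampled at
512 Hz are band-pass filtered to 1–32 Hz (zero-phase FIR), re-referenced to
the common average, downsampled to 64 Hz, and cut into baseline-corrected
1-s epochs: 60 resting epochs per participant from the 30–90 s window of a
120 s resting block, plus one epoch per task trial (12 picking + 12
coordination). With the default ten participants that is 840 epochs per
channel (600/120/120).

Each epoch-channel is transformed into a **CWT scalogram** — a 32-scale ×
64-sample magnitude image under a Symlet wavelet (orders 2–10, default 6) —
then min-max normalised and embedded by a **frozen feature extractor**
(pluggable backend; the default is a seeded random-convolution surrogate,
and the contract admits an ImageNet-pretrained CNN's last pooling layer).
Per channel *i*, three **one-vs-all sigmoid heads** trained with
class-balanced binary cross-entropy under stratified 4-fold
cross-validation give a probability triple `M_i(x_i)`; the channel's label
is its argmax.

Channels are fused as a weighted average

    M_a(x) = Σ_i a_i · M_i(x_i) / Σ_i a_i ,   a_i ≥ 0,

scored by the mean cross-entropy between fused prediction and one-hot label

    J(a) = (1/m) Σ_k −log M_a(x_k)[y_k] ,

and `J` is minimised over the weights with a **genetic algorithm**
(population 50,000 at full scale, split 15,000 selection / 20,000
arithmetic crossover / 15,000 single-weight 10–50% mutations per
generation; a 250× smaller population with the same ratios is the fast
default). The equal-weights ensemble is the baseline. Reports cover the
3 × 3 confusion matrix, per-class PPV/TPR/FNR/FDR and total accuracy.

## Worked example

Single-channel out-of-fold decoding on a small synthetic dataset
(`python examples/03_single_channel_decoding.py`):

```
252 epochs, 6 channels, chance = 33.3%
   Fp1:  52.8%  (133/252 correct)
    F7:  54.4%  (137/252 correct)
   Fp2:  57.5%  (145/252 correct)
    F8:  51.2%  (129/252 correct)
    F3:  63.9%  (161/252 correct)
    F4:  63.9%  (161/252 correct)
```

Every channel beats the 33.3% chance level, and mid-frontal F3/F4 — the
channels the generator endows with the strongest task signal — lead, while
lateral F7/F8 trail. Metric arithmetic on a fused-model confusion matrix
(`python examples/05_confusion_metrics.py`):

```
total accuracy: 91.66% (770/840)
       resting: PPV 99.49%  TPR 98.17%  FNR 1.83%  FDR 0.51%
       picking: PPV 69.53%  TPR 74.17%  FNR 25.83%  FDR 30.47%
  coordination: PPV 76.67%  TPR 76.67%  FNR 23.33%  FDR 23.33%
errors only between adjacent reasoning depths: True
```

Resting is detected almost perfectly; the two task conditions are harder
and are only ever confused with each other or with picking — never resting
with coordination directly.

The other examples show simulation/epoching (`01`), the per-condition
scalogram signatures (`02`), and GA weight optimisation on a planted
informative channel (`04`). The full pipeline also runs from a shell:

```
levelk run --out runs/demo            # simulate → ... → evaluate
levelk grid --out grid.csv            # compare Symlet orders 2,4,6,8,10
```

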