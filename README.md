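# affectfuse

Multimodal physiological emotion recognition from EEG and peripheral
signals, built around differential-entropy scalp maps, channel attention,
a depthwise-separable CNN + ordered-neuron LSTM backbone, and multi-head
temporal self-attention, trained with a combined cross-entropy +
mutual-information objective.

## Who this is for

Researchers in affective computing who want a fully testable, CPU-scale
implementation of this model family.  The public emotion corpora this
architecture targets (32-channel EEG + 8 peripheral channels, or a
14-channel wearable headset + 2 ECG leads) are access-restricted, so the
package ships a synthetic-corpus generator that reproduces their exact
layout — 3 s baseline + 60 s stimulus at 128 Hz, per-trial ordinal ratings —
with controllable, label-dependent band-power structure.  Every stage of
the pipeline, including the full training loop, runs end-to-end on the
synthetic corpora with no downloads.

## The method

For each trial, signals are baseline-referenced (the mean of the three 1 s
pre-stimulus epochs is subtracted from every stimulus second), band-pass
filtered (EEG 0.5–40 Hz, peripherals low-passed at 30 Hz), z-scored per
channel, and cut into 3 s windows with 1 s step.  Per window:

* **EEG**: for each band b ∈ {θ, α, β, γ}, the differential entropy
  H = ½·ln(2πe·σ²_b) of the band-filtered signal is computed per channel
  and placed at the channel's cell of a 9×9 scalp grid (zero elsewhere),
  giving a 9×9×4 feature volume.
* **Peripherals**: five time-domain statistics per channel (mean, SD, peak,
  skewness, excess kurtosis) plus a learned LSTM embedding of the
  time-pooled trace.

Channel attention scores every sensor from pooled per-channel statistics
through a shared bottleneck MLP (sigmoid output in (0,1)); EEG scores are
re-arranged onto the grid to scale the DE volume.  A depthwise-separable
CNN (2× depthwise 3×3 + 2× pointwise 1×1, 64 channels) extracts spatial
features; a softmax-normalized modality weight ω = [ω_EEG, ω_PPS], Σω = 1,
scales each modality before mid-level concatenation.  Sequences of fused
window vectors feed a 2-layer bidirectional ordered-neuron LSTM (hidden
128/direction), whose outputs are projected to a 512-dimensional space
where 8-head scaled dot-product attention (the last-step output is the
query) with residual + layer norm produces the vector classified by
per-dimension softmax heads (high/low valence, arousal).

Training minimizes L = 0.6·L_CE + 0.2·L_MI where L_MI = −I(F_fusion; Y) +
0.1·Σ I(F_m1; F_m2), with Adam (lr 1e-4, ×0.9 decay every 5 epochs), L2
weight decay 1e-4, batch 32, early stopping on validation accuracy with
patience 3.  Splits are subject-independent and trial-wise (8:2 train/val
within training subjects); all windows of a trial stay in one partition.

The four ablation variants are DO (no attention), CDO (+channel attention),
DOM (+multi-head attention), and CDOM (both).

The network runs on a small reverse-mode autograd core over numpy included
in the package (`affectfuse.autograd`); gradients are verified against
finite differences in the test suite.

## Worked example

```python
import affectfuse as af
from affectfuse.network import ModelConfig
from affectfuse.train import TrainConfig
from affectfuse.preprocess import make_split

spec = af.SyntheticSpec(n_subjects=4, n_trials_per_subject=8,
                        seed=11, effect_size=1.5)
trials = af.generate_corpus(spec)          # 32 trials of 40 x 8064 samples
ds = af.build_feature_dataset(trials)      # 1856 windows of 3 s
subjects = sorted({t.subject_id for t in trials})
per = {s: sorted({t.trial_id for t in trials if t.subject_id == s})
       for s in subjects}
split = make_split(subjects, per, n_test_subjects=1, seed=5)
model = af.EmotionFusionModel(ds, split, config=ModelConfig(),
                              train_config=TrainConfig(max_epochs=12, seed=1))
results = model.fit(verbose=True)
print(results.summary())
```

Training prints one line per epoch; on this corpus the run ends around

```
epoch   8 lr 9.00e-05 loss 0.0128 val_acc 0.8750
...
epoch  10 lr 8.10e-05 loss -0.0041 val_acc 0.9074
```

i.e. validation accuracy climbs above 85–90 % within ~10 epochs because the
generator plants a strong (effect_size = 1.5) arousal-dependent β/γ
band-power shift and a valence-dependent frontal-alpha asymmetry, both of
which the DE features expose.  `results.summary()` then reports per-
dimension accuracy/precision/sensitivity/specificity/F1 on the held-out
subject, and `results.report.channel_weights` ranks sensors by their mean
attention weight.  With `effect_size=0` the same pipeline stays at chance
(~50 %) — the leakage-safe split leaves it nothing else to learn.

A command-line surface wraps the same steps:

```
affectfuse synth --out corpus.h5 --seed 1 --n-subjects 4 --n-trials 8
affectfuse featurize --archive corpus.h5 --out features.h5
affectfuse train --features features.h5 --out run/ --seed 1
affectfuse ablate --features features.h5 --out ablation.json --n-runs 3
affectfuse run --config config.yaml      # whole pipeline from one file
```

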