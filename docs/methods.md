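# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic test bed does and does
not establish.

## Signal model and preprocessing

A trial is a channels × samples matrix: 3 s of pre-stimulus baseline
followed by 60 s of stimulus at 128 Hz (40 channels in the 32-EEG + 8
peripheral configuration; 16 in the 14-EEG + 2-ECG configuration).
Preprocessing per trial, in order:

1. **Baseline removal.** The three 1 s baseline epochs are averaged per
   channel and per within-second sample; the average is subtracted from
   each of the 60 stimulus seconds, which are re-concatenated in order.
2. **Filtering.** EEG: 5th-order Butterworth band-pass 0.5–40 Hz.
   Peripherals: 30 Hz low-pass (order 5; the order for this filter was an
   open choice, set to match the EEG filter).  All filtering is zero-phase
   (forward–backward), so filtering never shifts samples relative to
   window boundaries; the alternative (causal filtering) would
   desynchronize windows from labels by the group delay.
3. **Normalization.** Per-channel z-score with the *population* standard
   deviation.  The N−1 sample SD appears only in the peripheral SD
   *feature*; the two conventions are deliberately kept separate.  A
   zero-variance channel raises an error naming the channel — a constant
   sensor trace indicates hardware failure, not data.
4. **Windowing.** 3 s windows, 1 s step, 0-based half-open sample ranges.
   Every window inherits the trial's binarized labels.

Label binarization is at the scale midpoint: high iff rating > 5 on the
1–9 scale, and by the same convention high iff rating > 3 on the 1–5
scale (the threshold for the 5-point scale is a convention of this
package; only the 9-point rule is externally fixed).

## Features

**Differential entropy.** For a band-filtered window segment treated as
Gaussian, H = ½ ln(2πe σ²) in nats (natural log throughout; the log base
was an open choice and nats make the closed form exact).  σ² is the
population variance of the filtered samples — the closed form
parameterizes the Gaussian by its variance, not by an unbiased estimator.
Per window this gives one value per channel per band (θ 4–8, α 8–13,
β 13–30, γ 30–40 Hz; B = 4 bands), scattered onto a 9×9 scalp grid
(anterior rows on top, left hemisphere left, midline in column 4) with
zeros at unmapped cells: a 9×9×4 volume.  The cell assignments follow the
standard 10–20 planar projection and are shipped as an explicit,
test-covered table (`affectfuse.montages`) — a convention, not a
reproduction of any specific figure.

For efficiency the dataset builder filters each trial once per band and
slices window variances out of the filtered trace, rather than filtering
each (two-thirds overlapping) window separately; this also keeps filter
transients at trial edges only.  The per-window API (`de_volume`)
filters the window directly and is what the unit oracles exercise.

**Peripheral statistics.** Per channel and window: mean, sample SD (N−1),
peak (max), skewness (population moments), excess kurtosis (0 for a
Gaussian; −1.2 for a uniform law — both asserted in tests).  Skewness and
kurtosis are undefined for zero-variance windows and raise.

## Network

Per window, the model consumes the channel-level DE values (the grid
scatter happens inside the network through a fixed 0/1 placement matrix),
the peripheral statistics block, and the peripheral trace average-pooled
to 16 steps.

* **Channel attention** (variants CDO/CDOM): per-channel max and mean over
  the feature axis pass through a shared bottleneck MLP (reduction ratio
  r = 4 by default; for channel counts not divisible by r the largest
  divisor ≤ r is used); the two outputs are summed and squashed by a
  sigmoid.  EEG weights scale the DE volume cell-wise via the grid;
  peripheral weights scale the per-channel feature block.
* **Spatial branch**: depthwise 3×3 → pointwise 1×1, twice, 64 channels,
  ReLU after every layer.  Dropout 0.2 is applied channelwise (whole
  feature maps), the standard form for convolutional features.  The
  flattened 9·9·64 output is linearly embedded to 128 dimensions — the
  recurrent input dimension is not externally fixed, and the embedding
  keeps the fused vector at a tractable width.
* **Peripheral branch**: a shared single-layer LSTM (hidden 8) runs over
  each channel's pooled trace; its last hidden state is concatenated with
  the channel's 5 statistics.  Both sources feed fusion by default; either
  can be disabled in `ModelConfig`.
* **Modality weighting**: one single-layer perceptron per modality scores
  its feature vector; a softmax over the scores yields ω with Σω = 1
  exactly (softmax is the mechanism chosen to realize the sum-to-one
  constraint).  Fusion is concatenation, EEG block first.
* **Temporal branch**: sequences of 6 consecutive windows (stride 3
  between sequence starts; both configurable — the sequence length over
  which temporal attention operates is not externally fixed).  A 2-layer
  bidirectional ordered-neuron LSTM, hidden 128 per direction, forget-gate
  bias initialized to 1, recurrent dropout 0.2 between layers.  The master
  forget gate is a cumulative softmax over 16 hidden chunks (chunk size 8),
  the master input gate its mirror; with the master gates forced open the
  cell reduces exactly to a standard LSTM, which is the reduction oracle
  in the tests.  The last-step output of the top layer is taken as the
  sequence summary.
* **Attention head** (variants DOM/CDOM): the recurrent outputs (256-dim)
  are linearly projected to 512 so that the attention block's fixed
  geometry (8 heads × 64 = 512) holds exactly; per head, unshared Q/K/V
  projections map the last-step output (query) and all-step outputs
  (keys/values) to 64 dimensions; scaled dot-product scores
  softmax(QKᵀ/√64) weight the values; contexts are concatenated, passed
  through dropout 0.1, added residually to the projected last-step output,
  and layer-normalized.  The √d_k scale is applied everywhere.
* **Classifier**: one softmax head per emotion dimension (valence,
  arousal by default).  Without the attention head (DO/CDO) the last
  recurrent state goes straight to the classifier.

All parameters are Glorot-initialized from a seeded generator; a closed-
form parameter count per block is regression-tested against the built
network.

## Objective and optimization

L = α·L_CE + β·L_MI with α = 0.6, β = 0.2, kept verbatim although they do
not sum to one.  L_CE is mean binary cross-entropy in nats (probabilities
clipped at 1e−12), averaged over the label dimensions.  L_MI =
−I(F_fusion; Y) + λ·Σ_pairs I(F_m1; F_m2), λ = 0.1, with Y the hard label
of the first dimension.

The canonical MI/entropy estimator is a plug-in on equal-frequency
quantile bins (16 per dimension), averaged over feature dimensions
(dimension i paired with dimension i, cycling the shorter set).  It is
deterministic, exact on small discrete distributions (the enumeration
oracles), and shared by the complementarity coefficient
C = I(F_a;F_b)/(H(F_a)·H(F_b)) (a √-denominator variant is behind a
flag).  The plug-in estimator is not differentiable, so the training-time
MI term uses a Gaussian soft-binning relaxation of the same quantile grid
(bin centers are batch quantiles, treated as constants; memberships are a
softmax of negative squared distances).  Gradients flow into the
modality-weight perceptrons and everything upstream.  For cost, the
relaxation samples at most 16 evenly strided feature dimensions per term.
This estimator choice is the largest open gap in the method as published
and is isolated behind `LossConfig.mi_estimator`.

Adam (β₁ 0.9, β₂ 0.999, ε 1e−8), initial lr 1e−4 decayed by 0.9 every 5
epochs, classic L2 weight decay 1e−4 added to gradients, batch 32, max
100 epochs (30 in the desk-scale experiments), early stopping when
validation *accuracy* (not loss) fails to improve for 3 consecutive
epochs; the best-validation weights are restored.  All randomness
(shuffling, dropout, augmentation) derives from one seed.

**Input standardization.** Before training, per-feature mean/SD are
computed on the training windows and applied to all inputs; the transform
is stored in the checkpoint.  Without it the DE features' small dynamic
range makes optimization at lr 1e−4 impractically slow.

**Augmentation.** The raw-window operation is a circular time shift
(uniform in ±0.1 s) plus amplitude scaling (uniform in [0.9, 1.1]);
circular wrapping preserves window length (edge handling was open).  During
training the equivalent transform is applied to the precomputed features
in closed form — scaling by s adds ln s to every DE cell, scales
mean/SD/peak by s, leaves skewness/kurtosis invariant, and scales and
rolls the pooled trace — avoiding per-epoch refiltering.  The equivalence
is tested.  The circular shift leaves window variance (hence DE and the
statistics) exactly unchanged, so only the pooled trace is rolled.

## Splitting

Subject-independent and trial-wise: test subjects held out whole; within
each training subject, trials split 8:2 into train/validation (at least
one validation trial per subject).  Sequences never cross trial
boundaries, so the trial-level guarantee transfers to sequences and
windows.  Leakage (a trial or subject in two partitions) is structurally
impossible and audited in tests.  Reference partitions: 32 subjects → 28
train / 4 test; 23 subjects → 20 train / 3 test.

## Synthetic corpus

Each EEG channel is a sum of band-limited filtered white noise (θ/α/β/γ,
resting variance shares 0.30/0.30/0.25/0.15) plus broadband noise, scaled
to ~10 µV.  High-arousal trials have β/γ variance multiplied by
(1 + effect_size) — a *composition* change that survives per-channel
z-scoring, which is where the DE features look.  Valence tilts frontal α
asymmetry (suppressed left / enhanced right for high valence).  EMG
amplitude scales with arousal; the plethysmograph/ECG carry a ~1.0–1.3 Hz
oscillation with a weak arousal effect; GSR and temperature are slow
drifts with no label effect; EOG is low-passed noise.  Ratings are uniform
over the ordinal scale, a per-subject constant offset (SD 5) is added to
every channel, and the 3 s baseline carries no label effect.  The default
effect_size for the demonstration corpora is 1.5 (a strong, clearly
separable effect); effect_size = 0 is the null condition.

What this does *not* emulate: volume conduction and realistic covariance
between electrodes, artifacts (blinks, line noise), non-stationarity
within a trial, realistic rating distributions, or any physiological
coupling between modalities.  Passing tests on this bed establishes that
the pipeline is wired correctly, leak-free, and able to learn planted
band-power structure — not that the architecture attains any particular
accuracy on real recordings.

## Desk-scale experiment sizes

The packaged experiments are sized for a single CPU: the separable-corpus
run uses 4 subjects × 8 trials (one test subject); the null-calibration
run uses 8 subjects × 12 trials (two test subjects) so the chance-level
estimate rests on 24 held-out trials, and is scored on the held-out
subjects (model selection already consumed the validation set); the
ablation demonstration uses 3 subjects × 6 trials with 30 s stimuli and
3 epochs × 3 seeds × 4 variants, which exercises the full comparison
machinery (mean ± SD, one-way ANOVA, Tukey HSD post-hoc — the post-hoc
test is Tukey by this package's choice) without asserting anything about
relative variant quality at that scale.

## Numerical notes and limitations

* The autograd core is float64 throughout; max-pool gradients split ties
  evenly; softmax and log are max-shifted / clipped for stability.
* The complementarity formula as printed rewards *redundant* features
  (I(F;F)/H² = 1/H), opposite to the prose claim that high C means high
  complementarity; the formula is implemented verbatim and the tension is
  documented rather than resolved.
* α + β = 0.8 ≠ 1; kept verbatim, no renormalization.
* The bidirectional "last step" is the top layer's output at the final
  time index (forward state at T, backward state having consumed only the
  final input), a common convention among several.
* Histogram-MI bias at batch size ~200 with 16 bins is non-trivial
  (O(K²/2n)); the MI term is a regularizer, so this affects magnitudes,
  not correctness of the classification path.
* Checkpoints store exact float64 parameters; eval-mode outputs reproduce
  bit-for-bit after a save/load round trip.
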