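# Methods

## Problem setting

Motor imagery (MI) modulates sensorimotor rhythms: imagining a movement
suppresses mu-band (≈8–12 Hz) power over the corresponding cortical areas
(event-related desynchronization, ERD). A motor-imagery brain–computer
interface decodes which movement a user imagined from multi-channel EEG.
Tasks within the same limb activate overlapping cortical regions, so single
decoders struggle; this package implements a multi-branch convolutional
ensemble that concatenates features from several established EEG
architectures and shapes the joint representation with supervised
contrastive learning.

## Model

Three feature extractors map a crop (channels × samples) to a flat feature
vector:

* **ShallowConvNet** — temporal convolution (40 filters), spatial
  convolution over all electrodes, batch normalization, squaring, average
  pooling and a log activation. The square → pool → log sequence computes a
  smoothed log band power, mirroring the log-variance features of
  filter-bank CSP.
* **DeepConvNet** — a linear temporal/spatial block with max pooling,
  followed by three conv–max-pool blocks (50, 100, 200 filters) with ELU.
* **EEGNet** — a compact architecture: length-preserving temporal
  convolution (8 filters), depthwise spatial convolution (16 maps, unit
  max-norm constraint), and a separable convolution, with average pooling.

For a 16-channel, 128-sample input these produce 480-, 800- and
64-dimensional features (1344 concatenated); for a 22-channel, 1000-sample
input, 2440/1400/112 (3952 concatenated).

The **feature projector** is a single 16-unit dense layer with ELU; its
output is L2-normalized by default so that the dot-product similarities of
the contrastive loss live on the unit sphere and the temperature keeps a
consistent scale. The **classifier** is a dense softmax head.

Two objectives are used. Cross-entropy
`L_cls = mean_i −log p_i(y_i)`, and the supervised contrastive loss over
mini-batch embeddings `z`,

    L_sup = Σ_i −1/|P(i)| Σ_{p∈P(i)} log [ exp(z_i·z_p/τ) / Σ_{a≠i} exp(z_i·z_a/τ) ],

where `P(i)` is the set of other same-class samples in the batch and
τ = 0.05. Anchors with no positive partner contribute zero. The
implementation stabilizes the log-sum-exp by row-max subtraction and has a
closed-form gradient that is checked against finite differences in the test
suite.

## Training protocols

**Sequential optimization** (default) trains disjoint parameter sets in
three stages:

1. *Pretraining* — each base learner, with a temporary softmax head over
   its own features, is optimized independently on cross-entropy.
2. *Contrastive representation learning* — the heads are discarded, the
   extractors are frozen (and run in inference mode, so their concatenated
   features are computed once and cached), and the projector alone is
   trained on `L_sup`. Batches are drawn class-balanced so that every
   anchor has at least one positive.
3. *Fine-tuning* — the softmax head alone is trained on the frozen
   projected embeddings with cross-entropy.

**Joint optimization** trains everything end to end on `L = L_cls + L_sup`
with unit weights (no tunable trade-off). The feature-concatenation variant
without projector or contrastive stage (MBCNN) fine-tunes the head directly
on the concatenated features; with joint optimization it reduces to plain
end-to-end cross-entropy.

All stages use Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch size 32, dropout
0.5 in the full-size extractors, and early stopping when the stage's
training loss has not improved for `patience` (default 10) epochs, with a
`max_epochs` safety cap (default 500). Early stopping monitors training
loss rather than a validation split; a held-out criterion can be emulated
by passing a pre-split crop set.

**Weighted voting (DE)** combines the pretrained learners' softmax outputs:
prediction = argmax_c Σ_b w_b·p_b(c). Weights in [0,1]^B are fitted by
DE/rand/1/bin — 50 candidates, 100 generations, differential weight F
dithered per generation in [0.5, 1], crossover probability 0.7, one
guaranteed mutant coordinate, greedy selection keeping the parent on ties —
maximizing training-crop accuracy. The initial population contains the
centre-of-box candidate (all weights 0.5), which is argmax-equivalent to
uniform voting, so the optimized ensemble never scores below uniform
voting on the training set. Weights are not normalized (argmax is
scale-invariant).

## Preprocessing

* 512 Hz, 16-channel chain: decimate ×4 (FIR anti-alias) → 0.5–30 Hz
  Butterworth band-pass (design order 8) → 50 Hz notch realized as a 48–52
  Hz Butterworth band-stop (design order 4). No artifact removal or
  standardization.
* 250 Hz, 22-channel chain: 4–38 Hz Butterworth band-pass (order 3) →
  per-trial electrode-wise exponential moving standardization,
  `x'_k = (x_k − μ_k)/σ_k` with `μ_k = (1−α)x_k + αμ_{k−1}`,
  `σ²_k = (1−α)(x_k−μ_k)² + ασ²_{k−1}`, α = 0.999, state initialized from
  the trial's own per-channel mean and variance. A variance floor of 1e−8
  guards constant channels. Both recursions are first-order IIR filters and
  are evaluated with `scipy.signal.lfilter`; a per-sample loop oracle in the
  tests confirms equality to 1e−10.

Filters default to zero-phase forward–backward application (the stated
order is the design order; forward–backward doubles the effective order);
a causal mode is available for online-style processing. Forward–backward
filtering pads by **even** (value-continuous) extension: odd extension
injects a step at the boundary whose transient decays over seconds when the
high-pass edge is at 0.5 Hz.

## Cropping and splitting

Sliding-window augmentation cuts each trial into
`floor((L−W)/S)+1` crops (first crop at sample 0). Fractional strides in
samples (0.1 s × 128 Hz = 12.8) round to the nearest sample (13) by
default; floor rounding is available. A 6 s trial at 128 Hz with a 1 s
window therefore yields 50 crops. Trial-wise mode uses one crop covering
the whole trial.

Splits are stratified k-fold over *trials*, independently reshuffled per
repetition, and crops are routed strictly by their parent trial's
membership — a fuzzed property suite verifies that no parent trial ever
contributes crops to both sides. Test-set crops are scored individually
(crop accuracy, the headline number) and aggregated per trial by averaging
softmax outputs (trial accuracy, also reported).

## Synthetic ERD data

The generator emulates the statistical structure the decoders exploit:
each trial is 1/f-shaped Gaussian background noise (unit variance per
channel, spectral exponent 1.0 by default) plus a mu-band sinusoid with
per-trial random frequency (8–12 Hz) and phase. Each class attenuates the
oscillation amplitude on its own block of channels by `erd_depth`, so a
depth d reduces oscillation band power by (1−d)². The in-band SNR parameter
is the ratio of oscillation band power to background power inside the mu
band on an unattenuated channel; the default of 3.0 represents a subject
with strong, clearly visible ERD. The default geometry (6 classes, 20
trials per class, 16 channels, 128 Hz, 6 s trials) exercises the reference
architecture shapes end to end; a 22-channel, 250 Hz, 4-class preset is
also provided.

What the generator does **not** model: temporal ERD ramps within a trial,
beta-band activity, inter-trial nonstationarity, volume conduction between
channels, and ocular/muscular artifacts. Passing tests on this data show
that the pipeline recovers class-dependent band-power structure; they say
nothing about robustness to artifacts or session-to-session transfer on
real EEG.

## Numerical choices

* Networks run in float32; gradient checks run the same code in float64.
* Weight init: fan-in uniform (±1/√fan_in) from a per-component seed;
  every stochastic element (init, dropout, batch order, DE, the generator)
  derives from explicit seeds, and training histories are bit-reproducible.
* ShallowConvNet's log activation is guarded as log(max(x, 1e−6)). The
  package defaults to the square → log reading of the architecture: the
  alternative ELU → log ordering leaves a large fraction of pooled values
  at the guard floor (their gradient is zero) and trains markedly worse;
  it remains available via `ExtractorSpec.shallow_activation="elu-log"`.
* Batch normalization uses eps 1e−3 and running-statistic momentum 0.99.
* Voting ties break toward the lowest class index; DE selection keeps the
  parent on fitness ties.
* The scaled-down `tiny` architecture preset used in fast tests lowers
  dropout to 0.25 and widens the deep blocks slightly — features tens of
  units wide do not tolerate the full-size regularization.

## Scaled-down experiment sizes

The end-to-end suite trains the full-size three-branch ensemble on the
default synthetic preset (120 trials → 6000 one-second crops at 0.1 s
stride, one fold of a stratified 5-fold split) with the pretraining stage
capped at 6 epochs — the base learners plateau on held-out crops by then —
and the cheap cached-feature stages (projector, head) capped at 60; at
these sizes the sequential sliding-window ensemble
reaches high held-out crop accuracy while the jointly optimized trial-wise
configuration, fitting 96 whole-trial samples, overfits — qualitatively
reproducing the ordering reported for the full-scale study. Micro
experiments in the unit tests use the `tiny` preset (4 channels, 64
samples) to keep individual tests in the seconds range.

## Known limitations

* The layer core is CPU-only numpy; it is adequate for the package's
  problem sizes but not for large-scale EEG corpora.
* GDF/EDF reading delegates to `mne`; only annotation-based event tracks
  are supported.
* Statistical comparisons (Shapiro–Wilk, two-sided Mann–Whitney U) follow
  the reporting convention of the field; with few cross-validation cells
  their power is limited, and identical samples are reported at p = 1.0 by
  definition.
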