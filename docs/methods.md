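# Methods

`eegaffect` implements an EEG emotion-recognition pipeline: continuous
affect ratings are binarized, multichannel trials are cut into overlapping
fixed-length windows, and a hybrid bidirectional/unidirectional gated
recurrent network classifies each window into a negative/positive affect
state per rating dimension (arousal, valence, dominance, liking).

## Segmentation model

A trial of `L` samples is windowed with two parameters: the window length
`N` and the overlap parameter `O`, defined as the number of samples **not**
shared by consecutive windows, so each consecutive pair shares `N − O`
samples and windows start at `0, O, 2O, …`.  Canonical semantics are
shift-by-`O` tiling (`tile` mode): windows are emitted while
`start + N ≤ L`, trailing samples that do not fill a window are dropped,
and the window count has the closed form `⌊(L − N)/O⌋ + 1`.  Indexing is
0-based and half-open.  A second mode, `capped(K)`, emits exactly `K`
windows at the same shift and errors if the last would overrun; it exists
because the reference protocol describes both a near-total overlap
(`N = 4032`, `O = 6`, which tiles an 8064-sample trial into 673 windows)
and a "two segments per trial" reading (which `capped(2)` with `O = 4032`
reproduces).  These two readings are mutually inconsistent at face value,
so the package makes the mode an explicit configuration choice and every
experiment records which one it used.

The two-phase parameter search mirrors the reference protocol: phase 1
sweeps candidate window sizes at a fixed overlap and selects the
accuracy-argmax per label (ties broken toward the larger window — longer
temporal context); phase 2 sweeps overlaps at the winning window size (ties
broken toward the smaller overlap, which keeps consecutive windows most
similar).  Both drivers take the evaluation function as an argument, so
they are testable with stubs and run for real via the pipeline.

## Classifier

The proposed stack is

    BiLSTM(128) → BiLSTM(64) → Dropout(0.5) → LSTM(32) → Dense softmax

operating on sequences whose steps are time samples and whose per-step
feature vector is the channel vector.  Each gated cell follows the standard
LSTM equations (input/forget/output gates, cell state), giving
`4h(d + h + 1)` trainable parameters for input width `d` and `h` units; a
bidirectional layer runs an independent reversed-time cell and concatenates
per-step outputs, doubling the count.  For 32-channel input the stack
totals 164 864 + 164 352 + 20 608 + 66 = 349 890 parameters.  Three
ablation variants (BiLSTM(128)+LSTM(64), BiLSTM(128)+BiLSTM(64),
LSTM(128) alone, each with the corresponding dropout and a softmax head)
isolate the contribution of depth and bidirectionality.

Design choices where the reference description is silent:

* **Dropout rate of the proposed stack**: 0.5, by analogy with the ablation
  variants that state 0.5; configurable.
* **Units of a bidirectional layer** mean units *per direction* (the
  parameter counts above assume this); configurable in principle by
  building a custom `ModelSpec`.
* **Loss**: categorical cross-entropy, the standard companion of a softmax
  head.  **Optimizer**: Adam, learning rate 0.001, batch size 32, 5 epochs.
* **Dropout placement**: after the two bidirectional layers, before the
  unidirectional layer, following the stated layer ordering.
* One independent binary model per label (four models), since each label is
  thresholded separately; no multi-task head.

The network, backpropagation through time and Adam are implemented in
NumPy (float32).  Weight initialization is Glorot-uniform for input
weights, per-gate orthogonal for recurrent weights, forget-gate bias 1;
gradients are clipped to a global norm of 5.  The backend has no
nondeterministic kernels, so a fixed seed makes initialization, shuffling
and dropout — and therefore entire runs — bit-reproducible; the
`deterministic_mode` flag is recorded for interface parity.

Because full-resolution windows (thousands of recurrent steps) train
slowly on CPU, an optional decimation factor average-pools the window along
time before the network.  Decimation defaults to off; the validation suite
and benchmark use factor 8.  Average-pooling by 8 at 128 Hz is a crude
low-pass: it passes delta/theta nearly intact, attenuates alpha to roughly
half amplitude, and suppresses 13–30 Hz content by a factor of 5–8 (with
spectral nulls at 16 and 32 Hz).  This matters for the synthetic design
below.  Inputs are scaled by a fixed global constant (1/15 per microvolt by
default) rather than per-segment normalization, which would erase the
between-class amplitude structure the classifier is supposed to detect.

## Evaluation protocol

Binary metrics come from confusion-matrix counts: accuracy
`(TP+TN)/total`, precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
`F1 = 2PR/(P+R)`.  Zero-denominator cases return 0 with a logged warning
so grid-search tables stay total.  The ROC curve sweeps the positive-class
probability over all distinct score values (ties grouped into one step),
runs from (0, 0) to (1, 1) and is non-decreasing in both coordinates.
Cross-validation forms shuffled k folds (k = 5 by default) at the trial
level and reports per-fold metrics with mean ± sample standard deviation
(the k−1 denominator).  Multiclass (SEED-style ternary) metrics are
macro-averaged one-vs-rest; only accuracy is meaningful there.

**Leakage**: with `O ≪ N` consecutive windows are near-duplicates, so
splitting at the segment level places near-copies of one trial on both
sides of the train/test divide and inflates test metrics.  The default
split (and CV fold) unit is therefore the trial; segment-level splitting
is available behind an explicit flag and logged as a leakage risk.  The
reference protocol does not state which unit it used, and with near-total
overlap this choice dominates achievable test numbers — which is one
reason published headline accuracies on the licensed data are not
reproduction targets for this package.

## Synthetic data

The generator emits the DEAP release geometry — 32 participants × 40
trials × 32 channels × 8064 samples at 128 Hz (63 s), ratings in [1, 9] —
with planted, recoverable class structure.  Ratings are drawn per label:
class from a Bernoulli with the configured positive fraction (defaults are
the published ratios: arousal 0.60, valence 0.53, dominance 0.65, liking
0.93), then a rating uniform on the matching side of the threshold 5.

Signals are sums of (i) band-limited carriers in the five canonical bands,
(ii) a 1/f background (8 µV RMS), and (iii) white sensor noise (6 µV RMS).
Class structure is band-limited amplitude modulation: each label owns one
band, and positive trials multiply that band's amplitude by
`1 + separability × (gain − 1)` with `gain = 3` by default, so
`separability = 0` is an exact null and `separability = 1` is the default
gap.  Each signature band is also concentrated on its own quarter of the
channels (weight 1 on the group, 0.1 elsewhere) — a coarse stand-in for
the spatial topography of real rhythms, and the feature that lets four
independent per-label classifiers each recover "their" effect.

Default carriers are **band-passed white noise** (every FFT bin in the band
gets an independent random phase).  A small fixed sinusoid mixture is
available (`carrier="sinusoid"`) but is not the default: with trial-fixed
frequencies and phases, a 350 k-parameter network trained on a few hundred
windows memorizes trial identity instead of the amplitude cue, which is
exactly the failure mode a recovery benchmark must not reward.

Band assignment and amplitudes were chosen for recoverability under the
default experimental representation, and deliberately deviate from scalp
realism in two places:

* **Liking is carried by delta, not gamma.**  Gamma (>30 Hz) scalp
  amplitudes are sub-microvolt and average-pool-by-8 has a null at 32 Hz;
  a gamma-carried label would be unrecoverable in the decimated
  representation.  The assignment (valence→alpha, arousal→beta,
  dominance→theta, liking→delta) keeps all four signatures below 30 Hz and
  is configurable.
* **Base amplitudes are equalized in effect, not in scalp microvolts**:
  delta 30, theta 22, alpha 30, beta 80, gamma 1.5 µV.  The nominally
  large beta value compensates the 5–8× pooling attenuation of 13–30 Hz
  content so that each label's effective (post-decimation) signature is
  comparably detectable.  Published scalp ranges (e.g. theta 100–150 µV,
  beta 5–20 µV) can be restored through `base_amplitudes` when realism
  matters more than recoverability.

What the generator does **not** emulate: volume conduction, electrode
geometry, artifacts, non-stationarity, inter-participant variability, or
any genuine neural correlate of affect.  A passing recovery benchmark
shows the pipeline finds planted spectral structure without leakage; it
says nothing about accuracy on real recordings.

## Recovery benchmark

`eegaffect.benchmarks` fixes the reference protocol used by the validation
suite and the reproduction script: 2 participants × 40 trials with
balanced (0.5) label ratios, disjoint 512-sample windows capped at 5 per
trial, stratified trial-level 50/50 split (→ 200 training segments, and
200 test segments from 40 held-out trials — an even split keeps the
training set at the reference size while giving the accuracy estimates a
low-variance test side; the 80/20 fraction remains the default everywhere
else), decimation 8 (64 steps), the proposed model, Adam lr 0.001 /
batch 32 / 5 epochs, 3 seeds.  Each label's model is compared
with a **shuffled-label null** — the same architecture trained on permuted
training labels — which controls for class imbalance and accidental
leakage.  Balanced ratios are used because against the published
imbalanced ratios the null itself sits at the majority rate (0.93 for
liking), leaving no headroom for a meaningful margin; the imbalanced
ratios are exercised by the generator's ratio-recovery checks instead.
Problem sizes were chosen so the full study (four labels, three seeds,
real + null, plus a four-level separability curve) completes in minutes on
one CPU while every label's task stays comfortably learnable; they are not
the published experiment's sizes.  Under the frozen defaults the
seed-averaged margins are roughly +0.4 to +0.5 per label and the
separability curve (0, 0.5, 1, 2) rises from chance to near-perfect.

## Numerical and degenerate-case choices

* Floor rule for split sizes: `⌊fraction · n_units⌋` units to train, the
  remainder to test; stratification applies the floor within each class.
* Windows that would overrun the trial are never emitted (no padding).
* The 3-second pre-trial baseline (384 samples) contained in the 8064 is
  kept by default; `drop_baseline` removes it on request.
* Ratings-column order in DEAP-layout files is (valence, arousal,
  dominance, liking), the public release order; configurable.
* Rating exactly 5 binarizes positive ("lower than five" is negative,
  otherwise positive).
* Non-finite ratings, single-class ROC inputs, zero-length splits and
  mismatched shapes raise validation errors rather than propagating NaNs.

## Known limitations

* Full-resolution training (4032 steps) is supported but slow on CPU —
  minutes per batch, so sweeps at full resolution are research-scale runs,
  not test-scale.
* The SEED pathway loads generic per-clip arrays with ternary labels; no
  dataset-specific container dialect is implemented.
* No early stopping or validation split during the 5 epochs; no
  hyperparameter search beyond the window/overlap grids.
* The NumPy backend trains on one CPU; there is no GPU path.
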