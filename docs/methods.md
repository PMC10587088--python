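# Methods

This note documents the models, defaults and numerical choices behind
`harpipe`, and what the synthetic experiments do and do not establish.

## Signal model of the synthetic generator

Real inertial HAR signals are quasi-periodic within an activity bout; the
generator captures exactly that structure and nothing more. Each activity
class is a per-channel mixture of sinusoids with class-specific frequencies
(cycles/sample, strictly below the 0.5 Nyquist limit) and amplitudes, plus
i.i.d. Gaussian sensor noise (default sd 0.3 in sensor units) and a constant
per-window drift drawn uniformly from ±0.5, standing in for posture-dependent
gravity offsets. The five default classes (walking, blinking, standing,
sitting, emergency) are separated both spectrally (frequencies spanning the
dyadic octaves the Haar bank resolves, ~0.01–0.35 cycles/sample) and by
amplitude (near-static postures 0.15–0.3, emergency 2.0). Defaults:
5 classes × 200 windows × 128 samples × 3 channels, i.e. a desk-scale but
non-trivial problem.

Defects are concrete realizations of the four classical stream-quality
problems: *missing* = one channel entry blanked to NaN; *corrupted* = one
entry multiplied by 50 (an outlier spike); *duplicated* = an exact copy of a
record inserted directly after it; rates are fractions of records and defect
sites are disjoint across kinds, so ground-truth bookkeeping is exact.

What passing tests on this generator do **not** show: robustness to
non-stationary activity transitions inside a window, correlated or heavy-
tailed sensor noise, inter-subject variability, or class imbalance. The
generator is a controlled testbed, not a biomechanical simulator.

## Cleaning (mode-integrated binning)

Per channel, values are binned (default 16 equal-frequency bins; equal-width
available), each value is replaced by its bin's representative (means by
default; medians and nearest-boundary supported) and missing values are
imputed with the grouped mode `M = l + t (F_m − F_p)/((F_m − F_p)+(F_m − F_s))`
of the modal bin. When the histogram is flat around the modal bin the formula
degenerates to 0/0; its symmetric limit — the bin midpoint — is used instead.
Values outside the fitted edges clamp into the terminal bins, which is the
binning's outlier mitigation: a ×50 spike lands in the last bin and is
replaced by that bin's mean. Bin-mean smoothing can only shrink per-channel
variance (law of total variance), which the tests assert. "Duplicate" means
consecutive records identical in source, timestamp, label and all channel
values (NaN-aware); nothing else is treated as duplication.

## E-C-D discretization

Channel entropy is the Shannon entropy of a 32-bin value histogram (empty
bins skipped) scaled by `C_boltz` (default 1, i.e. pure Shannon). Entropy
weights `E/ΣE` scale the channels before clustering; for per-channel 1-D
k-means a positive scale factor rescales centroids together with the data
and therefore leaves the partition unchanged — the weighting is kept for
fidelity of the model object (weights are stored and reported) but it is not
what drives the interval choice. k-means uses k-means++ seeding, 10 restarts
(5 in the pipeline default), 300 Lloyd iterations, tolerance 1e-6; the
candidate count (default candidates 4, 6, 8, 12, 16) with the highest mean
silhouette across channels is selected. Quantization maps each value to the
nearest centroid, ties to the smaller centroid, making the transform a
projection (idempotent, codomain = centroid set). Whether discretization
should emit level indices or quantized values is an open design point; values
are emitted because the wavelet stage needs real-valued signals.

## Wavelet scattering

Band-pass filters are dyadically dilated Haar wavelets, scale `j` having
`2^(j−1)` taps of `+2^(−j/2)` followed by `2^(j−1)` of `−2^(−j/2)` (zero
mean, unit l2 norm). The low-pass is the Symlet-4 scaling filter cascaded
à-trous; the cascade depth is the smallest whose support reaches `2^J`,
capped so the support never exceeds the window, and the taps are normalized
to unit sum so constants pass unchanged. All convolutions are circular: this
makes the global time-average of every scattering path *exactly* invariant
to circular shifts, which the tests check to 1e-9, and lets an O(n²) direct
convolution serve as an independent oracle for the FFT path (agreement to
1e-10). Only frequency-decreasing second-order paths (`j2 > j1`) are
computed, the standard scattering convention; there is no intermediate
subsampling, pooling being a single global average per path. With
`normalize=True` each band-pass filter is rescaled to unit operator norm
(max circular-DFT magnitude at the configured window length), making every
stage non-expansive; the measured feature-map Lipschitz ratio on random
64-sample windows is ≈ 0.05, far below 1. Default `J = 4` for 64–128-sample
windows.

## Golden-eagle feature selection

Positions live in `[0,1]^M` and decode to masks by `x_j > 0.5`. Per
iteration each eagle picks a prey uniformly from the population's memories,
forms the attack vector `α = prey − x`, and a cruise destination on the
hyperplane `{A : α·A = α·prey}` by fixing one coordinate with nonzero `α`,
drawing the rest uniform on [0,1] and solving for the fixed one (the
construction satisfies the hyperplane identity to machine precision; a zero
attack vector falls back to a random unit direction). The step is
`R1·k_a·α/‖α‖ + R2·k_c·G/‖G‖` with `R1, R2` elementwise
`Binomial(10, 0.5)/10` draws; propensities interpolate linearly, attack
0.5→2.0 and cruise 1.0→0.5, over the run. Positions are clamped to the box;
memories are elitist, so the best-so-far trace is monotone.

The wrapper fitness is a *soft* nearest-centroid score: mean 3-fold
stratified-CV softmax probability of the true class under Gaussian
posteriors `p_c ∝ exp(−‖x − μ_c‖²/2)`, minus a sparsity penalty
`ω·(∇/M)` with `ω = 0.1`. Plain 0/1 CV accuracy is available as a plug-in
scorer but is a poor default: on well-separated problems CV accuracy
saturates and ties large sets of near-optimal masks, so the argmax carries
no information about marginal features; the soft score stays strictly
sensitive near the ceiling. Mask fitnesses are cached (the decode is
many-to-one), empty masks score −∞, and everything is deterministic given
the seed. Defaults: population 20, 100 iterations (60 in the pipeline
default).

## Scatter-matrix normalization

The scatter matrix is the unnormalized sum of centered outer products over
the training samples restricted to the selected columns; features are
z-scored by `sqrt(diag(δ)/n)` (biased sd). Zero-variance columns center to
zero with scale 1. The summary is fitted on the training split only and
applied frozen to the test split. Full whitening is deliberately not the
default: the classifier benefits from per-feature range normalization, and
decorrelation is not required by any downstream contract.

## Lego-filter classifier

One shared bank of `n_lego = 4` filters of shape `fragment_dim × kernel_len`
(4 × 3) serves all layers and all fragments, so the convolutional parameter
count is `n_lego · fragment_dim · kernel_len = 48` regardless of input
width. Masks assigning (output slot, fragment) pairs to filters are fixed at
initialization by balanced round-robin — learnable masks would need
straight-through machinery that is out of scope. Per layer the input is
zero-padded to a whole number of fragments, each fragment is contracted
against every filter, the mask picks one product per slot and slots are
summed over fragments; merging is concatenation + ReLU, with global average
pooling after the last layer and a zero-initialized dense softmax head
(hence exactly uniform probabilities before training). Training is
mini-batch explicit-Euler descent on cross-entropy — the canonical
time-discretization of the loss gradient flow, with the learning rate as the
Euler step — using manual backprop verified against central differences to
1e-5 relative. Defaults: 2 layers, lr 0.05, 300 epochs, batch 32, early
stopping on a 10% validation split with patience 50, best-validation
parameters restored. Ties in the argmax resolve to the smaller class id.

## Evaluation protocol

Stratified 80/20 split (per class, `round(0.8·n_c)` to train), deterministic
given the seed. Metrics are computed from one-vs-rest confusion tables:
accuracy `(TP+TN)/n`, precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
`F = 2PR/(P+R)`, all ×100 and reported to 3 decimals; zero denominators
yield flagged zeros. Multi-class summaries macro-average the per-class
values; the headline accuracy is the plain multi-class hit rate. Every
stateful stage (binning, discretizer, selection mask, scatter summary,
classifier) is fitted on training windows only; a permuted-label control
lands at the 20% chance level for 5 classes, and identical seeds reproduce
reports byte-for-byte.

## Problem sizes

The default experiment is 5 classes × 200 windows × 128 samples × 3
channels (1 000 windows, 33 scattering features), which runs end to end in
well under a minute on one CPU; the recovery experiment uses 400 samples ×
50 features with 10 planted columns. These sizes were chosen as the smallest
at which every stage's behaviour (selection pressure, generalization gap,
chance controls) is clearly measurable.

## Known limitations

- The Haar/Symlet bank is fixed; no learned or tunable-Q filters.
- Channels are discretized independently; no joint vector quantization.
- The cruise fallback for 1-D problems degrades GEO to random search.
- The classifier consumes pooled feature vectors, not time-resolved maps;
  kernel taps act along the feature axis within a fragment.
- Cleaning assumes defects are pointwise; burst losses or clock skew between
  peers are out of scope, as are streaming ingestion and binary formats.
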