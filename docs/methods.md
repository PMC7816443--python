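# Methods

## Problem and model

Given a bipartite network of validated drug–target interactions, the
task is to score unseen (drug, protein) pairs. Proteins enter as
PSI-BLAST position-specific scoring matrices (PSSMs): L×20 integer
log-odds matrices whose entry P_ij measures how readily position i
tolerates amino acid j over evolution. Drugs enter as 881-bit
substructure fingerprints. The pair representation is a fixed-length
protein feature vector concatenated with the raw fingerprint bits, and
the classifier is a weighted extreme learning machine (WELM).

## PSSM → image → SURF features

The PSSM is rescaled per protein by a linear min–max map to [0, 1]
(a constant matrix maps to 0.5 everywhere: it carries no contrast and
must yield no keypoints). The rescaled matrix is treated as a
single-channel image. Rationale for min–max: it preserves the relative
ordering of substitution propensities, is deterministic, and needs no
corpus statistics.

**Detection.** Second-order Gaussian derivatives are approximated by
box filters evaluated on an integral image; the detector response is
det H = Dxx·Dyy − (0.9·Dxy)², each D normalised by filter area, with
the Laplacian sign (Dxx + Dyy) distinguishing bright from dark blobs.
One octave of filter sides 9, 15, 21, 27 is used (σ = side·1.2/9 =
1.2, 2.0, 2.8, 3.6); grids are tiny (20 columns), so deeper pyramids
and sub-pixel interpolation add nothing. Keypoints are strict maxima
over the 26-neighbourhood in (row, col, scale), evaluated at the two
interior levels only; consequently the detectable blob widths are
roughly σ ∈ [2.0, 2.8]. The detection threshold is relative,
0.01 × the grid's maximum response: an absolute threshold would be
meaningless across proteins whose PSSM contrast varies, and a much
lower relative threshold admits the faint annulus extrema that an
isolated blob's tails generate under the largest filter.

Because the grid is only 20 columns wide, the normalised image is
reflection-padded far enough to support the largest filter, the
orientation circle (6σ plus the wavelet side) and the rotated
descriptor window (10√2 σ plus the wavelet side); keypoints whose
extremum falls in the padding are mirror artefacts and are dropped.
An optional integer `upsample` factor (default 1) replicates pixels
before padding.

**Orientation.** Haar responses with side ≈ 4σ sampled on a σ-spaced
grid within radius 6σ, Gaussian-weighted (std 2σ); a π/3-wide sector
slides in 0.15-rad steps and the orientation is the angle of the
longest summed response vector. Ties resolve to the first sector
encountered, making the result deterministic. An `upright` flag skips
orientation entirely.

**Descriptor.** A 20σ×20σ window aligned with the orientation, 4×4
sub-regions of 5×5 σ-spaced samples; per sub-region (Σdx, Σdy, Σ|dx|,
Σ|dy|) of the rotated, Gaussian-weighted (std 3.3σ) Haar responses
(wavelet side ≈ 2σ); 64 entries, normalised to unit length. Raw norms
below 1e−9 are declared flat and returned as the zero vector — on a
constant window the integral-image arithmetic leaves ~1e−13
cancellation dust that unit normalisation would otherwise inflate into
spurious structure.

**Pooling.** The number of keypoints varies per protein; the
fixed-length protein vector is the arithmetic mean of its descriptors
(64-d) by default. Mean pooling is translation-invariant and
parameter-free. The alternative is a bag of visual words: a k-means
codebook (K = 32 default, seeded) fitted on the pooled descriptors of
all proteins, each protein encoded as the L1-normalised histogram of
nearest-word assignments. How a descriptor set should best be
collapsed is genuinely open; both modes are first-class and the choice
is a config key. Zero keypoints give the zero vector, flagged via
`n_keypoints = 0`.

## Classifier

Hidden layer: weights U(−1, 1), biases U(0, 1), drawn once from a
seed; activations sigmoid 1/(1+e^−(a·x+b)) or Gaussian RBF
exp(−b‖x−a‖²). Defaults follow the evaluation protocol: 2500 hidden
neurons, C = 160, sigmoid. Output weights solve the weighted ridge
problem in closed form with the branch chosen by sample count N versus
hidden width L; the two branches are algebraically equivalent
(push-through identity) and the test suite asserts their numerical
agreement to 1e−8. Solves use an LU factorisation of the regularised
Gram matrix, never an explicit inverse. Targets are one-hot in
{−1, +1}; prediction is argmax with ties to the earlier class in the
sorted class order.

Class weighting: `w1` assigns 1/Count(class) (equalises the aggregate
influence of each class), `w2` additionally multiplies the unique
majority class by 0.618. When class sizes tie there is no majority and
all classes receive the minority weight. `none` is the plain ELM
baseline used for comparison runs.

The protein block of the pair feature vector is z-scored with
statistics of the training portion only (stored on the model, applied
at prediction); fingerprint bits pass through unscaled, since 0/1
indicators are already on a bounded, comparable scale.

## Evaluation protocol

Negatives are drawn uniformly without replacement from the non-edges
of the bipartite network, by default as many as there are positives.
Cross-validation is a seeded stratified shuffle into k = 5 folds;
stratification prevents class-starved folds on small datasets. Metrics
per fold: accuracy, sensitivity TP/(TP+FN), precision TP/(TP+FP), and
Matthews correlation; zero-denominator cases return 0 with a
degenerate-case flag rather than raising. A non-standard legacy
sensitivity variant with denominator TP+TN exists behind
`metrics(..., legacy_tpr=True)` purely for auditing older reports.
ROC curves come from a threshold sweep of the positive-class score;
AUC is the trapezoid integral, which equals the Mann–Whitney
concordant-pair statistic (asserted in tests by exhaustive pair
counting).

A single global experiment seed derives per-stage seeds (negative
sampling, hidden layer, fold shuffle, codebook) via SHA-256, so any
stage can be reproduced in isolation and a full rerun is
byte-identical. Extracted features are cached on disk keyed by the
hash of (PSSM contents, extractor config).

## Synthetic worlds

The generator plants a recoverable signal: drugs and targets carry
r-dimensional standard-normal latent factors; the pairs in the top
`density` quantile of factor inner products are the edges. Target
PSSMs are i.i.d. integer noise in [−6, 8] (the typical log-odds range)
plus Gaussian blobs of spatial std 2.5 at fixed anchor positions whose
amplitude is signal_strength × tanh(v_k) × 3 — the factor's sign
selects bright versus dark blobs and its magnitude their contrast.
Blobs of that width sit exactly in the detector's sensitive band, so
the planted information is what the SURF stage can recover. Drug
fingerprint bits are Bernoulli with logits baseline + signal_strength
× (fixed projection of the factor).

Presets (the study conditions; sizes chosen to keep a full run in
seconds on one core):

* `separable` — 40×40 entities, r = 1, density 0.15, strength 5,
  PSSM length 60, balanced negatives. The rank-1 world makes the edge
  rule (same sign, large magnitudes) fully expressible through the
  blob code, and 5-fold CV recovers it with mean accuracy and AUC
  well above 0.9.
* `weak` — same world at strength 1.
* `null` — strength 0 and r = 8. Rank matters here: at r = 1 the
  quantile edge rule concentrates edges on a few high-magnitude
  entities, and because the same drugs and proteins recur across CV
  folds, a classifier can exploit entity base rates through
  identifier-like fingerprints even with no planted signal (a known
  leakage mode of pair-level DTI evaluation — accuracy ≈ 0.74 with
  zero signal). A rank-8 world homogenises degrees so that a
  signal-free run truly scores at chance (≈ 0.5).
* `imbalanced` — 30×30, density 0.08, nine negatives per positive,
  for comparing the weighting strategies. At the default 2500-neuron
  capacity the ridge near-interpolates and `w1` and `none` typically
  coincide here; the strict minority-recall improvement from
  weighting is exhibited on a low-capacity overlap toy in the unit
  tests.

What the synthetic worlds do **not** emulate: real amino-acid
composition and sequence correlation in PSSMs, chemically valid
fingerprint bit correlations, and the hub structure of curated
interaction databases. Passing tests therefore demonstrate that the
pipeline recovers signal of the planted geometry, not that it attains
any particular accuracy on curated benchmark data — reproducing those
numbers requires the original databases and a PSI-BLAST run against a
large sequence collection, both outside this package's scope (the
PSI-BLAST settings conventionally used are e-value 0.001, three
iterations).

## Numerical choices and limitations

* Coordinates are 0-based (row, col); descriptor sample positions are
  rounded to the nearest integer pixel; Haar boxes are clamped at the
  (generously padded) grid edge.
* Keypoint ordering is deterministic (response desc, then scale, row,
  col); k-means uses a fixed seed and 10 restarts.
* The detector cannot see blobs narrower than σ ≈ 2 (single octave,
  interior levels only) — on 20-column PSSMs this is a feature bound,
  not a bug, but it bounds what "signal" means for this method.
* Mean pooling discards keypoint positions and counts; two proteins
  with similar local motifs at different positions look alike. BoVW
  trades that for codebook variance.
* Entity-identity leakage is intrinsic to pair-level CV on bipartite
  data (see the `null` preset discussion); per-entity or cold-start
  splits are out of scope here.
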