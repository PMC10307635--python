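# Methods

This note documents the model, its tunable parameters, the synthetic data
the package is validated on, and the numerical and design choices made where
the design was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The object of study is intraoperative surgical activity in robot-assisted
procedures, observed only through video.  Three recognition tasks share one
architecture: suturing subphase recognition (needle handling / driving /
withdrawal), dissection gesture classification (hook, clip, cold cut, camera
move, peel, retraction, or suturing gestures R1/R2/L1/C1), and binary skill
assessment of needle handling and driving.  Raw video never enters the
package: a frozen external extractor (e.g. a self-supervised vision
transformer for appearance and an optical-flow network for motion) is
assumed to have produced, offline, one D-dimensional embedding per frame per
modality, stored in an HDF5 container keyed by video id and modality with a
frame-rate attribute.  Only the adapter seam for such extractors is exposed
(`sais.features.FrameFeatureExtractor`); the extractors themselves are out
of scope.

## Clip classifier

**Frame sampling.**  Gesture clips contribute ten equally spaced frames:
for an n-frame clip, indices k·⌊(n−1)/9⌋, k = 0..9, which pins the first
frame to 0 and reproduces the canonical 90-frame example [0, 9, 18, …, 81];
clips under ten frames fall back to all frames (logged).  Subphase and skill
clips contribute every tenth frame, [0, 10, 20, …].  Motion features pair
each appearance frame with the frame `round(fps · 0.5 s)` later; pairs that
would overrun the clip anchor backwards, and clips shorter than 0.5 s yield
no pairs.  Timestamps are `start_s + index / fps`; all intervals are
half-open `[start, end)` seconds.

**Encoder.**  Per modality, a learnable D-dimensional classification token
is prepended and learned temporal positional embeddings (capacity `max_t`,
default 512; exceeding it is an error) are added to the frame rows before a
post-norm transformer encoder (default 4 layers; 8 heads; feed-forward width
4·D; dropout 0.1 during training only).  Encoder parameters, the token and
the positional table are shared across the two modality streams; the token's
final-layer representation is the modality summary.  Variable-length batches
are zero-padded with a boolean mask; padded keys receive a −10⁹ additive
attention bias, and padded rows are zeroed after the positional addition so
padding can never leak into any summary (verified to 10⁻⁶ under 100 random
padding trials).  The `use_self_attention=False` ablation replaces the
encoder by the mean over valid frame vectors; the single-modality ablations
replace the missing summary by zero.  The two summaries are added
elementwise and projected by Linear(D→E) → ReLU → Linear(E→E), E = 256 by
default.

**Prototype classification and loss.**  C prototypes (one per category,
dimension E) are learned jointly with everything else.  Classification is a
softmax over raw cosine similarities; prediction is the argmax with ties
broken toward the lowest category index.  The training objective is the
prototype InfoNCE summed over the batch with the raw cosine as the logit
(no temperature); the per-sample mean is what the loss curves record.
Optimisation is plain SGD, mini-batch 8, learning rate 0.1, default 50
epochs with the checkpoint chosen by validation loss.  The epoch count and
selection rule are this package's defaults, not inherited choices: the heads
are small and converge within a few epochs on separable data.

The forward and backward passes run on a compact reverse-mode autodiff
engine over float64 numpy arrays written for this package
(`sais._autodiff`); its gradients are held to finite differences at 10⁻⁴
relative tolerance in the test suite, and the InfoNCE value to an
independent brute-force implementation at 10⁻⁹.

**Explanation.**  Frame importance for a clip is the final-layer attention
out of the classification token, averaged over heads and over the two
modality streams, renormalised over valid frames (padded frames get exactly
zero).  The layer/head convention is a package choice; the mean-pooling
ablation has no attention and explanation is refused explicitly.

## Cross-validation and balancing

Splits are Monte Carlo, drawn at the case-video level: each fold
independently samples 10% of videos as test and 10% of the remaining pool as
validation (fold f seeded with `seed + f`), so folds may overlap — they are
repeated resamplings, not a partition — and no clip of a test video is ever
trained on.  Class balancing (on by default for skill-style tasks)
downsamples every category to the rarest category's count, deterministically
given a seed.  Two runs with the same seed produce bit-identical splits and
float-identical loss curves.

## Whole-video decoding

Windows: subphase regime uses 10-s windows sliding by 5 s (approach 1) plus
5-s non-overlapping windows (approach 2); gesture regime uses 1-s
non-overlapping windows; trailing partial windows are dropped.  Outputs are
pooled on 10-s timespans laid on the 5-s grid: an approach-1 window votes on
the timespan sharing its start, a 5-s window on both 10-s timespans that
contain it (the assignment of odd-phase sliding windows to timespans is not
canonical; this grid rule reproduces the three-outputs-per-timespan
accounting and is the package's convention).  With three test-time
augmentations (start-frame offsets 0, 3, 6 at the regime's sampling stride,
overflowing indices dropped) and F folds, an interior subphase timespan
accumulates exactly 3 × F × 3 outputs (90 at F = 10); edge timespans are
averaged over whatever cells exist.  Bagging is the arithmetic mean of the
probability masses — the mean rather than the bare sum, which is equivalent
for the argmax but required for the entropy to be well defined.

Abstention drops a bagged mass whose Shannon entropy (natural log, 0·log 0
= 0) strictly exceeds S_thresh.  The reference threshold 1.74 applies to the
six-category gesture vocabulary it was reported for (ln 6 ≈ 1.792); for any
other C the default is 0.95·ln C, config-overridable and documented as this
package's rule, with thresholds above ln C rejected as unsatisfiable.
Raising the threshold never removes a kept prediction.

Chaining merges same-category predictions: overlaps are unioned, and a gap
(next start − previous end) strictly below the chain gap (3 s subphases,
2 s gestures) merges; different categories never merge and the operation is
idempotent.  The worked retraction example — predictions at 10–11, 11–12 and
15–16 s, gap 2 s — yields exactly two events, 10–12 s and 15–16 s.

**Background handling.**  Pure entropy abstention assumes out-of-vocabulary
stretches produce near-uniform bagged masses.  Measured on this package's
synthetic streams, that assumption fails quietly: every fold maps
zero-signal input to a similar "resting" embedding, so background masses
stay tilted after bagging (background entropy ≈ 0.85–1.10 nats at C = 3
versus ≈ 0.84–0.91 over true events).  The decoder therefore supports an
explicit idle state: when the training vocabulary includes a background
category (`gen_dataset(include_background=True)` provides matching
pure-noise clips), `InferenceConfig.background_category` drops
background-labelled timespans before chaining, with entropy abstention still
active on top.  This is a deliberate design of this package for decodable
synthetic studies; runs without an annotated idle state fall back to pure
abstention and should expect spurious short events in idle stretches.

## Metrics

One-vs-rest ROC AUC per category (trapezoidal, via scikit-learn) with a
macro average; PPV per category, undefined (NaN, warned) when a category is
never predicted; segmental F1@k with k = 0.10 by default: greedy one-to-one
matching of predicted to ground-truth segments of the same category by
intersection-over-union ≥ k, each ground-truth segment claimable once,
F1 = 2·TP/(2·TP+FP+FN) on a 0–100 scale.  The greedy matcher agrees with
exhaustive optimal matching on randomised small cases in the test suite.
Whether segmental F1 should be pooled over videos or averaged per video is
not canonical; the command-line `evaluate` reports both.  Fold summaries are
mean ± standard deviation across folds.

## Outcome association

The skill probability Z1 ∈ [0, 1] of each video sample (optionally averaged
within surgical case — the per-case variant; Z2, Z3 and Y must be constant
within a case) enters a maximum-likelihood logistic model
Y = σ(b0 + b1 Z1 + b2 Z2 + b3 Z3) with Wald 95% confidence intervals; the
reported effect is the adjusted odds ratio e^{b1}.  Perfect or
quasi-separation is detected and refused rather than reported.  The
per-sample variant does not adjust standard errors for within-case
correlation; this mirrors the simplest analysis and is a documented
limitation.

## Synthetic data: what it emulates and what it does not

Each category is a fixed random unit direction μ_c in D-dimensional feature
space (pinned to the config seed); a clip's appearance stream is
snr·μ_c + AR(1) noise (unit marginal variance, coefficient 0.8 by default,
emulating the temporal smoothness of video embeddings), and its motion
stream is ρ·appearance + √(1−ρ²)·independent noise (ρ = 0.7), emulating
correlated but non-identical modalities.  Timelines repeat an ordered motif
(default: the categories in order, mirroring the stereotyped hook → clip →
cold-cut dissection pattern) with uniform durations (2–4 s) and gaps
(2.5–6 s); between events the streams are pure noise.  The default test
dimension is D = 32 (not the full-size 384) to keep runs fast; the
architecture is unchanged by D.  The outcome cohort draws Z1 uniform,
Z2 Poisson (mean 250), Z3 normal (62 ± 8 years) and Y Bernoulli with the
stated linear predictor; the default b1 = 0.27 corresponds to an odds ratio
of about 1.31 per unit of skill probability.

What passing tests on these streams demonstrate: the machinery — masking,
optimisation, ensembling, abstention, chaining, scoring — is correct and
recovers planted structure at the stated signal-to-noise ratios (macro AUC
≥ 0.95 at snr 5; chance at snr 0; ≥ 90% event recovery and segmental F1 > 80
on planted timelines).  What they do not demonstrate: performance on real
surgical video, whose embeddings are not Gaussian, whose classes are not
linearly separated directions, and whose annotations carry human
disagreement.  No claim about real-world AUC/PPV/F1 is made or testable
here.

## Numerical conventions and degenerate inputs

Float64 throughout.  Attention masking uses an additive −10⁹ bias; layer
norm uses ε = 10⁻⁵; cosine norms are ε-stabilised so an exactly zero
embedding (possible for an untrained rectified head) scores zero against
every prototype, while the user-facing `classify` rejects zero embeddings
outright.  Argmax ties break to the lowest category index.  Empty clip
windows, videos shorter than the smallest window, clips shorter than the
flow-pairing span, single-category balancing, conflicting per-case
outcomes, mixed-timespan bagging and thresholds above ln C are all explicit
errors or warnings, not silent behaviour.  Checkpoints serialise the full
parameter set, architecture and category names; reload reproduces
predictions exactly.

## Problem sizes used by the test suite

The suite trains two-layer encoders on D = 32 streams: 400 four-class clips
for the ten-fold recovery study (12 epochs per fold) and 160 clips (three
gestures + background, 15 epochs) for the ten-fold ensemble that decodes a
10-minute timeline; the whole suite runs in a couple of minutes on one CPU
core.  These sizes are the package's chosen study conditions for its
synthetic validation; larger configurations (D = 384, 4 layers, E = 256,
50 epochs) are the library defaults for real-data use.
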