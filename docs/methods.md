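# Methods

This note documents the models, statistics and numerical choices behind
`spncoding`, and what the synthetic-data generator does and does not emulate.

## Scope

The package implements the computational chain from (a) top-down pose tracks
of a freely exploring mouse and (b) deconvolved calcium event rasters of
striatal projection neurons (dSPNs/iSPNs) to population-level encoding and
decoding analyses: unsupervised behavior segmentation over a fixed
12-behavior repertoire, activation-similarity statistics, detection of
behavior-active and behavior-silent cells, one-vs-one SVM decoding with a
behavioral-distance error metric and a time-lagged chance level, and
longitudinal (cross-session) stability analyses.  Upstream steps — pose
network training, calcium source extraction, spike deconvolution, and the
probabilistic cell-registration algorithm — are out of scope; their outputs
are consumed as files.  Omnibus linear mixed-effects modelling is left to
general statistics packages; only the permutation post hoc t-test is
implemented here.

## Posture features

Eight body parts (nose, neck, ears, head-mounted camera, body center, tail
start, tail end) give six per-frame features: body speed (projection of the
body-center velocity on the body-center→neck axis, cm/s), head speed (norm
of the camera-minus-body-center velocity, cm/s), movement angle (signed
angle between the body-center velocities of the previous and subsequent
frame, rad; positive = right turn in image coordinates), body length,
neck elongation, and head elevation (distance from the neck to the
projection of the camera onto the inter-ear axis — a top-down proxy for head
raising, not a true height).  Coordinates with tracking likelihood < 0.9 are
masked, not interpolated; features needing a masked part are masked, and a
20-frame mask-aware moving average smooths each channel.  Velocities are
central differences (one-sided at the ends); whether the original analyses
used central or forward differences and a boxcar or another smoothing kernel
is not documented, so both choices here are ours.

## Behavior segmentation

1. Features are z-scored; a quarter of the valid frames is subsampled
   (capped at `max_embed_frames`, default 3000, a desk-scale choice).
2. t-SNE embeds the subsample in 3 dimensions (validated against the
   smallest PCA dimensionality explaining ≥ 70% variance; a warning is
   raised on mismatch), 10 replicates, perplexity 30.
3. Each embedding is clustered by a full-covariance Gaussian mixture, 50
   random restarts, giving 500 partitions.  The component count is chosen
   per embedding by BIC over 8–30 (scanned in steps of 3): deliberately more
   than 12 classes, so over-segmentation precedes merging.
4. Consensus: average-linkage agglomeration of the frame×frame Hamming
   disagreement (1 − co-assignment frequency), cut at dissimilarity 0.5;
   clusters under 20 frames are dropped.  The agglomeration scheme and cut
   are our choices — only "clustered using the Hamming distance" is given.
5. Clusters are merged in ascending order of their summed per-feature 1-D
   Wasserstein distances until the smallest distance reaches 1.  The cutoff
   is interpreted in z-scored feature units (it is otherwise
   unit-dependent).  Empirical distances use the sorted-sample
   (quantile-integral) form, no binning.
6. Registration to the 12-behavior catalog: an explicit cluster→behavior
   map (emulating manual registration from video) takes precedence; rule
   thresholds on cluster-median features implement the catalog's defining
   criteria otherwise (e.g. body speed > 15 cm/s → locomotion fast;
   camera speed ≈ 0 → immobility).  Grooming is identified by the
   conjunction still + short body + head low + camera moving (or large
   movement-angle variability); pure angle-variability criteria are
   unreliable once features are temporally smoothed, because clusters then
   split by angle value.
7. Every frame is assigned the behavior with maximal likelihood under
   per-behavior full-covariance Gaussians (diagonal regularization 1e-6,
   strengthened with a warning if singular); ties go to the lower behavior
   id.  A kernel-density likelihood was considered and rejected for speed;
   the Gaussian model is sufficient for well-separated repertoires.
8. Post-processing: episodes shorter than 4 frames (100 ms at 40 frames/s)
   are removed; unlabeled runs are split half/half to the neighboring
   behaviors (odd gap: extra frame to the preceding behavior; edge runs take
   their single neighbor), iterated to closure.

## Annotation metrics and the permutation t-test

Per-class one-vs-rest accuracy (TP+TN)/N, precision, recall and
F1 = 2PR/(P+R); undefined 0/0 ratios are reported missing and skipped by the
equal-weight macro average.  Majority classification keeps the modal class
when it reaches at least 50% of votes and is a unique mode; exact two-way
ties are discarded.  The permutation t-test permutes group labels, uses the
pooled-variance t, and reports the two-sided p with the observed labelling
counted in numerator and denominator, so p is never exactly 0 — a p of 0
from a finite permutation set would overstate the evidence.

## Activation similarity and behavioral distance

The activation map of a behavior is the vector of per-neuron mean
deconvolved activity (events/s) over the behavior's frames in a window;
windows sampling the behavior for less than 5 s are excluded.  Similarity
between maps X1, X2 is −‖X1/‖X1‖ − X2/‖X2‖‖ ∈ [−2, 0] (0 iff positively
proportional, −√2 for orthogonal, −2 for anti-parallel); the cosine form is
provided as the alternate metric.  Partitions: session halves, all 10
balanced splits of six 5-min slices, odd/even frames, alternating episodes;
the chance level is the mean over 10 neuron-index permutations of X2.
Behavioral distance between behaviors = sum over the six features of 1-D
Wasserstein distances between their empirical feature distributions;
behavioral similarity is its negative; the neural–behavioral coupling is the
Spearman correlation over the 66 behavior pairs.

The inverse coefficient of variation across episodes is not precisely
defined in the source description (per-neuron vs ensemble); the default
computes each neuron's episode-rate mean/SD and averages over neurons with
defined CV, with an `ensemble` switch for the alternative.

## Behavior-active, behavior-silent, behavior-inactive cells

Behavior information (bits/event) is BI = Σᵢ pᵢ (fᵢ/f) log₂(fᵢ/f), with pᵢ
the occupancy of behavior i, fᵢ the cell's rate in it, f its overall rate;
algebraically BI = Σᵢ qᵢ log₂(qᵢ/pᵢ), a KL divergence between the event
distribution over behaviors (qᵢ) and the occupancy distribution — the form
the implementation evaluates (0·log 0 = 0; BI undefined for a cell with no
events).  Note that BI equals the *positive-response term* of the plug-in
mutual information between a binarized event indicator and the behavior
label divided by the mean event probability; it is not the full mutual
information.

Significance: 1000 shuffles of the event train; a cell is behavior-active
when BI exceeds the shuffle mean by > 4 shuffle SD.  The default shuffle is
a uniform frame permutation (matching the stated procedure); a circular-
shift option preserves autocorrelation.  The population routine applies the
same label shuffles to all cells at once (each cell's marginal null is
exact; nulls are correlated *across* cells, which affects no per-cell
decision).  A per-behavior variant compares each behavior's event count to
its shuffle distribution with the same one-sided 4-SD rule, excluding
behaviors sampled under 5 s.

Activation occurrence is the fraction of a behavior's episodes containing at
least one event (any positive deconvolved amplitude counts; no minimum
episode duration is applied).  Behavior-silent: occurrence < 0.025 (strict).
Behavior-inactive: in-behavior rate < 0.1 events/s (strict).  The shuffle
variant flags a cell silent when its occurrence falls below the 2.5th
percentile of circular-shift occurrences; a cell with no events at all
(percentile 0, occurrence 0) is flagged by convention.

Longitudinal stability is the Jaccard index of (neuron × behavior) binary
attributes across registered cell pairs.  Controls: random re-pairing
(derangement) of registered cells, and replacement of each session-B cell by
its nearest neighbor by centroid.

## Decoding

Rasters are convolved with a 500-ms square window (10 frames at 20 frames/s,
centered, summing).  The 12-class problem is decomposed into 66 one-vs-one
linear SVMs; prediction is by pairwise vote, ties to the lowest behavior id.
The 80/20 train/test split is a contiguous random block by default — a
frame-random split (also available) leaks information across the split
through the 500-ms convolution; this choice is documented prominently
because the original split type is unspecified.  Per-neuron z-scoring uses
training frames only.  Regularization: 5-fold CV over the logarithmic grid
C ∈ {0.01, 1, 100}; the CV stage runs on at most 500 frames per pair and the
winning C is refit on the full pair training set (at most 1500 frames,
subsampled beyond that); liblinear runs primal with tol 1e-2, max 400
iterations.  These caps are desk-scale speed/accuracy tradeoffs and are all
configurable.

Reports carry the test-bin accuracy, the behavior reconstruction error
(mean behavioral distance between predicted and observed behavior, 0 on
correct bins), per-behavior one-vs-rest simple matching coefficients, and
per-pair accuracies.  The chance level reverses the label series, applies a
cyclic shift with |lag| > 30 s, retrains the full decoder on the lagged
labels and scores it against the original labels, averaging 10 random lags.
Subset decoding discards sessions with fewer than 40 behavior-active or 20
behavior-silent/-inactive neurons (strict).  Longitudinal decoding trains on
session A restricted to registered cells (columns ordered by the registry)
and tests on session B, requiring at least 40 registered cells.

## Synthetic sessions

The generator plays the role of the unavailable recordings; its defaults are
the study conditions used by the tests and the acceptance script.

* **Labels**: first-order Markov chain at 40 frames/s, geometric dwell times
  (mean 2 s — episode statistics beyond an episode-duration histogram are
  not published, so this is a stated default, not a fit), uniform
  off-diagonal transitions; all 12 behaviors recur.
* **Features**: per-behavior Gaussians whose means follow the catalog's
  defining criteria (e.g. locomotion fast at 22 cm/s); noise is temporally
  correlated over 20 frames (unit marginal variance), emulating smoothed
  features.  Head speed is truncated at 0.  Turning behaviors carry head
  speeds near (neck+head offset)·angular rate, keeping the feature set
  kinematically consistent.
* **Pose**: an explicit inverse of the feature computation — heading
  integrates half the movement angle per frame (stable smoothed recursion),
  the body center integrates body speed along the heading, body parts sit at
  the feature-dictated offsets, and a bounded lateral camera wiggle is
  solved per frame to realize the head-speed target.  Round-trip MAE at
  defaults: body/neck lengths exact; movement angle < 0.03 rad; body speed
  < 0.5 cm/s; head elevation < 0.3 cm; head speed < 3 cm/s (it floors at
  the kinematic minimum during sustained turns and grooming).  A 5% fraction
  of frames gets one body part with likelihood < 0.9 for filter testing.
* **Rasters**: inhomogeneous Poisson at 20 frames/s (labels aligned by
  taking every second behavior frame).  Defaults: 300 neurons, 30-min
  sessions, baseline 0.5 events/s; 10% planted behavior-active cells (rate
  gain 5 in their behaviors), 10% planted behavior-silent cells (rate 0 in
  their behaviors); each tuned cell prefers a behavior and its 2 nearest
  neighbors in ground-truth feature space, so similar behaviors recruit
  overlapping ensembles — the substrate of the neural–behavioral coupling.
  Episode-to-episode variability is a lognormal (mean 1, sd 0.5) gain per
  (tuned neuron, episode); untuned cells are homogeneous Poisson, keeping
  the permutation null calibrated for them.  Pathway presets: "dSPN-like"
  (18% active, 8% silent, gain sd 0.3) vs "iSPN-like" (14% active, 18%
  silent, gain sd 1.0) — chosen so both pass the 40-active/20-silent subset
  thresholds while reproducing activation-biased vs silencing-biased coding
  and low vs high episode variability.
* **Session pairs**: a rounded fraction of cells (default 0.34) is shared,
  optionally with a fraction of shared cells' assignments redrawn; centroids
  support the closest-neighbor control.
* **Perturbation**: per-neuron circular time shifts destroy behavior locking
  while preserving rates and autocorrelations.

What the generator does **not** emulate: calcium indicator dynamics,
deconvolution artifacts, imaging noise and motion, non-Markovian behavioral
sequencing, drift in tuning, correlated population noise beyond the episode
gain.  Passing tests therefore demonstrate correctness and calibration of
the analyses under these idealized conditions, not performance on real
recordings.

## Problem sizes and determinism

Analyses in the test suite and acceptance script run at desk scale chosen to
finish comfortably on one CPU: 30-min sessions for parameter recovery,
15-min sessions with 150 neurons for decoding calibration, 15-min sessions
with the embedding subsample capped at 3000 frames and 4 t-SNE × 10 GMM
replicates for segmentation recovery (the pipeline defaults remain 10 × 50).
All stochastic stages take seeds (NumPy `default_rng`); fixed seeds
reproduce results bit-for-bit at fixed library versions.

## Known limitations

* The consensus step materializes an n×n co-assignment matrix — fine to
  ~10k subsampled frames, not beyond.
* Rule-based cluster registration assumes the cluster medians reflect one
  behavior; heavily mixed clusters raise an explicit unregistered-cluster
  error and should be resolved with a manual map.
* The time-lagged null retrains one decoder per lag; its cost dominates
  decoding analyses.
* BI significance shared-shuffle batching correlates nulls across cells;
  joint statistics over cells (e.g. counts of co-active cells) should use
  per-cell independent shuffles.
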