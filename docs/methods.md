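# Methods

`dfcstates` implements a complete analysis chain for asking whether a brain's
spontaneous activity shows the dynamic signature of consciousness: a rich,
flexible repertoire of functional-connectivity (FC) states, versus the rigid,
anatomy-locked configuration typical of anesthesia. It also implements the
accompanying EEG spectral markers of anesthetic depth and exact generators
for the stimulation and auditory-oddball paradigms used in such experiments.

## Dynamic FC and brain states

**Windowed connectivity.** Each session is an ROI-by-scan matrix (82 regions,
500 scans, TR 1.25 s by default). A sliding window of 35 scans (step 1)
moves across the run; within each window the signals are demeaned, tapered
with a Hamming window, and correlated pairwise. Correlations are clipped to
|r| <= 1 - 1e-6 and Fisher-transformed, z = atanh(r), giving one symmetric
z-matrix per window.

*Boundary convention.* The count of feasible width-35 placements in 500
scans is 466; this package deliberately discards the first and last
placement, giving N - w - 1 = 464 windows per 500-scan session, the window
count the downstream bookkeeping assumes. The convention is fixed in
`sliding_windows` and exact for every (N, w, step).

*Why correlation before atanh.* The Fisher transform is only bounded for
correlations, so each window computes the Pearson correlation (tapered
covariance normalized by tapered standard deviations) before the transform.
Zero-variance ROIs within a window yield zero correlations plus a warning
rather than an abort.

**Clustering.** Windows from *all* conditions and sessions are pooled and
vectorized (strict upper triangle, d = 3321 features for 82 ROIs), then
clustered into k = 7 states with k-means under the Manhattan (L1) metric.
The centroid update consistent with the L1 objective is the component-wise
median (k-medians); the implementation asserts a nonincreasing total L1
deviation at every Lloyd iteration and repairs empty clusters by reseeding
them with the point farthest from its assigned centroid.

*Initialization.* Windowed-FC features are an extreme clustering regime:
within-cluster spread (estimation noise across ~3300 coordinates) is several
times larger than the distance between cluster centers. Point-based seedings
(k-means++ and variants) almost never land one seed per true state there and
Lloyd stalls in shallow basins. The default initialization therefore finds
the partition in the top-20 principal-component subspace — where the state
structure is well conditioned — using many cheap L1 k-means restarts, and
then refines the few best subspace partitions on the full features with L1
Lloyd, keeping the lowest full-data inertia. Greedy L1 k-means++ seeding
remains available (`init="++"`) and is the default for small problems; on
well-separated data the two routes agree, and on tiny instances the result
matches the exhaustive-partition optimum (verified in the test suite).

**Ranking by structure-function similarity.** Each state centroid is scored
by the Pearson correlation between its strict upper triangle and the
corresponding structural-connectome weights (structural zeros retained;
constant matrices score 0 with a warning). States are relabeled 1..k in
ascending similarity: state k is the most anatomy-like. Ties are broken by
cluster size (larger first), with a warning. Similarity is computed on raw
weights rather than binarized structure; the functional is pluggable if a
different variant is preferred.

**Statistics.** Within each session, occupancy (the probability of
occurrence of each state) is regressed on state similarity by OLS; the slope
is the headline statistic. Anesthesia concentrates occupancy on
structure-like states (large positive slope); wakefulness spreads it (slope
near zero). Slopes are compared across conditions with a classical
equal-variance two-sample t test (Welch by flag) and a JZS Bayes factor with
Cauchy prior scale sqrt(2)/2 (the conventional default; the analysis that
motivated this package states no prior). BF10 > 3 is read as strong
evidence. Slopes are fitted per session, since the group comparison needs
session-level replicates; similarity *values* (not ranks) are the regressor.
State durations use maximal-run decomposition; z-value histograms use 45
bins over a range shared across the states being compared; the z-vs-distance
histograms use Euclidean inter-ROI distances from the 3-D coordinates.

## Synthetic resting-state generator

No public recordings accompany the analysis this package operationalizes, so
the generator is the test bed. It emulates the acquisition geometry (82
ROIs, 500 scans, TR 1.25 s, 7 states) and the statistical premise of the
method: recurring windowed-FC patterns driven by a latent state sequence.

* **Connectome.** ROI coordinates on a jittered spherical shell (mean radius
  30 mm); edge weights follow an exponential distance rule (length constant
  20 mm) with log-normal variability, sparsified to the requested density
  with a minimum-spanning-tree guarantee of connectedness.
* **Templates.** State i's covariance is the convex blend
  m_i·C_struct + (1-m_i)·C_rand_i. The default mixing grid tiles [0, 0.75]
  at gaps of 0.15 and places the final, fully structural template at 1.0;
  the widest gap sits at the top because that pair's difference involves
  only one random component (the m = 1 template has none), making it
  otherwise the least distinct pair. C_struct is the correlation matrix of the
  spectral-norm-normalized structural weights plus the smallest ridge from
  {1e-6..1e-1} (after an eigenvalue shift) that gives positive definiteness;
  the ridge used is recorded on the template. C_rand_i is a template-specific
  random correlation matrix built from ~n/10 latent factors, so its
  correlations are strong (sd ~0.3), matching the network-dominated
  covariance of real resting-state FC — full-rank Wishart draws would give
  correlations too weak for the states to be distinguishable at realistic
  window lengths. Construction retries (fresh random components) until the
  structure similarity is strictly increasing across templates.
* **Latent dynamics.** A sticky first-order Markov chain with transition
  matrix P = p·I + (1-p)·1·pi^T, whose stationary distribution is exactly the
  requested occupancy profile pi for any profile. The stickiness is
  calibrated as p = 1 - 1/(D·(1-1/k)) so that under a uniform profile every
  state's expected dwell time equals D scans exactly. The default D = 25
  scans (~31 s at TR 1.25 s) reflects the tens-of-seconds persistence of
  windowed-FC states while keeping a 500-scan session long enough (~20 state
  visits) for its occupancy to be informative.
* **Observations.** Zero-mean multivariate Gaussian draws from the active
  template's covariance plus isotropic noise (sd 0.25).
* **Condition profiles.** `default_occupancy_profiles()` encodes the study
  conditions: awake = uniform (full repertoire), anesthesia = 50% occupancy
  of the most structure-like state with the remainder tilted toward high
  similarity, and a DBS-restored condition that is near-uniform with a mild
  residual tilt. Clustering always pools all conditions, which also keeps
  the pooled state sizes balanced enough for the partition to be
  identifiable.

What the generator does **not** model: hemodynamics (no HRF, no volumetric
images), physiological noise structure (cardiac/respiratory), scanner drift,
head motion, inter-subject anatomical variability, and any coupling between
the EEG and fMRI generators. Passing tests therefore demonstrate that the
analysis recovers the constructs it defines under its own statistical
assumptions — not that it is robust to every nuisance in real recordings.

**Recovery is measured against the realized latent path.** The ground truth
for a window is the majority latent state among its 35 scans; occupancy
recovery compares pipeline occupancy to the occupancy of these realized
window labels. (Comparing to the *requested* profile would conflate pipeline
error with the sampling variability of a sticky chain at 500 scans, which is
substantial and not a property of the analysis.) Windows that straddle state
transitions are intrinsically ambiguous — near-50/50 mixtures sit halfway
between two templates — which bounds attainable label agreement a few
percent below 100%.

## EEG markers

* **Gradient-artifact removal.** Average-artifact template subtraction: the
  recording is segmented on the artifact period (default 1.25 s, the TR);
  each occurrence's correction template is the inclusive sliding average of
  the 21 surrounding occurrences (truncated at the edges; global template
  with a warning when fewer than 21 periods exist). Occurrence and template
  are both baseline-corrected over the first 200 ms before subtraction. A
  perfectly periodic artifact cancels to machine precision; for signals
  uncorrelated with the artifact period the template tends to the sliding
  signal mean, costing ~1/21 of signal amplitude.
* **Preprocessing.** Zero-phase Butterworth band-pass (order-6 high-pass at
  1 Hz and order-8 low-pass at 25 Hz sections, forward-backward, i.e.
  effective orders 12 and 16), polyphase resampling to 250 Hz, trimming of
  15 s at each end, and average-reference (per-sample channel-mean
  subtraction).
* **Epoching.** 0.8-s epochs whose onsets advance by i.i.d. Uniform(0.55,
  0.85) s jitters, seeded. Because the gap can be shorter than the epoch,
  consecutive epochs may overlap; this onset-to-onset reading of the jitter
  is a deliberate disambiguation and is logged in the epoch onsets.
* **Spectral markers.** Welch PSD (Hann, 1-s segments, 50% overlap,
  zero-padded to a bin width <= 0.5 Hz; all parameters in
  `SpectralConfig`). Normalized band powers for delta (1-4), theta (4-8) and
  alpha (8-13 Hz) over the 1-25 Hz total band, with half-open band edges so
  a tiling set of bands partitions the power exactly. Spectral entropy
  SE = -sum p log p / log(n_bins) on the normalized 1-25 Hz PSD (1 for a
  flat spectrum). Median spectral frequency by linear interpolation of the
  cumulative trapezoidal power integral. Closed-form checks (SE on a pure
  tone, band-ratio recovery) are run with longer Welch segments than the
  0.8-s default, since at 0.8 s the spectral resolution — not the marker
  definition — dominates the error.
* **Group comparison.** Two-sided Mann-Whitney U per marker (all-tied data
  gives p = 1 with a warning), Benjamini-Hochberg FDR step-up across the
  marker family, significance at adjusted p < 0.05.

The EEG generator sums band-limited Gaussian noise components (order-8
Butterworth band-pass, forward-backward; unit RMS per component) with
requested amplitudes, so true relative band powers are known exactly; the
optional scanner artifact is an exactly periodic decaying-oscillation burst
scaled to a requested artifact-to-signal RMS ratio.

## Paradigm schedules

All schedule arithmetic is integer-exact. The DBS block design is 50 TR
baseline plus five cycles of (5 TR ON + 50 TR OFF) = 325 TR, ON onsets at
TRs 51, 106, 161, 216, 271. Pulse trains default to 130.208 Hz (period
7.68 ms), monopolar, pulse count floor(duration/period). The local-global
run is 6 TR rest + 5 x (15-TR series + 6 TR rest) = 111 TR at TR 2.4 s; each
series is 4 habituation trials plus 20 post-habituation trials containing
exactly 4 global deviants at seeded uniform positions (no adjacency
constraint — none is specified for the original design; a constraint hook
can be added at `make_series`). Each trial is five 50-ms tones at 150-ms
onset asynchrony (650-ms sound span) in a 1500-ms footprint; 24 trials tile
the 15-TR series block exactly (24 x 1500 ms = 15 x 2400 ms), validated at
construction. Habituation trials repeat the block's global-standard pattern.
The clinical arousal exam sums six items (five 0-2 items plus corneal reflex
0-1) to a 0-11 score.

## Numerical choices and degenerate inputs

* Correlation clipping at 1 - 1e-6 bounds |z| at atanh(1 - 1e-6) ~ 7.25.
* k-means tolerance 1e-6 relative inertia change, max 300 iterations,
  default 20 restarts; ARPACK SVD for the PCA subspace uses a fixed start
  vector so results are bit-reproducible for a given seed.
* OLS slope via `scipy.stats.linregress`; the all-equal-similarity regressor
  raises (undefined slope) rather than returning 0.
* Occupancy rows, histogram masses and band-power partitions are normalized
  and asserted to sum to 1; empty positive/negative z sets in epoch
  summaries are reported as 0 with an explicit empty-set flag.
* Degenerate chains (one-hot profiles) and k = 1 clustering are supported.

## Problem sizes

The acceptance run and the heaviest tests use the defaults above — 4
sessions x 500 scans x 82 ROIs per condition, 464 windows per session,
pooled k = 7 clustering — which the package analyses end-to-end in a few
tens of seconds on a single core; statistical checks with brute-force
oracles run on deliberately tiny instances (<= 10 points, n = 3 + 3) where
exhaustive enumeration is exact.

## Known limitations

* The structure-function similarity functional is one defensible reading
  (Pearson on raw upper triangles); ranking could differ under binarized or
  log-scaled structural weights.
* k is fixed at 7 by design; no model-order selection is provided.
* The k-medians objective can genuinely prefer splitting one very large
  state over separating two similar rare states when occupancy is extremely
  unbalanced; the pooled multi-condition design keeps state sizes in the
  identifiable regime.
* Bayes factors come from `pingouin`'s JZS implementation; only the
  two-sample location test is wrapped.
* The EEG path does not model or correct ballistocardiogram artifacts, bad
  channels, or source geometry.
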