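# Methods notes

This note records the modelling assumptions, parameter conventions and
numerical choices behind `megrsa`, in the spirit of a methods appendix: it
states what the code computes and why each open design decision was
resolved the way it was. No empirical claim here goes beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Synthetic data model

**Design.** The generator reproduces the factorial structure of the
experiment: 2 (size) × 2 (clutter) × 2 (contrast) × 2 (luminance) ×
n exemplars (3 by default → 48 conditions), with condition ids dense and
ordered deterministically (factors slowest-to-fastest, exemplar fastest).
Trials are assigned to runs cyclically, so 60 trials per condition over 15
runs reproduces 4 presentations per image per run.

**Signal.** Each injected effect ties a multivariate pattern to a factor
level (or to each individual condition, for "identity" effects). Patterns
are unit-norm Gaussian random vectors over channels, drawn once per
(factor, level) from a fixed pattern seed; each subject receives a jittered
copy (`p + σ_j·ε`, renormalized, σ_j = 0.2 by default), so the group shares
a code without duplicating it. The temporal envelope is a half-cosine ramp
up from onset to peak and down from peak to offset: simple, smooth, and
with an unambiguous ground-truth onset and peak for parameter recovery.
Amplitudes are in fT against the noise scale below; effects used in the
recovery tests (200–250 fT against 100 fT noise SD) produce clustering
effects of roughly 10–40 percentage points, comfortably detectable at 8
subjects yet far from ceiling-trivial at the single-pair level.

**Noise.** Sensor noise is Gaussian with a low-rank-plus-diagonal channel
covariance `scale²·(I + UU')` (rank 5 by default) — a few strong shared
components over an independent floor, mimicking the dominant-subspace
structure of MEG sensor noise without a forward model — followed by AR(1)
filtering along time (coefficient 0.8 **per sample**, innovation variance
scaled to keep the marginal variance constant). The AR coefficient is a
per-sample convention: the desk profile (5 ms steps) is therefore somewhat
less temporally correlated in real time than the full profile (1 ms); both
are configurable.

**Scale profiles.** `desk` (30 channels, 5 ms, 20 trials/condition,
8 subjects, 200 permutations/bootstraps, reduced decoding repetitions)
completes in minutes and is what the tests, the analysis drivers and the
acceptance script use; `full` mirrors the recording-scale constants
(306 channels, 1 ms, 60 trials, 15 subjects, 100 repetitions, 1000
permutations/bootstraps). Eight subjects is the smallest group for which
the exhaustive sign-flip null (2⁸ = 256 assignments) resolves two-sided
p-values well below 0.05.

**What the generator does not emulate.** No sensor geometry or forward
model (patterns are random, not dipolar), no eye/muscle artifacts beyond
single-sample spikes, no inter-trial drift or adaptation, no 1/f spectrum,
and the "images" are random textures rather than scene photographs.
Passing recovery tests therefore validate the *analysis machinery* —
calibration, latency recovery, generalization logic — not claims about
real cortical dynamics.

## Stimulus statistics

The experimental images were adjusted so that the two contrast levels have
RMS values 34% and 50% and the two luminance levels 34% and 51%. The exact
formulas behind those percentages are not published, so the package fixes
its own conventions:

* RMS luminance = `sqrt(mean(I²))` of intensities in [0, 1], in percent of
  full scale;
* RMS contrast = `std(I)/mean(I)` in percent (relative RMS contrast).

The relative definition for contrast is deliberate. If contrast were the
absolute SD in percent of full scale, three of the four contrast×luminance
cells would be unreachable for in-range images: SD = 0.50 with
RMS = 0.51 forces mean 0.10, but the maximum SD of a [0,1] variable with
mean 0.10 is 0.30; SD = 0.34 with RMS = 0.34 forces mean 0. With the
relative definition, the implied moments (`μ = rms/√(1+c²)`, `σ = c·μ`)
are comfortably interior for all four cells, and the generator hits every
target to machine precision before the 0.5-percentage-point tolerance even
matters. Images are smooth Gaussian random textures (tanh-squashed to
bound the tails) mapped affinely to the target moments, with re-projection
after any clipping.

## Decoding

**Classifier.** Linear soft-margin SVM with C=1 (libsvm). No feature
scaling beyond the preprocessing z-score — the baseline normalization is
the only standardization, matching the analysis convention. Decision ties
(exactly zero decision value) go to the first class, deterministically.
The hot path calls scikit-learn's bundled libsvm binding directly (~35 µs
per 6-sample fit instead of ~2 ms through the estimator API); the test
suite asserts exact agreement of decision values and predictions with
`sklearn.svm.SVC(kernel="linear", C=1)`, and a fallback to the public
estimator exists if the binding is unavailable.

**Pairwise scheme.** Per repetition, each condition's raw trials are
randomly partitioned into groups of k=5 and averaged (pseudo-trials);
`M mod k` leftovers are discarded for that repetition — a fresh random
assignment each repetition recycles all trials in expectation, and the
reference trial counts (60/5) divide exactly anyway. Cross-validation
holds out **one pseudo-trial per class** per fold (folds = pseudo-trial
count); accuracy is averaged over folds and repetitions and written
symmetrically into (i, j) and (j, i); the diagonal is NaN and excluded
from every downstream mean. Time points are processed independently, so a
configurable decimation (`time_decim`) trades latency resolution for
runtime at desk scale without changing any per-timepoint computation.

**Cross-classification.** Trials are pooled across all images sharing the
target and generalization levels, sub-averaged with k=60, the classifier
trained on all pseudo-trials of one generalization level and tested on the
other; the reversed assignment is computed and the two directions
averaged. The identity variant trains on exemplars {1, 2} of every factor
combination and tests on exemplar 3 (then the reverse); the held-out
exemplar index is fixed rather than randomized, which keeps runs
reproducible and is immaterial under the generator's exchangeable
exemplars.

A caution that the null-control tests encode: with a *finite, fixed*
stimulus set, exemplar-specific response patterns that are shared across
subjects project consistently onto the classifier axis, so cross-exemplar
"generalization" can sit slightly but systematically off chance even
without any factor-level code. The package's negative-control fixtures
therefore use subject-idiosyncratic identity patterns; with real data the
analogous caveat applies to stimulus-locked confounds.

## RDM statistics

All RDM comparisons vectorize the strictly lower triangle (the matrices
are symmetric, the diagonal undefined). Correlations are Spearman with
average ranks on ties. Multi-layer models are compared layer-by-layer and
the per-layer correlations averaged arithmetically; per-layer curves
remain available. The partial correlation is computed on ranks: rank-
transform target, brain and nuisance vectors, residualize brain and target
ranks on the nuisance ranks (plus intercept) by least squares, correlate
the residuals. Rank-deficient nuisance sets are handled by the
least-squares pseudoinverse (logged); a vector fully explained by the
nuisance set returns a partial correlation of 0 by convention rather than
amplifying rounding noise. The clustering statistic (between-level minus
within-level mean) is the same contrast as the binary-model Spearman
correlation up to the data's variability; their signs agree except within
rounding of zero.

## Feature models

**GIST.** Images are resized to 128×128 and filtered in the Fourier domain
with 32 analytic Gabor transfer functions (8 orientations × 4 scales,
center frequencies 0.32/2ˢ cycles/pixel, one-octave radial bandwidth); the
response magnitude (local oriented energy) is averaged in a 4×4 grid,
giving 512 dimensions. Every filter's DC bin is zeroed exactly, so the
descriptor is invariant to constant intensity shifts; a 90° image rotation
permutes orientation channels and remaps grid cells, which the tests check
against an explicit permutation oracle (up to the Nyquist-bin asymmetry of
even-sized FFT grids).

**HMAX.** Four layers: S1 (rectified spatial Gabors, 4 orientations × 4
sizes), C1 (max over paired scales, local spatial max-pool with stride),
S2 (Gaussian radial-basis similarity to a dictionary of C1 patches sampled
from generator images with a fixed seed; 100 patches by default), C2
(global max per patch). For RDM purposes S1/C1 are summarized on coarse
spatial grids — raw maps would make the RDM an image-alignment detector —
while S2 keeps per-band maxima and C2 is the standard global vector.

**Activation tables.** Deep-network features are not computed here;
`load_activation_features` ingests a long-format CSV (condition_id, layer,
f0…fN), realigns rows to the design regardless of file order, and feeds
the same RDM machinery, so any externally computed model slots in.

## Inference

Per-timepoint two-sided empirical p-values come from the permutation
distribution of the sign-flipped group mean at that time point (pooling
over permutations only, not over time). Candidate clusters are maximal
runs of p below the cluster-definition threshold, positive and negative
effects tracked separately; the null distribution of the maximal cluster
size is built from the same permutations (each permutation's p-values
computed against the full permutation set, ties counted as
greater-or-equal), and a cluster's p-value is the fraction of null maxima
at least as large. Random sign assignments use the plus-one convention
(p never 0); when 2^subjects ≤ n_perm the full sign grid is enumerated
instead, which includes the identity assignment and makes the test exact.
With time-constant group effects the cluster-size statistic saturates:
every sign assignment whose pointwise p clears the threshold forms a
full-window cluster, so the smallest attainable cluster p is the
suprathreshold count over the number of assignments (12/256 at 8 subjects
and α=0.05), not 2/256 — the tests document this degenerate case.

Bootstrap CIs resample subjects with replacement (never trials), rerun the
full cluster test per sample, and take 2.5/97.5 percentiles. Onset is the
first time point of the earliest significant cluster; samples without any
significant cluster are excluded from the onset distribution and counted.
Peak latency is the global argmax of the group mean within the
post-stimulus window by default — a config switch restricts it to
significant clusters, since either reading of "peak" is defensible.
Peak-to-peak latency difference tests resample subjects jointly for both
time courses and call the difference significant when the 95% CI excludes
zero.

Label-permutation tests for model↔model RDM correlations permute rows and
columns simultaneously (a condition relabeling), two-sided on |ρ|, with
the plus-one convention; FDR across model comparisons is
Benjamini–Hochberg via statsmodels.

## Problem sizes used by tests and the acceptance script

Calibration and recovery run at desk scale as a deliberate design point:
48-condition null calibration uses 4–8 subjects with 2 decoding
repetitions and a 50 ms latency grid (the decoding problem is independent
across time points, so the coarser grid changes nothing but resolution);
onset/peak recovery uses the 16-condition design at a 10 ms grid, where
the tolerance of smoothing window + 2 sampling steps (30 ms) is the
honest resolution limit of the chain; the FWER calibration simulates 200
null experiments of 8 subjects × 200 time points with 500 permutations.

## Known limitations

* The exhaustive sign test cannot reach p < 0.05 below 6 subjects; desk
  configurations with 4 subjects run but cannot produce significant
  clusters — by construction, not by bug.
* Soft-margin SVM decisions are invariant to channel permutations and
  orthogonal channel mixing (the linear kernel is unchanged), but not in
  general to arbitrary invertible rescalings, which alter the effective
  regularization; the tests assert the orthogonal-family invariance.
* Cluster-size inference is insensitive to short, strong effects by
  design; single-timepoint effects at a coarse latency grid can be missed.
* No noise-ceiling estimation, weighted/regression RSA, temporal
  generalization matrices, or sensor-space (spatial) clustering.
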