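# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests demonstrate.

## Data model

All analyses run on a `TimePointDataset`: per subject a T × V matrix of
task time points by voxels, a length-T stimulus label sequence shared by
every subject (temporal alignment: the m-th time point shows the same
condition for everyone), a per-subject diagnostic group label, and a map
from atlas region id to its column slice. Voxels within a region are
ordered by ascending flattened index with the x axis varying fastest, so
models are bit-reproducible.

**Time-point extraction.** A volume's acquisition time is the middle of
its repetition interval, t_i = (i + 0.5)·TR (TR = 2 s). A volume belongs to
a task block when t_i − lag falls in the half-open block interval
[onset, onset + duration); the hemodynamic lag defaults to 4 s and shifting
it by one TR shifts every selected index by exactly one. Fixation volumes
are excluded. Real acquisitions may yield a different T than the 35 the
synthetic design is tuned to; nothing downstream assumes 35 beyond the
oddness that makes binary majority votes tie-free.

**Standardization.** Each voxel is z-scored against its own full-run
statistics (task *and* fixation volumes), then the task rows are extracted.
Standardizing within the task window alone would remove any block-level
activation difference — the very signal of interest — because a constant
shift across all task time points has zero within-window variance.
Zero-variance voxels standardize to zeros rather than raising, so masks
with dead voxels survive. For multi-run subjects each run is standardized
against itself, which absorbs run-level offsets and scanner drifts in mean
level.

## Synthetic cohorts

The generator emulates a two-group pediatric face-processing study:
23 control and 22 anxious subjects, a 12×12×12 volume carved into 20
regions of 40 voxels (remainder background), and a block-design face task.
Per subject and signal-region voxel, task volumes receive

* a **group effect**: a mean shift of `group_effect` noise-SD (default 2)
  for anxious subjects only, at every task volume — a sustained
  task-activation difference relative to fixation baseline;
* a **stimulus response**: W_i s_c, where s_fear ⊥ s_anger are drawn once
  per cohort with per-voxel RMS `stim_effect` (default 2) and W_i is a
  fresh random orthonormal V×k map per subject (k = 3). Sharing s across
  subjects while individualizing W is exactly the assumption the shared
  response model exploits: within-subject stimulus structure is strong,
  but raw voxel patterns do not transfer across subjects;
* optional **coupled regions**: a per-subject latent series added to the
  seed region and a configurable set of others (`coupling` = 0.5 noise-SD
  per voxel), sized to give group-mean region correlations well above the
  0.6 reporting threshold;
* i.i.d. Gaussian noise (SD 1) everywhere, on a baseline of 100.

Data is generated and stored as float32, so a disk round trip reproduces
the in-memory matrices exactly. All randomness derives from one root seed
through named `SeedSequence` child streams (design, shared responses, one
stream per subject), making partial regeneration stable.

**Block layouts.** `make_block_design` defaults to the acquisition
protocol: two runs, each 16 s lead/trail fixation and six 15-s task blocks
(three fear, three anger, order seeded-random) separated by 12-s fixation —
182 s per run. At TR 2 s and 4 s lag that layout yields 90 task volumes per
subject, not 35, and the design matrix that produced the study's 35 aligned
samples is not derivable from the protocol alone. The cohort default is
therefore a "compact" layout: one run, 16 s lead/trail, five 15-s task
blocks separated by 13-s fixation. The 13-s gap keeps every onset on an
even second, so each block contributes exactly 7 mid-volume samples and
extraction yields exactly T = 35. With five blocks the conditions split
3/2 (21 vs 14 time points, seeded order) — as balanced as an odd block
count allows. Because the label sequence must be identical across subjects
(the temporal-alignment premise), the block order is randomized once per
cohort, not per subject.

**What the generator does not emulate:** hemodynamic convolution and
undershoot, physiological and motion artifacts, scanner drift, spatial
autocorrelation, anatomical variability in region size. Passing tests
demonstrate that the pipeline recovers the structure it assumes when that
structure is present and stays calibrated when it is absent — not that the
real effects exist or that preprocessing of real data is adequate.

## Region super learner

The primary model treats the atlas region (the feature subset) as a
hyperparameter alongside the AdaBoost/logistic grid
(n_estimators ∈ {10, 50, 100, 150}; learning_rate ∈ {0.05, 1, 2};
max_iterations ∈ {100, 500, 1000}; penalty ∈ {L1, L2, none};
C ∈ {0.5, 1, 2}). `max_iterations` caps the weak learner's optimizer;
boosting rounds are `n_estimators`. Folds are always split by subject id —
a subject's time points never straddle a train/test boundary — and outer
folds are stratified by group. Inner folds score configurations by
subject-level accuracy after majority voting (a time-point-level switch is
provided). Joint search over region × grid is the default; a staged mode
ranks regions at the first grid point and then tunes the grid on the
winner. Ties break toward the lowest region id, then the earliest grid
point (smallest n_estimators first). `HyperGrid.reduced()` is a one-point
mid-grid (10 estimators, learning rate 1, L2, C = 1, 100 iterations) used
by the analysis drivers and calibration runs; with the planted effect size
the selection problem is about the region, not the classifier settings, and
the full 324-point grid multiplies cost by two orders of magnitude without
changing the result.

If the first boosting round's weak learner is no better than chance
(featureless null regions), boosting cannot proceed; the fit falls back to
the bare weak learner, which keeps the search total over all regions.

**Null behavior.** On cohorts with no group effect, subject-level CV
accuracy concentrates slightly *below* the 51.1% majority share (measured
mean 0.491, per-cohort SD 0.077 over 60 null cohorts). Two structural
effects combine: sampling subjects without replacement anti-correlates
train and test class composition (a fold whose training set over-represents
controls is tested on a fold that under-represents them), and the majority
vote amplifies the weak learner's training-prior bias from a ~53% tilt per
time point to a ~63% tilt per subject. This is a property of the specified
procedure worth knowing when interpreting small accuracy differences near
baseline.

## Shared response model

Both engines center each subject's voxels over training time points and
store the means for reuse at transform time. Initialization is seeded
random orthonormal maps (QR of a Gaussian); tol = 1e-6 on the relative
objective change; max_iter = 200; k defaults to 10 and must stay below the
smallest voxel count.

* Deterministic engine: alternate S ← (1/N)ΣW_iᵀX_i and W_i ←
  Procrustes(X_i Sᵀ); the recorded SSE trace is non-increasing by
  construction.
* Probabilistic engine: EM with per-subject isotropic noise σ²_i and a
  learned shared covariance Σ_s; the trace is the negative log-likelihood
  (computed via the Woodbury identity in the k-dimensional space), which EM
  decreases monotonically. Noise variances are floored at 1e-8 of the mean
  data variance: on noiseless data the likelihood is unbounded as σ → 0
  and the trace would otherwise wobble at float precision.

The factorization is identifiable only up to a k × k orthogonal transform,
so every recovery comparison first aligns the estimate to the truth by
orthogonal Procrustes. New subjects are mapped in by the Procrustes
solution of X_newSᵀ against the frozen S; a rank-deficient cross-product
raises with advice to lower k. SRM fitting always happens strictly inside
training folds.

## Stimulus and four-class decoding

The stimulus decoder is a linear SVM with fixed C = 1 (nothing is tuned
here; configurable), 5 folds split by subject, no majority vote — every
time point predicted individually. Because the compact design's label
split is 21/14, plain accuracy has a majority share of 0.6; chance
comparisons therefore use **balanced accuracy** (mean per-class recall,
chance 0.5 regardless of imbalance), with plain accuracy reported
alongside. The four-class model broadcasts each subject's predicted group
over its 35 time points, couples it with the per-time-point stimulus
prediction, and reports balanced accuracy (= unweighted mean of the four
class recalls), per-class precision/recall/F1, and a one-way fixed-effects
ANOVA across the classes' fold-wise precisions (fold structure inherited
from the stimulus CV; an all-identical table returns F = 0, p = 1).

## Beta estimation and group comparison

The design is the T × 2 fear/anger indicator matrix; OLS betas therefore
equal per-condition voxel means of the standardized signal (an optional
ridge term is available, default 0). The full hierarchical-covariance
treatment of grouped representational analyses is intentionally out of
scope; only the beta estimation is simplified, the downstream group test is
unchanged. The Mann–Whitney comparison pools, per group, each voxel's beta
averaged over the group's subjects and the two conditions, so the region's
voxel count sets both sample sizes. U is reported for the anxious group as
#{(a, b): a > b} + ½·ties (computed from midranks); the two-sided p uses
exact enumeration when n₁·n₂ ≤ 10 000 and the sample is tie-free, else the
tie-corrected normal approximation with continuity correction. The normal
approximation agrees with the exact null to within 0.01 at 12 samples per
group and degrades for much smaller groups (worst ≈ 0.04 at n = 3) — the
exact path exists precisely for that regime. RSMs are 2 × 2 per group
(1 − Pearson r between group-mean condition patterns); zero-variance
patterns yield NaN entries with a warning rather than an error.

## Connectome

Region-mean series use all 35 task time points regardless of stimulus,
averaged over voxels then over the group's subjects. Both thresholding
conventions are provided: absolute |r| ≥ 0.6 (default — it defines the
seed-edge counts the analysis reports) and a top-fraction percentile cut
("top30%"); the two coincide when the percentile happens to land on the
absolute cut, which the tests exploit as a cross-check. Zero-variance
series have undefined correlations: their edges are dropped with a warning.
Under independent noise at T = 35 the false-edge rate at 0.6 follows the
null distribution of the Pearson correlation
(r = t/√(t² + T − 2), t ~ Student(T − 2)), about 1.4 × 10⁻⁴ per pair, which
the tests verify by simulation.

## Problem sizes and runtime

Analysis drivers and acceptance runs use the full study-scale cohorts
(45 subjects, 20 regions, 800 voxels, T = 35) with the reduced one-point
grid: one nested region search takes ~15 s on one CPU. Calibration (null)
cohorts keep the 23/22 composition the 51.1% baseline requires but use 4
regions of 16 voxels, which leaves the fold structure and vote mechanics
untouched while keeping twenty searches under a minute each batch. Unit
tests run on a 12-subject, 4-region smoke cohort; quantitative accuracy
claims are asserted only at study scale.

## Known limitations

* The probabilistic SRM learns a dense Σ_s but shares no covariance
  structure across voxels; spatial noise correlation is not modeled.
* The four-class model inherits any bias of its two source models; its
  balanced accuracy is not corrected for the stimulus label imbalance of
  the compact design beyond the per-class averaging.
* `accuracy_by_covariate` reports descriptive bootstrap intervals
  (percentile, 2000 resamples); it does not adjust the classifier for
  covariates such as scanner site.
* Whole-brain decoding is supported as a pseudo-region (id −1) but the
  package deliberately implements no searchlight analysis.
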