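# Methods

## Overview

`csednn` implements a two-part scheme for diagnosing depression and
predicting symptom severity from resting-state fMRI:

1. **Cross-sample entropy (CSE) connectivity.** For every pair of atlas
   regions (ROIs), the asynchrony of their BOLD time series is measured by
   cross-sample entropy.  A subject is summarised by a symmetric ROI x ROI
   CSE matrix; picking one ROI as the *seed* and painting its CSE column
   onto the atlas geometry yields a 3D CSE volume — a spatial map of how
   asynchronous every region is with the seed.
2. **3D CNN ensembles.** One classification network per seed ROI is trained
   on that seed's CSE volumes; a subject's diagnosis is the majority poll
   of the per-seed votes (DDN).  Seeds whose classifier reaches an 0.85
   validation accuracy are retained for the severity pipeline (DSPN): a
   stage of per-seed high/low weak classifiers, a single moderate-vs-mild
   classifier for the low branch, and one regression network per severity
   level that predicts the 17-item Hamilton Depression Rating Scale (HAM-D)
   score.

## Cross-sample entropy

Given two z-normalised series of length L, CSE(m, r, L) =
−ln(p^{m+1}/p^m), where p^l is the probability that an l-point template
from one series matches an l-point template of the other within Chebyshev
distance r (strict `< r`).  Defaults: m = 2, r = 0.6 (in SD units of the
normalised series), L = 90 after augmentation.

Two counting conventions are implemented:

* `paper` (default): both template indices run over 1..L−l at every
  template length, so the denominator at length m+1 is (L−m−1)².  With
  short series p^{m+1} > p^m is possible and CSE can be negative; this is
  a property of the normalisation, not an error.
* `richman_moorman`: both index ranges are truncated to L−m templates at
  both lengths, so every (m+1)-match is nested in an m-match and CSE ≥ 0.

Self-matches are *not* excluded: the matrix diagonal is defined as each
ROI's CSE with itself, which differs from classical sample entropy (where
the i = j template pair is excluded).  Undefined values (zero matches at
either template length) are recorded as missing entries and imputed with
the control-cohort mean at standardisation time, keeping every volume
finite; each imputation is logged as a warning.

**Augmentation.** Each length-N series (N = 180, TR = 2 s) is partitioned
into three overlapping segments of length N/2 at offsets 0, N/4 and N/2,
tripling the number of CSE volumes per subject.  Each segment is
z-normalised independently before template matching, so r keeps the same
meaning (SD units) in every segment.  The series is normalised after
segmentation, not before — the alternative would let a segment's local
variance differ from 1 and silently rescale r.

**Standardisation.** Each CSE matrix entry is centred and scaled by the
entrywise mean and sample SD (ddof = 1, floored at 1e-6) of the *training
controls'* matrices.  Background voxels of a CSE volume carry 0, which is
exactly the control mean after standardisation — a neutral input for the
convolutions.

## Time-series preparation

Cleaning order: optional frame exclusion (motion scrubbing mask; excluded
frames are dropped, not interpolated) → linear detrend → zero-phase
4th-order Butterworth bandpass 0.01–0.08 Hz (forward–backward via
`scipy.signal.sosfiltfilt`, so no phase shift that would corrupt template
matching) → least-squares nuisance regression (intercept always included;
rank-deficient designs fall back to the pseudo-inverse).  All steps are
linear and applied uniformly, so ROI averaging commutes with them: when a
4D volume is supplied the ROI means are extracted first and cleaned once,
which is mathematically identical to voxel-wise cleaning followed by
averaging, at a fraction of the cost.  Volumes are assumed already
spatially normalised to a common grid; no realignment or registration is
performed.

## Network architectures

Classification network: average-pool (2³) → conv 32@3³ → max-pool 2³ →
batch-norm → conv 64@3³ → max-pool 2³ → batch-norm → conv 128@2³ →
flatten → FC 500 → 500 → 500 → 2, softmax head.  Regression network: the
same front end but all conv kernels 3³, batch-norm applied *before* each
max-pool (kernel 3³ at full scale), and seven FC layers 1028×3 → 512×3 →
1 with a linear head.  ReLU follows every convolution and every hidden FC
layer.  Convolutions are unpadded with stride 1 — the minimal assumption
consistent with the stated filter counts, and the full 91×109×91 input
survives all reductions under it.

The networks are built on a small numpy engine written for this package
(`csednn.layers`): valid 3D convolution expressed as einsum contractions
over sliding-window views, non-overlapping average/max pooling, per-channel
batch normalisation with running statistics, dense layers, ReLU, the Adam
optimiser, softmax cross-entropy and mean-squared-error losses, all with
reverse-mode gradients verified against central differences in the test
suite.  The builders are fully parameterised (input shape, filter counts,
kernel sizes, FC widths), so desk-scale instances exercise exactly the
same code path and layer order as the full-scale configuration.

**Training protocol.** Adam, epoch cap 200, batch size 32, early stopping
on validation loss (patience 60 for classification, 20 for regression)
with restoration of the best-validation-epoch weights.  Learning rate
1e-4 for the stage-2 severity classifier and the regressors; 1e-3 for the
diagnosis and stage-1 classifiers, where no specific value is prescribed.
Weight initialisation is He-normal with a fixed seed; seeded runs are
bit-reproducible on one device.

## Ensemble scheme

*Diagnosis (DDN).*  Per seed, the three augmented volumes' class
probabilities are averaged and arg-maxed into one vote; the final label is
the majority over seeds.  A tied poll resolves to "depressed": in a
screening context the cheaper error is a false positive.  Augmented
segments are independent training samples but are pooled at inference.

*Severity (DSPN).*  Severity levels on HAM-D: severe > 13, moderate 11–13,
mild 8–10.  Stage 1 (one weak classifier per retained seed, polled; ties
to the severe branch) separates high (= the severe range) from low; stage
2 (a single classifier fed every retained seed's volume, polled) separates
moderate from mild.  The per-level regressors are trained on *overlapped*
HAM-D ranges — severe > 11, moderate 9–15, mild 8–12 — so a subject routed
to a neighbouring level still lands inside the regressor's training
support.  The overlap is applied to the regressors only; the severity
classifiers use the class ranges.  The final score is the mean of the
per-seed regression estimates (each averaged over the three segments),
rounded half-away-from-zero to avoid platform-dependent banker's rounding.

*Splits.*  Subject-level, stratified by group, with HAM-D spread evenly
across sets by an even-spacing assignment within each group, so augmented
copies of one subject never straddle splits.  Default split proportions
follow 51/7/13 (diagnosis) and 29/10/10 (severity).  Standardisation
statistics and ROI retention use training/validation data only.

## Synthetic cohorts

The generator emulates post-preprocessing ROI series.  Each ROI has a
private stationary AR(1) latent (coefficient 0.4, unit variance); a
subject's series are coupling-weighted mixtures of the latents plus white
noise (SD 0.25 by default):

    x_i = Σ_j C_ij u_j + σ ε_i,   C symmetric, unit diagonal, C_ij ∈ [0, 1]

For depressed subjects the coupling of designated effect pairs is shifted
by `effect_size · (hamd − 7)/13`, clipped to [0, 1]: linear in severity,
full effect at HAM-D 20, nearly none at the diagnostic threshold.
Controls draw HAM-D uniformly from 0–7, depressed subjects uniformly over
`hamd_range` (default 8–20, matching the observed range of the study
population; the true within-patient distribution is unknown, so uniform is
a stand-in).

AR coefficient and noise SD were fixed by a sensitivity analysis of the
generator itself: CSE at segment length 90 responds to coupling only when
the shared structure dominates the observation noise (matches are counted
over all ~L² template pairs, so pairwise synchrony enters heavily
diluted), and φ = 0.4, σ = 0.25 places a full-strength coupling effect at
a subject-level Cohen's d ≈ 3 — a strong but not degenerate effect.  The
same dilution means weak-to-moderate coupling changes are nearly invisible
to CSE; this is a property of the statistic, mirrored by the subtle
between-group CSE differences seen in real data.

What the generator does *not* model: hemodynamics (no balloon/BOLD forward
model), head motion, physiological noise structure, spatial
heterogeneity within an ROI, or site/scanner effects.  Passing recovery
tests therefore shows that the pipeline can detect and localise coupling
effects of the kind it assumes, not that it reaches any particular
accuracy on clinical data.

## Desk-scale study conditions

The recovery tests and the acceptance script run the full pipeline at a
reduced scale chosen once for a single CPU:

* 8 ROIs on a 16×20×16 toy atlas of contiguous blocks; 60 subjects
  (diagnosis) or 12 controls + 36 depressed (severity); N = 180, TR = 2 s.
* Strong-effect topology: ROIs 1–2 act as hubs coupled to every region,
  plus direct pairs (3,4), (5,6), (7,8) — every seed carries signal, the
  hubs most, so majority polling is informative.  Effect size 0.9.
  The diagnosis cohort draws patients from HAM-D 13–20 (the severity
  scaling makes near-threshold patients near-null by construction); the
  severity cohort uses the full 8–20 range; the localisation cohort
  (single effect pair 1–2) uses 16–20 and pools two cohort replicates to
  stabilise the per-seed ranking.
* Networks: filters (4, 8, 8), classifier FC (32, 32, 32, 2), regressor FC
  (64, 64, 64, 32, 32, 32, 1), kernels (3, 3, 2), max-pools 2³, and kernel
  1 in the average-pooling slot so the layer stack survives the small
  grid; epoch caps 40–60 with patience 10–15.
* DSPN recovery retains four seed ROIs directly (the 0.85 retention rule
  is unstable on a 7-subject validation split and is unit-tested
  separately) and evaluates RMSE over the pooled validation + test
  subjects (14) to tame small-sample variance; validation subjects
  influenced training only through early stopping.

## Numerical choices

* Tolerance r is applied to per-segment z-normalised series; population SD
  (ddof 0) for series normalisation, sample SD (ddof 1) for the cohort
  standardizer.
* Strict inequality `< r` for template matches; Chebyshev distance.
* Match counting is chunked over templates (~4M elements per block), so
  L = 10⁴ series fit in a small memory footprint.
* Batch-norm: eps 1e-5, momentum 0.9; pooling crops remainders (floor
  division).
* Ties: diagnosis poll → depressed; stage-1 poll → severe branch; stage-2
  poll → moderate; RMSE ranking → lower ROI label first.

## Known limitations

* CSE is weakly sensitive to moderate coupling (the L² dilution above);
  effects must be strong in synchrony terms to be recovered at L = 90.
* The numpy engine is single-threaded and CPU-bound; full-scale
  (91×109×91, 90 seeds) training is out of reach without a GPU framework,
  which is why all recovery experiments are desk-scale.
* The two-stage severity router degrades non-gracefully at intermediate
  signal strength: confidently wrong routing can produce errors above the
  no-signal baseline, which is why the recovery grid spans the detectable
  regime.
* With only two severity classifiers and integer rounding, predicted
  HAM-D scores are biased toward each regressor's training-range centre
  for out-of-range subjects.
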