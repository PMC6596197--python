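# Methods

This note documents the models, estimators, parameter choices and known
limitations of `seqobs`.

## Experiment structure

Sequences are permutations of the five fingers (1 = thumb .. 5 = little
finger).  The admissibility constraint — no monotone run of more than
three *adjacent-finger* presses — is read as: no window of four
consecutive presses whose successive finger indices all step by +1 or
all by −1.  Under this reading 114 of the 120 permutations are
admissible (exhaustive enumeration; the six rejected ones contain a
4- or 5-long ascending or descending run).  The reading is isolated in
a single predicate (`design.is_admissible`) so an alternative
interpretation (e.g. counting repeated neighbor transitions
non-monotonically) can be swapped in; the pool count depends on it.
A 12-sequence stimulus pool is drawn from the admissible set and
partitioned 4/4/4 into trained / untrained / unused conditions.

Training sessions have 4 blocks of 20 videos (per trained sequence: 4
correct videos and 1 error video per block; 5–7 attention questions per
block), giving at least 80 correct executions observed per sequence.
Scanning sessions have 10 runs of 17 videos (8 sequences twice plus one
error video), five 13 s rest phases per run — the first at run onset,
the rest in distinct inter-trial gaps so two rests never abut — and two
questions per run.  Trial timing within a run is fixation 0.4 s, cue
2.6 s, video 13 s, question 2.6 s, with no jitter by default; the
timeline (≈342 s) fits inside the 136 recorded volumes at TR 2.6 s
(two dummy volumes are considered discarded before analysis, and all
onsets are expressed relative to the first recorded volume).

## Synthetic-data model

The generator produces exactly the statistical structure the analysis
assumes, which is what makes the downstream estimators testable:

* **Patterns.**  Each sequence has a latent voxel pattern
  `mean_cond + a(session, condition) · z_seq`, with `z_seq` i.i.d.
  standard normal over voxels and `a` the signal amplitude (default 0.5
  in every session × condition, i.e. sequence-specific coding present
  and equal across conditions; amplitude 0 is the null).  Within a
  condition all four sequences share `mean_cond`, so univariate
  condition contrasts and multivariate sequence dissimilarity are
  controlled independently.
* **BOLD.**  `y = X·B + drift + ε` per run, where X is the same
  boxcar-convolved design the GLM uses (canonical double-gamma HRF,
  peak 6 s, undershoot 16 s; a mismatched HRF can be passed for
  robustness checks), drift is a random combination of the three
  slowest discrete-cosine components (so the 1/52 Hz high-pass removes
  it exactly, keeping the zero-noise chain exact), and ε is AR(1) in
  time (default lag-1 coefficient 0.3) with spatial covariance
  `Σ_ij = σ² exp(−d_ij / ℓ)` (default σ² = 1, ℓ = 4 mm): cheap,
  positive definite, and non-spherical enough that prewhitening
  matters.
* **Behavior.**  Log-normal initiation and execution times (moment-
  matched to the requested mean and SD, keeping times positive),
  subject-level offsets (SD 120 ms), persistent subject × condition
  idiosyncrasies (SD 40 ms) — exactly the nuisance the intercept
  regression corrects — and post-training trained-condition speed-ups
  of 84 ms (initiation) and 115 ms (execution) by default, with a 12%
  execution error rate.  Sessions contain 8 sequences × 5 executions
  per subject.

Not emulated: physiological noise, motion, susceptibility artifacts,
slice-timing effects, surface geometry, or any between-region
heterogeneity of the noise model.  Passing tests therefore validate the
estimators' statistical contracts (unbiasedness, calibration, recovery),
not robustness to those real-data complications.

## First-level GLM

Two design modes: `univariate6` (trained videos, untrained videos,
error video, question, trained cues, untrained cues; rest is the
implicit baseline) and `mvpa8` (one regressor per sequence per run
covering both 13 s video occurrences, plus error-video / question / cue
nuisance columns — included by default since their presence is an open
choice, and configurable).  High-pass filtering projects out the
discrete-cosine basis below 1/52 Hz from both data and design, so drift
removal cannot bias betas.  AR(1) fits estimate the lag-1 coefficient
from pooled OLS residuals and prewhiten both sides with the standard
transform (first row scaled by √(1−ρ²)).  Residuals are returned in the
whitened space and feed the noise-covariance estimate.

## Crossnobis / LDC

Pair LDC: fold m contributes `mean_{r≠m}(d_r) · d_m / P`; the pair value
is the unweighted mean over the R folds, the condition value the mean
over the six sequence pairs.  Choices the source analysis left open,
fixed here:

* **Normalization by P** (distance per voxel) so ROI and searchlight
  values are comparable across sizes.  Absolute LDC magnitudes are
  therefore convention-dependent and are not compared against any
  external values.
* **Training-fold statistic** is the unweighted mean of the 9 training
  runs' differences.
* **Noise covariance** is estimated once from all runs' residuals
  (run-wise covariances averaged), then restricted to the member voxels
  of each ROI / searchlight before inversion — inverting a full-brain Σ
  would be ill-posed.  Shrinkage toward the diagonal uses the standard
  analytic optimal intensity (summed sampling variance of off-diagonal
  entries over their summed squared magnitude, clipped to [0, 1]),
  guaranteeing a well-conditioned PD matrix even with more voxels than
  time points.
* **Random subspace**: 160-voxel subsets drawn without replacement,
  default 1000 subsets, average of subset LDCs; an ROI of exactly 160
  voxels reduces to the whole-ROI value, a smaller ROI falls back to it
  with a logged warning.

## ROI definition and searchlight

Group peaks are cluster maxima (face connectivity, cluster-forming
threshold on |t|, minimum 10 voxels), subject peaks the strongest voxel
inside the 15 mm group sphere, ROIs the 10 mm sphere around the subject
peak clipped to the mask.  Distances are world-mm via the affine;
sphere membership is inclusive (≤ radius); peak ties break to the
smallest linear voxel index for determinism.  The native-space
back-mapping step is the identity on the synthetic common grid but kept
as an operation boundary.

The searchlight is volumetric with fixed cardinality: for every in-mask
voxel, the k = 160 nearest in-mask voxels by mm distance (ties by
index), realized radius recorded.  This replaces a surface-based
construction (no surface reconstruction here); consequently "area" in
the global summary is count × in-plane voxel area (reported in cm²),
a convention difference to keep in mind when comparing with
surface-based reports.  LDC maps may be smoothed with a 4 mm FWHM
Gaussian renormalized inside the mask (smoothed values divided by the
smoothed mask indicator, so edge voxels are not diluted).

## Inference

* `intercept_effect`: OLS of post on pre differences; B₀ with intercept
  SE, t (df = n−2), two-sided p, 95% CI; with a zero-variance predictor
  it degenerates to the outcome mean (df = n−1, logged).  d_z is the
  mean of the post differences over their SD — the matched-level paired
  effect size; when the predictor is centered the intercept equals the
  paired mean exactly.
* `ci_multiplier` returns the 95% t critical value rounded to two
  decimals for display (df 15: 2.13 two-tailed, 1.75 one-tailed — the
  exact quantile 1.7531; some reports round this down to 1.74).
* `within_subject_ci`: Cousineau centering (subject means removed,
  grand mean restored) with the Morey C/(C−1) variance correction;
  C = 1 falls back to the ordinary CI.
* `rm_anova` delegates the fully-crossed repeated-measures F tests to
  statsmodels' AnovaRM and adds partial eta squared as
  F·df₁ / (F·df₁ + df₂); it is cross-checked against an independent
  implementation in the tests.
* `cluster_inference`: voxelwise one-sample t, cluster-forming
  threshold p < 0.001 with k ≥ 10 (face connectivity), and cluster-
  extent FWE by sign-flip permutation of whole-subject maps against the
  max-cluster-size null, p = (1 + #{perm ≥ obs}) / (1 + n_perm).
  Sign-flipping replaces random-field theory: it is assumption-light
  (requires only symmetric errors under the null) and exact at the
  problem sizes used here.

## Problem sizes and numerical choices

The test and acceptance suites run the statistical contracts at these
sizes, chosen to give tight Monte-Carlo error at desk scale: estimator
unbiasedness over 1000 null studies of 16 subjects × (4 × 10 × 160)
patterns; behavioral recovery over 200 replicate 16-subject studies
(null-coverage check over 600); searchlight monotonicity over a 4-point
amplitude grid × 200 repetitions on a 6³ grid (k = 27) and cube
localization over 200 repetitions on a 10³ grid; FWE calibration over
500 null studies × 200 permutations of 12 smoothed 8³ maps.  Oracle
equivalences (fold enumeration, sphere membership, k-nearest
memberships) are exact to 1e−10 or set-identical.  The demo pipeline
uses 6 subjects on an 8³ grid with 50 × 64-voxel subspaces — the full
2-session × 10-run × 8-regressor structure at reduced spatial size.

Degenerate inputs: all-zero residuals, non-PD covariances, rank-
deficient designs, empty schedules, masks smaller than k, and
incomplete ANOVA cells raise `ValueError`; a tiny diagonal jitter
(1e−10 × mean variance) guards the shrunk covariance against zero-
variance voxels.

## Known limitations

* Volumetric fixed-k searchlights and voxel-count areas are a stated
  convention difference from surface-based analyses.
* The AR(1) coefficient is pooled over voxels per run, not spatially
  varying.
* The behavioral feedback rule's first trials have no prior median; they
  receive plain green feedback (one literal reading among several).
* Absolute LDC magnitudes depend on the per-voxel normalization
  convention and should only be compared within this package.
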