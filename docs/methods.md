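# Methods

`cordmap` implements a complete subject- and group-level analysis of
block-design cervical spinal-cord BOLD fMRI, together with a synthetic
phantom that generates runs with known activation ground truth. All
processing operates on template-space voxel grids; registration, motion
correction and segmentation are upstream concerns and out of scope.

## The phantom

The cord is modeled as an elliptical cylinder (default semi-axes 4 × 3 mm
in-plane) on a 24 × 24 × 48 grid at 1 × 1 × 3 mm — deliberately coarser
than the 0.5 mm templates used with real data so that a 24-subject cohort
runs in minutes on one CPU. Compartments are exact partitions: left/right
and dorsal/ventral hemicords split the ellipse at the (even-voxel) midline;
gray matter is a concentric inner ellipse whose area fraction (default
0.2) keeps the white-matter volume more than three times the gray-matter
volume, as in the real cord — sufficient for count-based statistics, which
are insensitive to the butterfly shape. Three segment levels (C5 superior,
C6, C7 inferior; z increases superiorly) are hard z-intervals of 16 slices
each. A CSF ring of width 2.5 mm surrounds the cord and stands in for the
spinal canal.

A synthetic run is

    data = baseline · (1 + task + physio + drift) + white noise (+ spikes)

with baseline 100 in cord, 120 in CSF, 50 elsewhere (arbitrary scanner
units). The task term is a gamma-HRF-convolved block regressor normalized
to unit peak and scaled by the target amplitude in percent (default 0.71%),
evaluated at each slice's true interleaved acquisition time and restricted
to the ground-truth voxels. The physiological term is phase-locked to
generated cardiac (~1 Hz) and respiratory (~0.25 Hz) traces with 5% cycle
jitter: first-harmonic cosines of the same phases the denoiser assigns,
with a fixed random phase per voxel, 1% amplitude in cord and 3% in the
canal for cardiac and 0.5% for respiratory. Drift is a 1% cosine with a
300 s period (above the 100 s high-pass cutoff). White noise SD 4 gives a
pre-smoothing temporal SNR near 25, matching values reported for cervical
cord acquisitions at 3 T. None of these noise amplitudes is reported in
the literature with any precision; they are package defaults, configurable
via `NoiseSpec`, and chosen once to land the phantom's QC metrics in the
observed range. Optional spike volumes add a whole-volume intensity offset
(a bulk-motion surrogate) for outlier-detection testing.

Ground-truth activation is one contiguous blob per hemicord inside a
chosen segment; the blob sizes realize a target left-right index and a
y-offset steers the dorsal-ventral index. The default active volume (320
voxels ≈ 19% of the cord) mirrors the proportion of suprathreshold cord
reported at the subject level in comparable experiments. A cohort draws
per-subject amplitude (SD 0.05%), LR target (mean +0.3, SD 0.1), DV target
(mean 0, SD 0.1) and a superior-inferior jitter (SD 1.5 voxels), and
re-pseudorandomizes the left/right block order per subject — the
randomization matters: with one shared order, design-order idiosyncrasies
are a fixed effect across subjects and leak into the habituation test.

What the phantom does *not* emulate: susceptibility artifacts, nonrigid
respiratory displacement of the cord, partial-volume structure at real
template resolution, spatially correlated scanner noise, and
subject-specific anatomy (all subjects share one grid and one atlas).
Passing recovery tests therefore demonstrates the correctness and
calibration of the analysis chain under the stated noise model, not
robustness to every artifact of real acquisitions.

## Stimulation protocol and design

A run is 20 trials of 15 s rest, 15 s left and 15 s right tactile
stimulation, the left/right order pseudorandomized (balanced to within one
trial, no more than three consecutive repeats), 900 s = 450 volumes at
TR 2 s. Each of the 40 stimulation blocks is its own explanatory variable:
a boxcar on a 0.1 s grid convolved with a gamma HRF of mean lag 6 s and SD
3 s (shape 4, scale 1.5 s; phase 0), normalized to unit peak so that betas
stay on the percent-signal-change scale, and decimated at volume midpoints.
Temporal derivatives of all 40 EVs, six motion parameters and one-hot
columns for DVARS-flagged volumes are covariates of no interest. The same
discrete-cosine high-pass projection applied to the data is applied to
every design column; omitting this attenuates task betas noticeably.

## Denoising

* **DVARS** — root-mean-square of the volume-to-volume intensity
  difference over the cord; volumes above Q3 + 1.5·IQR of the series are
  flagged. A step at volume *s* perturbs two consecutive differences, so
  both *s* and *s+1* are flagged. The box-plot rule flags ~1% of a clean
  Gaussian series too; that is inherent to the rule, not a defect.
* **High-pass** — projection onto the complement of the discrete-cosine
  components with period > 100 s (K = ⌊2·T·TR/100⌋ = 18 for the default
  run), mean restored. Transfer-function tests (50 s retained ≥ 90%, 400 s
  attenuated ≥ 90%) define correctness; no attempt is made to replicate any
  particular tool's filter bit-for-bit.
* **RETROICOR basis** — cardiac phase is linear between pulse peaks;
  respiratory phase uses the amplitude-histogram-equalization transform
  with the derivative sign. Per slice: sin/cos of four harmonics of each
  phase (16 columns) plus sum- and difference-phase interactions
  {sin,cos}(kφc ± φr), k = 1..4 (16 columns) — the sum/difference form is
  chosen so the interaction block totals exactly 16 columns.
* **CSF regressors** — per slice, the five leading principal-component
  time courses of the canal voxels (mean-centered, unit norm). Slices with
  fewer canal voxels than components get fewer columns, with a warning.
* **Nuisance regression** — voxelwise least squares against the voxel's
  own slice block, mean restored. By default the nuisance block is first
  orthogonalized against the (high-passed) task design: with 37 columns
  over 450 samples, chance task–nuisance correlation otherwise drains
  roughly 8–10% of true task amplitude (measured on noise-free phantoms).
  The alternative `nuisance_in_glm` path skips pre-regression and fits
  task and slice nuisance jointly per slice, with the task EVs evaluated
  at that slice's acquisition times; it is the preferred route for
  unbiased amplitude estimates and is used by the recovery tests.
* **Slice-timing** — resampling to the volume midpoint, by default a
  Fourier phase shift on the reflect-padded series (exact for band-limited
  signals); two-point linear interpolation is available but attenuates
  amplitudes by ~1.5% and is not the default.
* **Smoothing** — mask-normalized Gaussian (2 mm FWHM) restricted to the
  cord, so edge voxels are not diluted by outside-mask zeros. This stands
  in for intensity-adaptive edge-preserving smoothing; downstream
  statistics depend only on suprathreshold topology, not on the kernel's
  fine behavior at edges.

## GLM and inference

Voxelwise prewhitened least squares: OLS fit, AR(1) coefficient from the
residuals, one Cochrane–Orcutt refit under the binned (width 0.01)
whitening transform. Two corrections matter for calibration and were
validated on null phantoms: (i) the lag-1 autocorrelation of OLS residuals
carries a spurious negative bias of order p/T (≈ 0.2 for 87 columns over
450 volumes); its exact white-noise expectation, tr(A·M)/tr(M) with M the
residual projector and A the symmetrized lag-one shift, is subtracted
before whitening; (ii) noise dimensions already removed upstream (18
high-pass components, 37 pre-regressed nuisance columns) are subtracted
from the residual degrees of freedom. With both, null phantom Z maps have
SD 1.00 and a 2.3-threshold exceedance within a factor ~1.3 of nominal.

Subject-level side maps combine the 20 trial copes by inverse-variance
fixed effects — the same operator as the group level. This treats trial
estimates from one fit as independent; the exact mean-of-trials contrast
(`ContrastSpec.side_mean`), which propagates the full between-trial
covariance, is provided for calibration studies and gives nearly identical
maps on the phantom. Side differences (L>R, R>L) are cope differences with
summed variances. Z is the normal transform of the t statistic at the
model's degrees of freedom.

Group maps are inverse-variance fixed effects across subjects —
deliberately so, since between-subject variance is not modeled; a
sign-flip permutation test is provided as the principled mixed-effects
alternative. Subject-level thresholding is uncorrected Z > 2.3; group maps
use cluster-extent correction: supra-threshold 26-connected clusters are
retained when their extent exceeds the 95th percentile of the max-cluster
extent over ≥ 100 (default 500) Gaussian null fields, smoothness-matched to
the residual FWHM (gradient-variance estimator averaged over sampled
residual volumes). A cluster-mass variant is a config switch. The null is
Monte-Carlo rather than a random-field formula; a calibration test holds
its family-wise error near 0.05.

Percent signal change is 100 · cope · (EV peak height) / baseline. The
phantom's injected amplitude is defined at the peak of the union (all
blocks) regressor, so the amplitude-recovery readout uses the mean of all
40 trial copes via the joint-GLM unsmoothed analysis, averaged over the
true active voxels. Smoothing is excluded from this readout because it
redistributes amplitude across blob edges by construction; the
conventional per-side PSC over suprathreshold voxels is also reported, and
carries the usual suprathreshold selection bias.

## Localization statistics

Counts per compartment are exact voxel counts with the partition
identities enforced. LR = (left − right)/(left + right), DV likewise with
dorsal positive; a subject with no active voxels gets NaN and is excluded
pairwise from group tests. The superior-inferior center of gravity is
Z-score-weighted over suprathreshold voxels by default (an unweighted
centroid is a config option; the two differ by well under a voxel on the
phantom). The gray/white ratio is (%GM active)/(%WM active), undefined
when no white matter is active. Consistency maps are voxelwise sums of
binarized subject maps. Group tests: Wilcoxon signed-rank against median 0
(indices) or 1 (GM/WM ratio), exact enumeration for n ≤ 12 without ties,
normal approximation with tie and continuity correction otherwise, the
signed z reported with the sign of the rank sum; paired two-tailed t and
Pearson correlations for run comparisons. No multiplicity correction
beyond α = 0.05 is added.

On odd-x grids the midline voxel column would straddle the hemicords; it
is excluded from both hemicords and from the totals. The default grid is
even so the question does not arise.

## Time-dependent effects

The 20 trials are divided into five consecutive sets of four; each set's
trial copes are combined by fixed effects and summarized as suprathreshold
count and mean Z. Because design efficiency is not constant across sets —
the final trial's response is truncated by the end of the run — each set's
cope is standardized by the across-set pooled SE before thresholding
(without this, a perfectly stationary cohort shows a strong spurious
"habituation": the last set detects systematically fewer voxels). Plain
per-set re-thresholding remains available. The group trend test applies
the orthogonal linear contrast (−2,−1,0,1,2) per subject and a one-sample
two-sided t across subjects (equivalent to the linear contrast of a
one-way repeated-measures ANOVA, whose full table is also emitted). Type-I
error is within the binomial envelope of 0.05 over 600 simulated
stationary cohorts.

## Numerical and degenerate-input choices

Rank-deficient designs raise errors naming the offending columns (greedy
QR elimination). Ill-conditioned nuisance blocks warn and fall back to the
SVD pseudo-inverse. Aliased respiratory harmonics that collapse to
near-constants after high-pass are dropped from joint per-slice designs.
Zero-variance voxels are excluded from TSNR with a logged count. All
randomness flows from explicit integer seeds; identical spec + seed gives
bit-identical arrays, and per-subject streams are derived with
`SeedSequence` spawn keys so cohorts are order-independent.

## Known limitations and observed behavior

* Under the default study-scale conditions (TSNR ≈ 25, 0.71% amplitude, 20
  trials, 2 mm smoothing) the voxelwise detection sensitivity inside the
  true region at Z > 2.3 is ≈ 0.55–0.62, not higher: the side-specific
  contrast is intrinsically inefficient because left and right blocks are
  adjacent and their hemodynamic responses overlap (per-voxel contrast SE
  ≈ 0.6% of baseline). Detection of the *region* is nevertheless reliable
  in every phantom subject, and recovered laterality indices are
  positively biased toward zero (dilution by false positives and smoothing
  halo) but reject the zero-median null decisively at n = 24.
* Fixed-effects group inference understates between-subject variance by
  design; use the sign-flip test for generalizable claims.
* The trend statistics remain count-based and threshold-dependent; a
  cope-based trend would be more efficient but is not what the procedure
  specifies.

## Problem sizes used by the test suite

The default phantom (24 × 24 × 48 grid, 1728 cord voxels, 450 volumes) and
a 24-subject cohort are used for recovery tests; cluster calibration uses
400 + 400 null fields; Wilcoxon power uses a 500-replicate parametric
bootstrap of the recovered index distribution. These sizes were chosen so
the full suite is a few minutes on one CPU while keeping Monte-Carlo error
well inside the asserted tolerances.
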