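# Methods

This note documents the models and procedures implemented in danioquant,
the defaults that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Cardiac rhythm analysis

**Signal model.** A chamber's mean-ROI intensity is treated as a
quasi-periodic pulse train: one smooth unimodal pulse per contraction,
superimposed on slow drift (photobleaching, focus) and frame noise. Only
pulse *timing* carries information; pulse shape is never interpreted.
Traces are linearly detrended before any spectral step.

**Peak-rate estimator.** After detrending, the trace is smoothed with a
Gaussian of σ = (minimum peak distance)/4 samples and peaks are detected
with scipy's `find_peaks` using

* minimum peak separation 60/(1.5 · band-max bpm) s (default band max
  480 bpm → 83 ms), i.e. half a period at 1.5× the fastest rate the band
  admits — rejects dicrotic ripples without suppressing true beats;
* prominence 0.25 × robust amplitude, where robust amplitude is the
  2.5–97.5 percentile range of the detrended trace. A percentile range is
  used rather than a median-based scale because pulse trains with duty
  cycle below 50% have median absolute deviation near zero, which would
  let every noise wiggle through.

The rate is 60(n−1)/span over the detected peaks. Fewer than two peaks
raises a dedicated "insufficient beats" error so asystole or a flat trace
is never reported as a numeric rate.

**Fourier estimator.** The dominant frequency is the argmax of the
full-length periodogram within a band that must exclude DC (default
0.5–8 Hz, i.e. 30–480 bpm, excluding respiratory/drift frequencies).
Using the whole trace gives spectral resolution 1/duration (1 bpm at
60 s); the resolution is always reported alongside the estimate. Peak
counting loses beats when they crowd together at tachycardic rates, so
the Fourier path is the method of choice above ~250 bpm; on clean traces
the two estimators agree within one resolution step (tested).

**Spectrograms** use 5 s windows with 75% overlap, per-window linear
detrending: ≥2 beats per window at the slowest rates of interest, and a
0–5 Hz display band that corresponds to 0–300 bpm.

**AV classification.** The ratio r = atrial bpm / ventricular bpm is
classified with multiplicative bands: matched if r ∈ [1/1.15, 1.15], 2:1
block if r ∈ [2/1.15, 2 · 1.15], intermediate n:1 otherwise. The ±15%
width absorbs rate-estimation error at typical 30–60 s trace lengths
while keeping the bands disjoint (they end at 1.15 and 1.74). A
ventricular rate of zero is reported as a distinct ventricular-standstill
class, not an infinite ratio. Classification depends only on the ratio,
never the absolute rates.

**Switch calls.** A larva recorded twice is a switcher iff its AV class
differs between recordings. A separate per-recording flag detects abrupt
regime changes *within* one trace by classifying per-spectrogram-window
dominant-frequency ratios; it is reported independently and does not
enter the two-recording switch statistic.

## Seizure-like episode scoring

Windows are 1 s, non-overlapping, anchored at recording start; a window's
distance is the sum of successive Euclidean displacements whose starting
sample falls inside it, and a trailing partial window is dropped.
Tracking dropouts up to 0.5 s are bridged by the straight-line
displacement; windows touched by longer gaps are dropped.

The threshold is the empirical (1 − f) quantile (f = 0.001) of window
distances pooled across all wild-type vehicle-treated larvae, defined as
an order statistic: with n pooled windows, exactly ⌊fn⌋ lie strictly
above the threshold (fewer under ties). Hence the calibration pool's own
exceedance is ≤ f by construction, and over a 900-window (15 min)
recording the implied expectation is 0.9 — slightly less than one
episode — for calibration-like larvae. Raising f can never raise the
threshold (tested). Calibration pools the illuminated-phase windows by
default (configurable); the pipeline thresholds in mm since the generator
works in mm, and a pixel↔mm scale can be applied upstream when tracking
hardware reports pixels. Whether a high-temperature experiment reuses the
standard-temperature threshold or recalibrates is the caller's choice —
both are a single `calibrate_threshold` call on the appropriate pool.

Group comparison fits episodes/min ~ genotype + replicate by OLS per
measure (each light phase, and each treatment if present), reports the
genotype main effect, and Benjamini–Hochberg-corrects across measures.
Groups with n < 2 are excluded with a warning; the replicate blocking
term is dropped automatically when only one experiment is present.

## dF/F activity maps

Frames are smoothed spatially with a 2-voxel Gaussian (σ configurable;
σ = 0 is the identity). Per voxel, the baseline F0 is the minimum over
the recording and dF/F = 100 (max − F0)/F0 — non-negative by
construction and invariant to multiplicative gain, which is the point of
min-baseline normalization: it cancels expression-level differences
between fish. It is *not* invariant to additive offsets (a constant
camera offset deflates dF/F; tested as a directional property), and it
explodes as F0 → 0, so voxels with F0 at or below a floor — default 1%
of the series' 99.9th-percentile intensity — are marked invalid and
excluded from summaries. The activity summary is the mean dF/F over
valid voxels in a cellular-regions mask. Inputs are assumed
motion-corrected and co-registered; registration itself is out of scope.

## Voxel-based morphometry

**LJD.** From a dense displacement field u(x) in physical units, the log
Jacobian determinant ln det(I + ∇u) is computed with central differences
(one-sided at borders). Voxels with det ≤ 0 (non-invertible local warp)
are flagged NaN and excluded. Sign convention: negative = local
contraction relative to the reference. Closed forms (identity → 0,
uniform scaling s → 3 ln s, composed scalings add) hold to 1e-6 and a
brute-force per-voxel oracle agrees to the same tolerance (tested).

**Volumetry.** A reference-space mask's subject-space volume is
Σ_mask exp(LJD) · voxel volume — each reference voxel contributes the
subject volume it maps from. This is mathematically equivalent to
inverse-transforming the mask and counting voxels, without reimplementing
registration; a voxel-counting mode for binary segmentations is provided
for pipelines that do have inverse-transformed masks. Percent-of-brain
normalization divides by the whole-brain volume computed the same way.

**Cluster inference.** Candidate clusters are connected components (full
26-connectivity) of voxels whose two-sided Welch-t p is below the
cluster-forming threshold (default p < 0.01). Group labels are permuted
(default 1000 times; exhaustive enumeration with a notice when fewer
distinct arrangements exist, e.g. 20 for 3+3) and the maximum
supra-threshold cluster extent recorded per permutation; a cluster's
family-wise p is the standard Monte-Carlo estimate (1 + b)/(m + 1),
significant at cluster_alpha = 0.05. Extent-based max-cluster permutation
is the conservative standard when no spatial model of the noise is
assumed. The nominal per-voxel p is reported only inside surviving
clusters.

**Symmetrization** replaces each voxel's p by the greater of its own and
its mirror's across a declared midsagittal plane (default the grid
midpoint; even extents mirror between voxel centers by nearest-voxel
mapping, and an inconsistent plane is rejected rather than guessed).
Taking the maximum makes the operation conservative, idempotent and
never-decreasing.

**Two-cohort combination** fits value ~ group + cohort per voxel and
tests the group effect against the cohort-only model, so constant
between-cohort intensity offsets are absorbed by the blocking factor.
Channel-level findings across tuba/gad1b/LJD should be BH-corrected by
the caller (the same `multipletests` route used in the seizure module).

**Intensity contrasts** report per-subject in-mask means, group means,
and 100 (1 − mutant/wild-type), with a delta-method 95% CI on the ratio
of group means.

## Synthetic-data generator

The generator's defaults are the study conditions the pipelines are
validated under.

* **Cardiac**: strictly periodic atrial beats; raised-cosine pulses of
  width 0.4 periods (shape is arbitrary — only timing is analyzed);
  deterministic every-k-th conduction for integer ratios, Bernoulli
  conduction with p = 1/ratio for intermediate ratios (long-run ratio
  correct without an electrophysiological model); optional mid-recording
  regime switch; additive Gaussian noise as a fraction of pulse
  amplitude; 100 samples/s; default duration 30 s (recording durations
  are not standardized in this kind of experiment; 30–60 s is typical
  and configurable).
* **Tracks**: 10 Hz, 7 × 7 mm reflecting arena, two 15-min phases
  (illuminated, dark) with position continuous across the phase change.
  Baseline bouts are a 0.2 Hz Poisson process with displacement
  N(1.0, 0.3) mm spread over 0.3 s; seizure-like bursts occur at a
  per-group rate (default 0.02/min for untreated wild-types) with
  displacement N(12, 2) mm executed as a 1 s random walk aligned to a
  window, so a planted burst produces exactly one supra-threshold
  window. The constructor rejects burst distributions that do not sit
  strictly above the baseline, since ground truth would otherwise be
  ill-defined.
* **Volumes**: 32×32×16 grid at 2×2×4 µm with ellipsoidal brain and
  region masks ("MHB", "subpallium", "cellular"); a planted volumetric
  factor f adds the constant ln f to the LJD inside its region, so
  region-integrated exp(LJD) equals f × reference volume exactly at zero
  noise; intensity factors scale the baseline channel intensity inside
  their region. Noise is Gaussian-smoothed white noise rescaled to the
  requested sd; the default smoothness of 1.5 voxels keeps the noise a
  smooth field (voxelwise-independent noise makes max-cluster-extent
  nulls so discrete that permutation inference turns conservative) while
  staying small relative to the planted regions so region-scale effects
  remain resolvable.
* **GCaMP**: 150 frames at 0.5 Hz (a 5-min recording); per-voxel Poisson
  events rising instantly to amplitude × baseline and decaying with a
  4 s time constant, so a lone event's planted amplitude is exactly what
  min-baseline dF/F reads back.

Per-subject seeds derive from a master seed plus a CRC32 hash of the
subject's identity, so any cohort member regenerates identically in
isolation.

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: heart-rate variability and pulse
shape changes (only mean rate and conduction are planted),
video-artifact noise (noise is white Gaussian), realistic swim-bout
kinematics (bouts are isotropic random displacements), registration
error (LJD fields are planted directly rather than derived from warping
real anatomy; spatial noise correlations of real registration pipelines
may differ from the smoothed-white-noise model), and GCaMP indicator
nonlinearity. Recovery results validate the estimators' correctness
under their stated models, not robustness to every real-world artifact.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale versions of the
experimental designs: 27- and 41-larva cardiac cohorts at 30–60 s per
trace, 120 calibration larvae (≥10⁵ pooled windows), volumetric cohorts
of 10–15 subjects per group on 32³-scale grids, and the family-wise
error calibration at 500 null cohorts of 6+6 subjects on a 12×12×6 grid
with 199 permutations each. Exact planted-recovery identities (volume
factors, intensity factors, dF/F amplitudes) are asserted to 1e-9
relative error at zero noise; LJD closed forms to 1e-6 (finite-difference
exactness holds for affine fields); noisy recoveries within
delta-method CIs. Ties in quantile calibration are resolved by counting
strictly-greater windows, which can only lower the exceedance below the
nominal fraction.
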