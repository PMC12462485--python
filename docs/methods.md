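# Methods

`beliefdyn` implements an analysis chain for naturalistic-viewing fMRI
studies in which participants' *belief updates* — moments when their
predictions about the unfolding stimulus change — are measured behaviourally
and related to neural state dynamics and intersubject statistics.  Because
the real imaging cohorts such analyses use are large external archives, the
package ships a synthetic-cohort generator with planted structure, and every
stage of the chain is validated against that ground truth.

## Behavioural update courses

Raters watch the stimulus and press a key whenever they feel their beliefs
in one domain (scene **states**, **agents**, **actions**) have been updated.
The pipeline:

1. expands each press into a forward 5 s boxcar (`[press, press + 5 s)`) — a
   press reports an update that has just been experienced, so the window
   runs forward from the press; a TR is covered when its acquisition
   interval overlaps the boxcar (0-based TR indexing throughout);
2. averages boxcars over raters into a group update-probability course;
3. smooths with locally weighted quadratic regression (loess, tricube
   weights, 10 % span — the R `loess` defaults), clamping to [0, 1];
4. thresholds at `mean + θ·SD` (sample SD), collapsing each supra-threshold
   run to its **final** TR.  θ defaults: 2 for movie update domains, 1 for
   arousal, 1.2 for the narrative stimulus.

Matched non-update control TRs are the lowest-rated TRs lying more than one
TR from every update of every domain, exactly as many as the domain has
updates, ties broken by TR index.  Rating quality is summarised by 100
random split-half correlations corrected with Spearman–Brown (2r/(1+r)),
and between-domain associations by Pearson r, lagged cross-correlation, and
plug-in mutual information over an 8×8 equal-width binning (natural log).
The rating literature does not pin down an MI estimator; the plug-in
histogram estimator is adequate at these series lengths and is validated
against the closed form for bivariate Gaussians.

## Signal cleaning and intersubject statistics

ROI-mean series are cleaned by least-squares removal of the six motion
parameters (plus intercept), linear detrending, and a zero-phase
second-order Butterworth band-pass in 0.01–0.1 Hz at the scan's sampling
rate.  All intersubject statistics are leave-one-out: subject versus mean of
the remaining subjects (ISC); subject's region *i* versus left-out mean of
region *j* (ISFC, asymmetric, reported in the i→j direction); per-TR spatial
correlation of a subject's voxel pattern with the left-out mean pattern
(ISPC).  Update-locked variants concatenate windows of ±3 TRs (7-TR, for
ISC/ISFC) or ±4 TRs (9-TR, for ISPC) around the update points, merging
overlaps so no TR enters twice; windows clipped at the run boundary are
kept when at least half the nominal length survives.  The sliding-window
ISC uses 21-TR windows stepped by 1 TR, Fisher-z transformed (capped at
|z| = 18.7, the value reached within ~1e-16 of r = 1) and averaged over
subjects, indexed at window centres.

The seed ISFC map correlates each subject's seed series with every target
voxel's left-out mean series.  Because all subjects face (nearly) the same
target course, subject-level values are strongly dependent: a chance
correlation between the seed's shared course and a voxel's mean course
shifts every subject coherently, so a one-sample t over subjects is wildly
anticonservative.  The voxel p-value is therefore computed from the
group-mean r against its finite-sample null with dof = segment length − 2,
followed by Benjamini–Hochberg FDR (q = 0.001) and a display threshold
r > 0.1.

## Latent-state dynamics

Each ROI's state dynamics are modelled with a hidden Markov model with
univariate Gaussian emissions per state — the simplest emission model
consistent with ROI-mean input.  Fitting is Baum–Welch with per-step
scaling: means initialised by k-means++ on the pooled samples (seeded),
SDs at the data SD, sticky transition initialisation (diagonal 0.9),
convergence when the log-likelihood gain falls below 1e-6 (500 iterations
max).  A variance floor of 1e-6 of the data SD guards against state
collapse; because a floored M-step can in principle lower the likelihood,
fitting stops at the best parameters if a decrease is detected, keeping the
reported history non-decreasing.  Decoding is Viterbi with ties broken
toward the lower state index; states are relabelled by ascending mean.

The group model can be fitted on the subject-mean series (default) or on
all subjects' series as independent sequences sharing parameters
(`fit_on="concat"`).  The mean series is the default because the consensus
procedure decodes the mean series anyway, and averaging ~100 subjects
suppresses idiosyncratic noise by an order of magnitude, making the
bootstrap loop hundreds of times cheaper at equal recovery in our
simulations.  BIC uses p = (K−1) + K(K−1) + 2K free parameters and
n_obs = the number of samples actually entering the likelihood.

The bootstrapped consensus procedure:

* **State count** — 30 bootstrap runs, each dropping 10 random subjects,
  fitting K = 2..9, recording the BIC-minimal K; the lower median over runs
  is the selected count (fewer than min(20, n_boot) successful runs is an
  error).
* **Consensus transitions** — ten refits of the selected model from fresh
  initialisations; each run's Viterbi path on the subject-mean series marks
  TR t when state(t) ≠ state(t−1); the 0/1 marks are averaged into a
  consensus course and binarized with the same mean + 2 SD / final-TR rule
  as the behavioural courses.
* **Coincidence** — for window sizes t = 0..8, the proportion of each
  domain's update points falling inside the union of forward windows
  `[transition, transition + t]` (t = 0 is the transition TR itself).

## Permutation inference

Surrogate courses are built by FFT phase randomization: fresh phases
uniform on (−π, π) at every non-DC frequency, DC (and the Nyquist bin for
even lengths) kept, conjugate symmetry enforced.  The amplitude spectrum —
hence the circular autocorrelation — is preserved exactly and the mean is
unchanged.

The **coincidence test** phase-randomizes the *continuous* consensus course
before each re-binarization (the threshold is recomputed per surrogate),
keeping the update points fixed.  The conditional statistic per window size
is the smaller of the two margins by which the preferred domain's capture
proportion exceeds the other domains' (`min_diff`); the directional
criterion requires both margins positive; p-values are one-tailed add-one
estimates per window size (the null is not pooled across window sizes).
An own-proportion statistic is available as an alternative.  The **ISPC
contrast test** correlates each prefrontal region's ISPC course with the
integrator region's over each domain's concatenated 9-TR windows, forms
relative contrasts of the own-minus-mean-of-others form, and compares the
preferred region's contrast against each other region's, with nulls built
by phase-randomizing the prefrontal ISPC courses (per subject) while the
integrator stays fixed.  The **arousal variant** asks whether high-arousal
points (θ = 1) are captured by transition windows more than every domain's
updates.  The **coupling–experience** analysis correlates, across subjects,
mean integrator–PFC ISFC during updates with whole-run integrator ISC, and
repeats it at matched non-update points.

## Parametric-modulation GLM

The design contains a stimulus event regressor (events on a 1 s grid,
convolved with the canonical double-gamma HRF: response gamma(6),
undershoot gamma(16)/6, 32 s support, unit peak), one column per update
domain formed by multiplying the mean-centred update course into the event
train *before* convolution (the modulation applies to neural, not
hemodynamic, signal), six motion nuisances, and an intercept.  Modulators
enter simultaneously without orthogonalisation; rank deficiency is flagged
with a condition number, never silently repaired.  A continuous stimulus
makes the event regressor near-collinear with the intercept away from the
run edges; the condition number reports this.  Voxelwise OLS per subject,
[1, −0.5, −0.5] contrasts over the modulators, a one-sample t over
subjects, BH-FDR at q = 0.05, and a 25-voxel cluster-extent threshold with
orthogonal-neighbour connectivity, applied to positive- and negative-t
survivors separately (mixed-sign clusters are not meaningful units).

## The synthetic cohort

Defaults emulate a movie-watching study: 111 subjects × 189 usable TRs at
TR = 2.47 s; a narrative preset gives 52 × 400 at TR = 1.5 s.  Rater panels
of 18/21/19 per domain press with probability 0.8 at the event time plus
Normal(0, 1 s) jitter.  One global seed fans out into fixed per-component
streams, so outputs are bit-identical given the config.

Planted structure, and the reasoning behind the main choices:

* **Events** — 5/3/4 events per domain on jittered regular grids, separated
  across domains.  Counts are deliberately sparse: with the 10 % loess span
  (~19 TRs here) each smoothed update bump spans roughly the span width, so
  the bumps must occupy a minority of the run for the mean + 2 SD threshold
  to retain a baseline.  Real thresholded update counts are *outputs* of
  that threshold, not ground-truth event counts.
* **Hemodynamic lag** — BOLD latent-state changes lag the stimulus events
  by 5 s (~2 TRs at the movie TR).  An instantaneous level shift at event
  onset would be physiologically wrong, and it would also misalign the
  coincidence analysis: detected update points sit ~5 s after events by the
  update-window convention, so undelayed neural transitions would
  structurally miss the short forward windows.
* **ROI-mean BOLD** — per-state emission means with adjacent separation
  `effect_size` (default 1.5 noise SDs; the `state_planted_config` preset
  uses 3 with no transient, making the generative process exactly a K-state
  Gaussian HMM for state-recovery studies), plus an HRF-shaped shared
  transient (amplitude 1.5) at the ROI's preferred domain's events, plus a
  shared stimulus-locked noise course (weight 0.5) and unit idiosyncratic
  noise.  A per-subject gain (SD 0.3, mean 1) scales the shared part —
  the subject-level "shared processing" factor that links coupling to
  shared responses.  The integrator region changes state at every domain's
  events.
* **Voxel patterns** — event-locked amplitude (HRF-convolved bump course)
  times a spatial profile: a uniformly positive fixed response map (a
  compact region activating with updates, recoverable by the GLM) plus
  per-state templates orthogonalised against it at half weight, plus unit
  voxel noise.
* **Arousal** — loess-smoothed pooled event density rescaled to [−1, 1]:
  arousal tracks the overall density of updates without asserting any
  mechanism.
* **Motion** — small Gaussian random walks (step SD 0.02), six columns.

What the generator does **not** emulate: volumetric geometry and spatial
smoothness, physiological noise spectra (cardiac/respiratory), scanner
drifts beyond what detrending removes, rater false alarms, and
between-subject variation in update *timing* (only responding and gain vary
across subjects).  Passing tests therefore demonstrate the correctness and
calibration of the machinery on data with the assumed structure, not that
the scientific conclusions would replicate on real cohorts.

Two further generative consequences worth knowing when reading outputs:
within update windows the sustained state levels dominate raw-series
variance, so the own-domain ISC advantage is assessed on *cleaned* series
(the band-pass strips sustained levels, as in the real pipeline); and the
sign of a single pairwise ISFC value during a domain's few update windows
depends on the realized relative direction of the two regions' planted
state steps, so individual pairs can be negative while the across-subject
coupling–ISC correlation (carried by the gain factor) stays positive.

## Problem sizes used in validation

Oracle and exactness checks run on toy problems (5 subjects × 20 TRs;
K ≤ 3, T ≤ 8 with exhaustive enumeration).  Recovery and power studies run
at movie scale (111 × 189) over 20 generator seeds.  Null calibrations use
200 reduced cohorts (24 subjects for the coincidence test; 12 subjects ×
24 voxels for the ISPC test) with 200 permutations each, checking the
empirical rejection rate at α = 0.05 against its binomial 99 % interval.
The analysis drivers use 1000–2000 permutations; a production analysis of
real data would use the 10,000 of the original design.

## Known limitations

* The loess smoother is O(n·q) per course; fine at hundreds of TRs, slow
  for hour-long runs at short TR.
* Group HMM fitting on the subject-mean series assumes state timing is
  shared across subjects; subject-specific timing variability is exactly
  what the bootstrap is meant to absorb, but extreme desynchronisation
  would call for the `concat` mode (or per-subject decoding, not
  implemented).
* The conditional coincidence statistic is one defensible reading of a
  directional two-comparison hypothesis; the `own` statistic is provided
  for sensitivity analyses.
* Phase-randomization surrogates assume stationarity; the consensus course
  (an average of binary marks) is only approximately so, and the null
  calibration test is the empirical check that the approximation holds at
  these sizes.
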