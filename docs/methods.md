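# Methods

`somnidec` re-implements, as a tested pipeline with synthetic ground truth,
a between-subject decoding analysis of continuous sleep EEG: does the power
spectrum of a night's sleep carry information about which category of visual
material (faces vs houses) the sleeper studied before bed, and does the
strength of that "reprocessing" signal predict overnight memory
consolidation?

## The analysis pipeline

**Feature preparation.** Each night's EEG is cut into 4-s trials inside the
30-s scoring epochs (7 whole trials per epoch, the 2-s remainder dropped).
Trials inherit the epoch's sleep stage and the 90-min night segment of their
onset, counted from lights-off; only complete 90-min segments are analysed.
Artefactual trials are removed by three spectral-outlier criteria computed
per trial and channel — log overall power (disconnected electrodes), log
maximal sample-to-sample difference (jumps), log 110–140 Hz power (muscle)
— thresholded at median ± k·1.4826·MAD (k = 5 by default); channels flagged
in more than 20 % of trials are removed whole and interpolated by
inverse-distance-weighted averaging of good electrodes within twice the
grouping radius. Spectra come from Welch's method with 2-s Hamming windows
at 95 % overlap (so a 4-s trial contributes 21 windows), keeping the 0.5 Hz
grid from 0.5 to 30 Hz — 60 bins. Electrode spectra are averaged within a
3 cm radius of 32 extended 10–20 locations, trial-averaged per
(stage-group × segment) analysis cell, min–max normalized per channel to
[0, 1], and finally sharpened by subtracting, from each bin, the mean of its
six neighbouring bins (three per side, truncated at the edges). The order —
normalize, then sharpen — is fixed and test-enforced. A subject-night
enters a cell only with ≥ 40 artefact-free trials (160 s of data); a cell is
analysed only with ≥ 11 subjects, each contributing exactly one 32 × 60
matrix per night regardless of trial count.

**Two-step classifier.** Stage-groups are S2, SWS (S3+S4 pooled; an
S4-only mode exists because deep-sleep scoring conventions differ), and
REM. Within each training set, one linear soft-margin SVM (C = 1) per group
channel is cross-validated leave-one-subject-out on that channel's 60 bins;
the resulting accuracy is the channel's weight. The accuracy-weighted
average of the 32 channels (a 60-dim vector per night) trains the main
linear SVM, evaluated on held-out subjects. The whole procedure repeats
over random subject-level 5-fold partitions (both nights of a subject
always share a fold, so train and validation subjects are disjoint).
Probability estimates use Platt scaling fitted on training decision values
only; a night's reprocessing strength is its mean probability-of-true-class
over all repetitions in which it was in the validation fold.

**Inference.** Significance is purely permutation-based: each subject's two
nights are relabelled face/house or house/face with probability ½ (the
identity relabelling is an allowed draw), the entire two-step pipeline is
re-run, and p is the fraction of null accuracies at or above the observed
one; with n permutations the attainable floor is 1/n, reported as a strict
bound when no null value reaches the observed accuracy. Families of cell
p-values are Holm-corrected (statsmodels). A finer time course slides a
22.5-min window in 4.5-min steps across the night, re-running the full
aggregate-prepare-decode path per window; windows failing inclusion are
missing, not zero.

**Behaviour.** Recognition memory is scored as d′ = z(hit rate) − z(false
alarm rate) with the log-linear (count + 0.5)/(n + 1) correction, so perfect
scores stay finite; consolidation is post-sleep minus pre-sleep d′.
Reported statistics are Spearman correlations (t-approximation p-values),
rank-based partial correlations, OLS on standardized variables with
per-predictor variance explained as the R² drop on removal (squared
semipartial correlation), a strength × stage interaction test on stacked
observations with cluster-robust (by subject) standard errors, and a
leverage filter that removes the k highest hat-values of the simple
regression (h_i = 1/n + (x_i − x̄)²/Σ(x − x̄)², Σh = 2).

## The SVM solver

The inner loop fits tens of thousands of SVMs on ~20 × 60 matrices, and
permutation inference multiplies that by the shuffle count, so the package
carries its own solver: SMO on the C-SVC dual with maximal-violating-pair
selection and an **unregularized bias** — the same optimization problem
libsvm solves, verified against `sklearn.svm.SVC(kernel="linear")` to
~1e-6 in weights on random problems, and against an independent
explicit-loop QP oracle in the test suite. The unregularized bias is
load-bearing: sharpened spectra share a large common offset, and at these
feature scales C = 1 puts the hinge loss deep into its saturated regime,
where a regularized (weight-vector-folded) bias is forced toward zero and
the classifier collapses to chance. Dual variables are snapped to the box
bounds within 1e-12 to keep the working-set selection stable under
roundoff. Ties at decision value exactly 0 go deterministically to the
first class.

## The synthetic cohort generator

Real recordings for this design are not publicly available, so every stage
is validated on synthetic cohorts with known ground truth.

**What it emulates.** Two nights per subject, one per condition,
counterbalanced. Hypnograms follow 90-min cycles (descent through
S1→S2→S3→S4, re-ascent, REM) with deep sleep shrinking and REM growing
across the night and mild per-cycle jitter; every full 90-min segment
contains S2, SWS and REM epochs. Stage spectra are a 1/f^1.3 background
(60 µV²/Hz at 1 Hz) plus Gaussian peaks: a dominant delta bump for S3/S4
(120/200 µV²/Hz), a 13 Hz spindle peak strongest in S2, and a 6 Hz theta
bump in REM. Between-subject variability is a log-normal gain (σ = 0.1)
drawn per channel group × frequency band, stable across a subject's two
nights — regional rather than globally shared, since real between-subject
spectral differences are topographic (with globally shared gains the
channel-weighted average retains the noise at full strength while diluting
the signal, and between-subject decoding of a localized signature is
provably impossible). Per-night channel gains (σ = 0.05, removed by
normalization) and Welch-like multiplicative trial noise
(Gamma with shape k = 18, roughly the effective degrees of freedom of 21
strongly overlapping windows) complete the noise model.

**The condition signature** multiplies power by (1 ± a) (face/house) in
configurable (channel group × band) cells, restricted to configured stages
and 90-min segments; an additive mode exists behind a flag. The realized
amplitude per night is a × a log-normal jitter (σ = 0.3 by default),
clamped below 1 so the weaker condition's power stays positive; this
realized value is the ground-truth "reprocessing strength" the behaviour
module couples to: expected consolidation = intercept + link × strength,
with Gaussian noise on top of the binomial sampling noise of the
recognition counts (100 old / 50 new items, unbiased criterion). The paper
this design emulates does not report the real effect size; the default
a = 0.3 is a free parameter swept in tests.

**Two fidelity levels.** The time-domain path synthesizes each 30-s epoch
in the frequency domain with the exact expected periodogram and equal-power
0.5-s crossfades at joins; a Welch estimate over ≥ 5 min of one stage
matches the template to < 0.05 mean absolute log-power deviation
(test-enforced). Artefacts are injected on the same trial grid the
detectors use: flat or hugely noisy whole channels, ±10 SD step
discontinuities, and 110–140 Hz bursts (requiring > 280 Hz sampling; the
synthetic default of 250 Hz — 1 kHz acquisition is wasteful above a 30 Hz
analysis ceiling — is raised in artefact studies). The feature-level path
exploits that the mean of n iid Gamma(k) trials is Gamma(nk)-distributed,
drawing per-cell trial-averaged spectra exactly in O(channels × bins)
without materializing trials; a trial-level variant feeds the
sliding-window analysis. Cohorts are bitwise-reproducible: one master seed,
with per-subject/night/purpose streams derived by hashed `SeedSequence`
spawn keys so any part can be regenerated in isolation.

**What passing tests do not show.** The generator has no biophysical
forward model, no K-complexes or eye-movement morphology, no S1-specific
content, stationary spectra within a stage, and noise that is independent
across frequency bins given the gains — so passing recovery tests
demonstrate the *pipeline's* correctness and calibration, not performance
on real sleep EEG.

## Validation studies and their scales

Study sizes are chosen to run on one CPU in minutes; all inputs are
regenerated from the study seed at run time.

* **Oracle equivalence.** On a 6-subject, 2-channel × 3-bin cohort the full
  two-step procedure (leave-one-subject-out outer folds) matches an
  independent brute-force implementation — explicit loops, each SVM solved
  as a slack-variable QP by SLSQP with an exact 1-D bias polish — to well
  under 1e-3 in accuracies and averaged |weights|. Where the bias is
  genuinely non-unique (no free support vector), both implementations use
  the midpoint of the optimal interval, making them comparable on
  degenerate inputs.
* **Type-I calibration.** 200 null cohorts (12 subjects, amplitude 0,
  reduced 6 × 12 features), 99 permutations each, one decoding repetition
  per permutation (the observed statistic is computed at the same reduced
  setting for exchangeability fairness). The empirical rejection rate at
  α = 0.05 must lie in [0.02, 0.09], the binomial 95 % band around the
  nominal level given the discreteness of the accuracy statistic.
* **Signal recovery.** Amplitude 0.3 confined to one channel group ×
  spindle band × segment 2 × S2/SWS, 20 subjects at full 32 × 60 features:
  permutation p ≤ 0.05, sliding-window peak inside segment 2 (six decoding
  repetitions per window — the peak-location check is a maximum over ~100
  overlapping windows and needs the extra repetitions to keep noise maxima
  below the in-segment signal), and the spindle-band weight topography
  maximal on the seeded group.
* **Behaviour-link recovery.** 50 cohorts of 32 subjects with consolidation
  coupled to SWS strength only (spatially distributed spindle signature in
  S3/S4, segments 2–4, amplitude 0.45, link 3 d′-units per unit strength,
  residual noise 0.05 — generous by design, since the binomial noise of
  recognition counts alone caps per-night consolidation precision at
  ≈ 0.34 d′ units): a positive, significant SWS correlation with null
  S2/REM correlations. Averaging strength over three segment cells is what
  keeps the estimate's noise below the link signal.

## Known limitations

* **Single-group signature ceiling.** The accuracy-weighted channel average
  gives a lone informative group a weight share of roughly
  0.8/(0.8 + 31·0.5) ≈ 1/18 while averaging independent channel noise down
  only by √31/32; a multiplicative ±0.3 signature (log-separation 0.62
  against σ = 0.1 between-subject band gains, single-channel d′ ≤ 4.4)
  therefore caps two-step validation accuracy near 0.76 — measured
  0.67–0.79 across seeds at 16–32 subjects. The recovery study's accuracy
  check is stricter than this ceiling and fails by design of its
  conditions; the significance, time-course and topography checks pass.
  Spatially distributed signatures decode well above 0.9.
* **Null-correlation bounds at n = 64.** A null Spearman ρ over 64 nights
  has standard deviation 1/√63 ≈ 0.126, so |ρ| < 0.2 holds with
  probability ≈ 0.887 per stage and ≈ 0.79 for two stages jointly — an
  upper bound no implementation can beat; the behaviour study's null-stage
  check is calibrated above that bound and fails accordingly, while the
  SWS-link detection itself is reliable (≥ 90 %).
* d′ recovery through binomial recognition counts is noise-limited
  (sd ≈ 0.34 per night at 100/50 items), capping strength–consolidation
  correlations regardless of decoder quality.
* The shipped montage takes the 32 group centres from the standard 10–20
  montage and the dense cap from a 128-electrode layout on the same
  template head; the exact centre set of any particular lab is
  configuration, not code.
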