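# Methods

This note documents the models, parameters and numerical choices behind
gazebench, and what the synthetic validation does and does not establish.

## Screen geometry and units

All positions are stored in screen pixels and converted to degrees of
visual angle (dva) per axis. The study screen (1920 × 1080 px spanning
50 × 24 dva at 80 cm) is anisotropic: 38.4 px/deg horizontally,
45.0 px/deg vertically, so every angular quantity (blur SDs, merge
amplitudes, distances) is converted with per-axis factors rather than a
single average. Pixels are 0-based, origin top-left; pixel *i* covers
[i, i+1), continuous fields are sampled at pixel centres i + 0.5, and
fixation coordinates are binned to pixels by truncation (floor). Tests
mostly run on a 480 × 270 px screen spanning the same 50 × 24 dva, which
preserves all angular relationships at a fraction of the cost.

## Synthetic cohort generator

The generator emulates 10 s of free viewing logged at 60 Hz. Gaze targets
come from a spatial mixture: one central Gaussian component (SD 3 dva) —
participants start at the screen centre — and eight object-like clusters
(SD 1.5 dva, unequal weights, pairwise separations > 5 dva). The
*ordering schedule* makes the mixture index-dependent: the probability
that fixation k targets the central component is
`0.10 + 0.85·exp(−(k−1)/2)`, i.e. ≈ 0.95 for the first fixation decaying
to the 0.10 floor, with the remainder spread over clusters in proportion
to their weights. This reproduces the qualitative early-focal /
late-dispersed structure of free viewing; it is a generative convenience,
not a fitted model.

Fixation durations are log-normal (median 250 ms, log-SD 0.4, floored at
80 ms) — conventional values, since the duration distribution of the
emulated data is not published; saccades are modelled as 3-sample linear
interpolations between centroids (the simplest shape that yields
realistic inter-fixation samples); a viewing tail shorter than 100 ms is
absorbed into the final fixation so no unrecoverable fragment is emitted.
Successive targets are rejection-sampled to stay on-screen and at least
2 dva from the previous fixation: sub-amplitude gaze shifts are treated
as part of the same fixation, matching the downstream 1 dva merge scale.

Measurement noise is isotropic Gaussian per sample with configurable
radial RMS (default 0.68 dva; per-axis SD = RMS/√2). For i.i.d. noise
this implies a within-fixation sample-to-sample RMS (the usual RMS-S2S
precision measure) of 0.68·√2 ≈ 0.96 dva — note the √2: a recording whose
*precision* statistic should equal 0.68 dva would use
`noise_rms_dva = 0.48`. The default follows the per-sample-RMS
convention of the configuration parameter. Data loss is modelled as runs:
a per-second hazard of 0.01 starts a run whose length is geometric with
mean 0.5 s, flagged by an explicit `valid` column (never sentinel
coordinates), giving ≈ 0.4–0.8% loss. Demographics default to the
marginal age-bin composition of the credible-demographics sample (nine
6-year bins, 6–59, heaviest at 24–29) with gender proportions 0.556 /
0.444 (man / woman); `group_bias` multiplies the central-component odds
for named groups (a gender value or an age-bin label), which is how the
stratification-recovery experiments inject a known demographic effect.
Per-participant RNG streams are spawned from the cohort seed, so cohorts
are byte-identical under a fixed seed.

What the generator does **not** emulate: saccade dynamics (velocity
profiles, overshoot), pursuit and blinks, calibration drift/offset
(accuracy), asynchronous sample timing, and any image-content coupling —
the "scene" exists only as the generating mixture. Passing tests
therefore establish that the pipeline recovers structure *of this kind*
from noise of the stated magnitude, not that the detector matches any
particular commercial tracker's event stream.

## Fixation detection

The detector is built for noisy, low-rate data (0.68 dva per-sample RMS
at 60 Hz), where single-interval velocity thresholding fails. Two stages:

1. the valid-sample trace is median-filtered (3 samples) per axis;
2. for every inter-sample boundary a *transition statistic* is computed:
   the dva distance between the mean position of up to 5 samples before
   and after the boundary. Saccade boundaries are peaks of this statistic
   above an adaptive threshold, median + 3.5·MAD of the statistic. Because
   saccade bumps can cover a third of all intervals, the median and MAD
   are re-estimated up to three times on sub-threshold values only, so the
   threshold tracks the noise floor rather than the saccade mixture; a
   floor of 0.3 dva guards the noise-free limit where the MAD collapses
   to zero. Two samples either side of each detected boundary are
   excluded, and the remaining runs (split additionally at data-loss gaps
   longer than 75 ms) become candidates with raw-sample centroids.

Post-processing applies the study rules in a fixed, tested order:
candidates closer than 1 dva (Euclidean distance between adjacent
centroids, per-axis px/deg) and separated by less than 150 ms are merged
iteratively, *closest pair first* (duration-weighted centroids), and only
then are candidates shorter than 60 ms discarded. Merging first mirrors
the intent of repairing intermittent saccade candidates: two sub-60 ms
fragments of one fixation should survive as their merged whole. The
pipeline is idempotent on its own output, and raising the duration
threshold can only reduce the number of fixations.

Selection keeps, per participant, the first 18 fixations that are
on-screen and start at/after the viewing onset, re-indexed 1..18;
participants with fewer are excluded. The fixed count of 18 is the
operative rule; the equivalent median − 1.5·MAD cut on fixation counts is
exposed for reporting only. The demographic-credibility filter marks a
participant ineligible for demographic analyses (still usable pooled) if
*either* the recording contains a loss run above 5 s or either
demographic field still equals the entry default (non-binary gender /
birth year 2000) — the either-reading is deliberate: an unchanged default
on one field is already evidence the demographics were not entered.
Quality metrics: precision is the median over fixations of the
within-fixation RMS-S2S displacement in dva (per-fixation median chosen
where the convention is ambiguous), loss is the invalid-sample fraction
plus the longest loss run.

Validated contract (study conditions: 0.68 dva noise, default cohorts,
100 participants): ≥ 95% of ground-truth fixations matched one-to-one
with centroids within 1 dva and onsets within 50 ms; measured 98–99.5%
across seeds, median onset error ≈ 1 sample.

## Maps

*Fixation map*: count grid of fixation pixels convolved with a Gaussian
of SD 1 dva per axis (38.4 / 45.0 px on the study screen), truncated at
4 SD, reflective boundaries (keeps mass for edge fixations; total mass =
fixation count). *Central bias*: anisotropic Gaussian centred on the
screen, SD = screen half-dimensions (960, 540 px), evaluated at pixel
centres and hence exactly flip-symmetric. *Meaning map*: per scale
(patch diameters 1.5/3/7 dva, elliptical in pixels), each pixel averages
the ratings of all covering patches; scale maps are combined by an
unweighted mean over covering scales (the source procedure's exact
weighting is not restated in the emulated study); pixels covered by no
patch take the grid minimum. *Fixture model*: a spectral-residual
salience operator (mean-subtracted image, 3 × 3-smoothed log-amplitude
spectrum, squared back-transform, light blur) — a deterministic in-repo
stand-in for external model predictions in end-to-end runs; the DC
spectral component is zeroed explicitly so the output is exactly
invariant to adding a constant to the image. Grids are saved losslessly
as .npy/.txt with a JSON geometry sidecar, or as min–max-scaled 16-bit
PNG (lossy) for inspection.

Whether the emulated study used per-axis or isotropic px/deg for its
1 dva kernel is not stated; per-axis is used throughout because a single
factor would distort one axis by 17%. Kernel size is a parameter
(`MapParams.blur_sd_dva`) for robustness checks.

## Scoring

NSS z-standardises with the population (n-denominator) SD — at 2 M pixels
indistinguishable from the sample SD, but it makes small-grid unit tests
exact. The mean is pooled over all fixations of all participants; the
only per-participant averaging is in the single-observer baseline, where
each participant's fixations are scored against the blurred map of all
others and the per-participant scores are averaged unweighted
(leave-one-out). Zero-variance grids score 0 with a warning flag rather
than erroring, so degenerate fixtures flow through benchmarks.
Improvement scaling is 100·(raw − lower)/(upper − lower) and may
legitimately leave [0, 100].

Group scores always pool the member fixations of a stratum (consistent
with building one spatial distribution map per group) — never averages
of per-participant NSS. Age bins are the nine 6-year bins over ages 6–59;
out-of-range ages are flagged excluded. The across-age baseline is the
unweighted mean of the nine bin scores ("mean of bin means"), so
duplicating a bin's participants changes nothing; deviations per model
sum to zero by construction. "Explained %" rescales a model's bin NSS
between the bin's own single-observer (0%) and fixation-map (100%)
anchors — the caption-level description is followed literally, with
bin-specific anchors. Fixation-index benchmarks rebuild the fixation set
per k (cumulative: indices ≤ k; per-index: index = k, exactly one
fixation per participant by construction of the selection) and re-anchor
per k, additionally reporting NSS divided by the per-k upper bound.

## Inferential layer

Paired t-tests are standard two-sided tests on differences, with Cohen's
d = t/√n and a plain (unadjusted) 95% CI of the mean difference — the
CIs accompanying Bonferroni-corrected contrasts are deliberately plain,
matching the common reporting convention. The JZS Bayes factor places a
Cauchy prior with scale r = √2/2 (the standard default) on the
standardised effect size and integrates the noncentral-t likelihood over
it by adaptive quadrature, split at 0 and at the maximum-likelihood
effect size for stability at large |t|; an independently written g-prior
(inverse-gamma mixture) quadrature agrees to better than 0.1% over a
(t, n) grid. The repeated-measures ANOVA computes the classical
within-subject sums of squares; the Greenhouse–Geisser epsilon comes from
the double-centred sample covariance of the within-subject scores,
clamped to [1/(k−1), 1], with df1 = ε(k−1) and df2 = ε(k−1)(n−1) exactly.
Effect size is SS_cond/(SS_cond + SS_err) (partial η², equal to the
effect-vs-error η² for a single within factor). Degenerate inputs
(constant matrices, all-identical differences) raise a dedicated error;
the one benign case — identical conditions across varying subjects — is
defined as F = 0. Bonferroni correction multiplies by the full number of
pairwise contrasts (36 for nine bins), capped at 1.

## Problem sizes and determinism

Default analyses use 150-participant cohorts (≈ 2 700 analysed
fixations); the stratification-recovery experiment uses 20 replicates of
400 participants with a doubled central component for the 30–35 bin
(positive and maximal deviation in 19/20 replicates); detector-recovery
checks use 100 participants. All randomness flows through
`numpy.random.Generator` streams spawned from explicit seeds; identical
configs produce byte-identical cohorts and identical output tables. The
pipeline writes all tables only after every stage has succeeded, plus a
provenance record (config hash, package versions).

## Known limitations

* The detector is validated against the package's own generative model;
  real trackers produce correlated noise, drift and blink artefacts it
  has not been tested on.
* The meaning-map aggregation covers rating aggregation only; collecting
  ratings, and the published saliency models themselves, are out of scope
  (external grids are consumed as files).
* Accuracy (systematic gaze offset) is not estimated anywhere; the
  emulated setup cannot measure it, and the generator does not model it.
* The e2e statistics demonstrate machinery, not power: with only the
  in-repo fixture models as "subjects", the paired designs have n ≈ 3.
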