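# gazebench

Benchmarking saliency-map predictions against cohort gaze data — from raw,
noisy gaze samples to fixation events, spatial fixation maps, baseline
models, NSS scoring, and stratified analyses across gender, age bins and
fixation index.

## The problem

Saliency models predict where people will fixate in a scene as a dense
spatial map. They are usually validated against fixation maps pooled from a
few dozen (mostly young, mostly student) observers viewing many images,
which leaves two generalisation questions open: do the predictions hold
*across people* (children, older adults, men vs women), and *across
fixations* (is the first fixation drawn to the same places as the tenth)?
Answering either needs fixation maps per demographic group and per fixation
index, hence very large cohorts. This package implements the full analysis
pipeline for that kind of large-cohort benchmark, together with a synthetic
cohort generator with known ground truth so every stage is testable without
the original recordings.

## What is computed

The evaluation metric is **Normalized Scanpath Saliency (NSS)**. For a
salience grid S and fixation locations {(x_i, y_i)}, the grid is
z-standardised over all pixels (population SD),

    Z = (S − mean(S)) / sd(S),      NSS = (1/N) Σ_i Z[y_i, x_i],

so 0 is chance level and the self-NSS of the cohort's own smoothed
fixation map (1 dva Gaussian blur of the discrete fixation locations)
is the empirical upper bound for any model. Baselines: an aspect-skewed
Gaussian **central bias** (SD = screen half-dimensions), the leave-one-out
**single observer** score, and a **meaning map** aggregated from patch
ratings at 1.5/3/7 dva scales. Scores are conventionally rescaled between
the central bias (0%) and the fixation map (100%):

    improvement% = 100 · (NSS − NSS_cb) / (NSS_fix − NSS_cb).

Upstream, raw 60 Hz gaze (per-sample noise ≈ 0.68 dva RMS) is turned into
fixations by a two-stage robust detector (median filter + two-window
transition statistic with a MAD-adaptive threshold), followed by the
study's post-processing rules: merge events closer than 1 dva, discard
events shorter than 60 ms, keep each participant's first 18 on-screen
fixations, exclude participants with fewer. Downstream, the stratified
analyses score pooled group fixations per gender and per 6-year age bin
(6–59) with bin-specific anchors, average *across bin means* to resist
class imbalance, and benchmark cumulative (indices 1..k) and per-index
(index = k) fixation sets. The inferential layer provides paired t-tests
with Cohen's d = t/√n, default-prior JZS Bayes factors (Cauchy scale
√2/2, numerical integration), Greenhouse–Geisser-corrected
repeated-measures ANOVA and Bonferroni pairwise contrasts.

## Worked example

Simulate a cohort, detect fixations and benchmark a model grid:

```python
from gazebench.synthetic import SyntheticCohortConfig, simulate_cohort
from gazebench.preprocess import preprocess_cohort
from gazebench.evaluate import benchmark_table

recordings, truth = simulate_cohort(SyntheticCohortConfig(n_participants=150, seed=20230))
fixations, exclusions, quality = preprocess_cohort(recordings)
bench = benchmark_table({"generating_mixture": truth.generating_salience_grid()}, fixations)
print(bench[["map_id", "nss", "improvement_pct"]])
```

The numbered drivers under `analysis/` run the same steps as a narrative
(`python analysis/01_simulate_cohort.py`, then 02…07), writing their tables
under `results/`. On the default 150-participant cohort they print:

```
            map_id stratum  n_fix    nss  lower  upper  improvement_pct
      fixation_map     all   2700  1.681  0.455  1.681          100.000
      central_bias     all   2700  0.455  0.455  1.681            0.000
   single_observer     all   2700  1.631  0.455  1.681           95.928
  fixture_spectral     all   2700 -0.053  0.455  1.681          -41.357
generating_mixture     all   2700  1.675  0.455  1.681           99.493
       meaning_map     all   2700  1.620  0.455  1.681           95.002
```

The fixation map and central bias land at exactly 100% and 0% by
construction; the cohort's true generating mixture nearly attains the
upper bound; the spectral-residual fixture model (which sees only image
structure, not the cohort) performs below the central bias. The
fixation-index step shows the early-focality pattern — the upper bound
falls from 3.16 (k = 1) to 1.68 (k = 18) and the central-bias NSS from
1.47 to 0.46 as fixations disperse — and the stratification step recovers
an injected demographic bias: when one age group is generated with a
doubled central-bias component, that group's central-bias deviation
(+0.105) is the largest across all nine bins.

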