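# Methods

`crowddev` simulates and analyses a child-friendly psychophysical
experiment measuring visual acuity and foveal crowding across development.
This note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## Task model

The simulated task is a four-alternative forced-choice (4AFC) gap
identification: on each trial the observer reports which of four directions
a target's mouth-like gap faces. Performance as a function of gap size
`s` (arcmin) follows a cumulative Gaussian rising from the 25 % guessing
rate to ceiling:

    p(s) = 0.25 + 0.75 * Phi((s - mu) / sigma)

The *threshold* is defined as the gap yielding 62.5 % correct — midway
between chance and ceiling — which under this parameterization is exactly
`mu`. Simulated observers add a lapse mechanism, `p' = (1 - lambda) * p +
lambda * 0.25`, modelling stimulus-independent attentional errors; lapses
exist only in the generator, because the analysis-side fit deliberately has
two free parameters (midpoint and slope) with a fixed ceiling of 1.

Three conditions are modelled per participant: **unflanked** (acuity),
**flanked-same** (target surrounded by same-polarity flankers; crowding) and
**flanked-different** (opposite-polarity flankers; partial release from
crowding). Stimuli scale rigidly with the gap: diameter = 5 × gap, flanker
centre-to-centre separation = 1.1 × diameter, Weber contrast 0.75. A
flanked gap-size threshold therefore converts deterministically to the
spatial extent of crowding (centre-to-centre separation at threshold,
5.5 × gap).

## Adaptive procedure

Each block is a QUEST Bayesian staircase: a posterior over log10 threshold,
initialized as a Gaussian prior (default guess 2.0′, SD 0.4 log units, 201
grid points over [−1.5, 1.6] log10 arcmin), updated by Bayes' rule after
every scored trial and read out as the posterior mean. The assumed
psychometric function is a Weibull on log10 gap with slope β = 3.5,
guessing rate 0.25 and lapse 0.01, offset so it passes through the 62.5 %
convergence criterion exactly at the threshold parameter. β = 3.5 was
chosen so the assumed slope approximately matches a cumulative-Gaussian
observer with σ = 0.3·μ near threshold; with this match the 35-trial
posterior-mean estimate is unbiased to within ~2 % for thresholds
0.5′–4′.

Four child-friendly modifications wrap the staircase:

1. **Practice**: five trials at a fixed large gap (5.3′) precede each
   block. Fewer than 4/5 correct restarts the block (re-explanation), up to
   3 restarts; beyond that the simulated participant is flagged
   non-compliant. The 4/5 criterion is a package choice: it catches
   chance-level responders while tolerating a single lapse. Practice trials
   never enter analysis and never update the posterior.
2. **Catch trials**: on trials 5, 15, 25 and 35 the stimulus is presented
   at exactly 3× the current estimate, unjittered — easy trials that
   monitor attention. By default their outcomes update the posterior (they
   are informative) and they are retained for the later refit; both
   behaviours are configurable.
3. **Threshold by refit**: thresholds are not read off the staircase but
   re-estimated by fitting the full trial log (below).
4. **Size jitter**: every other main trial presents the estimate plus
   Gaussian noise with SD = 0.5 × estimate, widening the sampled size range
   for the refit. Draws are clamped below at 0.1 × estimate to keep sizes
   positive; clamping rather than resampling keeps one rng draw per trial,
   so trial streams stay aligned across parameter changes.

Sessions run 1–3 blocks per condition (default 2 for children, 3 for
adults), always starting with the unflanked condition. Sizes are continuous
arcmin; display pixel quantization is not modelled.

## Threshold fitting

Per participant × condition, all blocks are pooled; practice is excluded
and catch trials included. Continuous jittered sizes are collated into bins
whose edges sit at integer multiples of the bin width (default 0.25′, so
1.9′ and 2.1′ fall either side of the 2.0′ edge), recreating the
repeated-size structure of a quantized display. The two-parameter
cumulative Gaussian is then fitted by least squares weighted by the trial
count in each bin — not by likelihood — minimising

    sum_i n_i * (phat_i - [0.25 + 0.75 * Phi((s_i - mu)/sigma)])^2

with a bounded trust-region optimizer (analytic Jacobian), 5 starts seeded
from weighted data quantiles and range fractions, and a slope floor of
1e−3·mu against step-function degeneracy. The reported threshold is the
fitted curve's 62.5 % point, i.e. `mu` itself. With two 35-trial blocks
this recovers generating thresholds over 0.5′–4′ with median relative bias
under a few percent and log-log correlation r > 0.95.

## Synthetic cohorts

Cohorts mirror the study structure: 10/22/24/14/19 children across the age
ranges 3–4, 5–6, 7–8, 9–10 and 11–12 years plus 30 adults (ages drawn
uniformly within range; adults in 18–38 and collapsed to age 18 for
trajectory fitting). Ground-truth thresholds follow logistic developmental
trajectories

    T(a) = L + E / (1 + exp((a - a0) / k))

with defaults (package calibration — the absolute scale is a documented
convention, the *ratios* are the calibrated anchors):

| condition     | L (adult, ′) | E (′) | a0 (y) | k (y) |
|---------------|-------------|-------|--------|-------|
| unflanked     | 0.8         | 0.6   | 4.0    | 0.8   |
| flanked-same  | 1.12        | 1.36  | 5.2    | 0.8   |

These place the flanked/unflanked threshold ratio at ~2.0 at age 3.8 and
~1.4 in adults, with acuity maturing by 5–6 years and crowding by 7–8
years. Flanked-different thresholds default to the exact midpoint of each
participant's unflanked and flanked-same thresholds (50 % generative
release); an explicit third trajectory may be supplied instead and is
clamped into that interval.

Between-subject scatter is lognormal with CV 0.25 on the unflanked
threshold (the CV is a free modelling choice, exposed in the spec of every
cohort), combined with a lognormal crowding-*ratio* factor (CV 0.12,
clamped at ≥ 1), so the ordering unflanked ≤ flanked-different ≤
flanked-same holds for every participant by construction. Observer slopes
are σ = 0.3 × threshold and the generator lapse rate is 0.01. Each
participant derives from an independent seed-sequence substream, so cohorts
are reproducible and adding participants never perturbs existing ones.

What the generator does **not** emulate: learning or fatigue across blocks,
fixation instability and eye movements, display quantization, response-
modality effects, and demographic covariates. Passing recovery tests
therefore demonstrate that the analysis chain is unbiased and well-calibrated
for stationary observers with the assumed psychometric shape — not that the
procedure is robust to every behaviour of real children.

## Trajectories, contrasts, meta-analysis

Development is summarized by a four-parameter logistic fit of thresholds
(or derived metrics) against age, least-squares with multi-start.
Uncertainty bands resample participants with replacement *within* age
groups (preserving the cohort's age structure), refit each of 1000
bootstrap cohorts (warm-started from the point estimate), and take per-age
2.5/97.5 percentiles; the band is widened if necessary to bracket the
point-estimate curve. On synthetic cohorts of ~60 participants the 95 %
band contains the generating curve at well over 90 % of evaluated ages.

Planned contrasts compare each child age bin to adults with Student's
independent-samples t-test (pooled variance, df = n1 + n2 − 2 — the form
consistent with the study's printed degrees of freedom) and Cohen's d using
the pooled SD. Contrasts are planned, so no multiple-comparison correction
is applied. The omnibus mixed-design ANOVA is intentionally out of scope;
the age × condition interaction is visible in the ratio trajectory.

The meta-analysis stage consumes user-supplied per-age study tables in any
supported crowding metric, converts the package's own thresholds into that
metric (gap acuity, diameter, centre-to-centre, edge-to-edge, flanked/
unflanked ratio or difference), min–max normalizes every study onto the
reference dataset's range (the simplest reading of "span the same range";
affine, order-preserving, idempotent), pools values within common age bins
(adding a 13–17-year bin), and contrasts each child bin against the pooled
adult values. Normalization operates on age-binned means by default, with a
raw-value option; a one-value-per-study pooling variant is also provided
since the exact pooling composition is an open choice. No inverse-variance
weighting is applied — studies pool as normalized values.

Release from crowding is computed per participant as
`100 × (flanked_same − flanked_diff) / (flanked_same − unflanked)` before
any averaging, keeping acuity and crowding variance separate; estimates
outside [0, 100] (possible when the crowding elevation is small relative to
fit noise) warn and are clipped to a reporting range of [−50, 150].
Per-participant release is undefined (and excluded) when the fitted
flanked-same threshold does not exceed the unflanked threshold.

## Numerical and reproducibility notes

- All randomness flows from explicit `numpy` `Generator`s /
  `SeedSequence`s; a stored pipeline config plus seed reproduces every
  artifact byte-identically.
- Posteriors are renormalized after every update and checked to sum to 1
  within 1e−9; an all-zero likelihood raises rather than silently
  renormalizing.
- All tabular artifacts are CSV (diffable); configs are YAML; the pipeline
  writes a manifest with a config hash, seed and stage timings.
- Problem sizes used by the validation suite: threshold recovery aggregates
  200 replicate seeds × 60 observers; bootstrap-band calibration uses 50
  replicate 60-participant cohorts at 1000 resamples each; the release
  check uses 30-child cohorts at 2 blocks per condition.

## Known limitations

- The weighted least-squares objective (chosen to mirror the analysis it
  reimplements) is statistically less efficient than a binomial likelihood
  fit and can be pulled by heavily-weighted ceiling bins when the data are
  inconsistent.
- Release estimates for observers with small crowding elevation (adults)
  are noise-dominated at realistic trial counts; cohort means remain
  unbiased but individual values are unstable.
- The staircase estimate (as opposed to the refit threshold) is mildly
  sensitive to mismatch between the assumed Weibull slope and the
  observer's true slope; the refit is the supported threshold estimator.
- The logistic trajectory assumes a monotone decline to a fixed adult
  asymptote; it cannot represent non-monotone development.
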