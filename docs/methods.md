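# Methods

This note records the models, conventions and design choices behind the
package, in the order data flows through it.

## The estimand and its conventions

For stay *i* with an initial antibiotic course of *m* consecutive days
(starting on ICU day 1) and realised length of stay *Y*, the estimator asks,
for every **antibiotic day** *t* (the treated days 1..m plus the first
antibiotic-free day m+1 when it falls inside the stay):

- **stop on day t** — day *t* is the first antibiotic-free day, i.e. the
  counterfactual course length is t−1 and m−t+1 treated days are avoided;
- **continue on day t** — antibiotics are given on day *t*; on treated days
  this is the factual action, on the cessation day it extends the course by
  one day.

This convention matches the donor pools: a stay joins the *stop* pool of day
*t* exactly when its cessation day is *t*, so the donors for a stop-at-t
estimate experienced precisely the counterfactual course being queried.
Consequences worth stating explicitly:

- The per-day role taxonomy follows directly: treated days are stop-impact /
  continue-control; the cessation day is stop-control / continue-impact;
  stays discharged on antibiotics contribute no stop-control day.
- The simulator's ground-truth stop counterfactual is floored at the day
  index on treated days (the stay cannot end before the day on which the
  decision is taken); on factual rows (continue on a treated day, stop on
  the cessation day) the counterfactual equals the realised LOS exactly,
  even when a fractional LOS puts it just below the day index. Under a zero
  cessation effect the two counterfactuals therefore coincide up to that
  floor: cf_stop = max(day, cf_continue).

## Synthetic cohort generator

One latent severity process drives everything observable. Per stay:

- **Severity** s₁ ~ lognormal (moment-matched to mean 2.6, SD 1.9), decaying
  daily by 18% with N(0, 0.35) innovations, floored at 0.
- **Antibiotic policy**: treat daily until severity first drops below 1.0,
  plus ±1 day of prescriber variability (probability 0.25 each side),
  clipped to 1–21 days. The jitter is essential, not cosmetic: without it
  the stop and continue populations at day 2 have *zero* severity overlap
  (stopping at day 2 ⇔ s₁ below threshold), and no matching estimator can
  be calibrated at that day.
- **Baseline recovery time** (course-free LOS), two discharge regimes:
  with probability 0.58 a *fast-track* stay steps down from the ICU at or
  before the end of its course (baseline ~ U(0, (1−e)·planned)); otherwise a
  *complicated* stay has baseline 0.2 + 0.37·s₁ + lognormal(ln 2.9, 0.7)
  tail. The mixture is what lets the cohort have both a strong LOS/course
  rank correlation and ~58% of stays leaving the ICU while still on
  antibiotics.
- **Realised LOS** = baseline + e·course, where e = `cessation_effect_los`
  (days of LOS per treated day; default 0.8, the recoverable parameter) and
  the course is truncated at discharge by a short fixed-point iteration.
- **Mortality** ~ Bernoulli(sigmoid(c + coef·z(s₁))), with the intercept c
  solved by bisection so the cohort-mean probability equals the configured
  rate for any severity draw.
- **Features**: 42 dynamic channels, each an offset + linear + saturating
  (tanh) readout of the day's severity **plus a readout of the stay's
  standardised baseline recovery time** (`prognosis_obs_coef`, default 1.5),
  plus N(0, 0.4) noise; one static age channel. The prognosis readout is an
  identifying assumption made explicit: if the recovery tail were latent,
  stop-pool donors would be selected on it and every matching estimator
  would be biased — observability is what the method's ignorability
  assumption *means* in generative terms. Feature coefficients come from a
  fixed generator-level RNG so variables keep the same semantics across
  seeds (a model trained on one cohort is applicable to another, as with
  real lab panels); the config seed drives only patient-level sampling.
- **Missingness**: feature-wise Bernoulli (default rate 0.3), optionally
  severity-linked via `informative_missingness`.

Defaults were calibrated once, before any downstream test was written,
against the joint structure of a large real ICU antibiotic cohort: Spearman
ρ(LOS, course) ≈ 0.75 (target band 0.65–0.79), course 4.5 ± 3.3 d, ~41% of
stays ceasing antibiotics in-ICU, mortality equal to the configured 18.6%.
Mean LOS runs ≈ 6.0 ± 4.4 d, slightly above the real cohort's 5.63; the
binding targets take precedence.

What the simulator does **not** emulate: real feature semantics (labs,
vitals, ventilation settings), antibiotic courses beginning mid-stay or
pre-ICU (every course starts on day 1), in-stay re-treatment (the
preprocessing handles it; the generator never produces it), temporally
dynamic labels, and informative missingness by default. Passing tests
therefore show the estimator is correct *when its identifying assumptions
hold*; they say nothing about confounding by unmeasured prognosis in real
data, where those assumptions must be argued clinically.

## Preprocessing

Long-format events are aggregated per (stay, day) by the mean (median
configurable), on a contiguous 1-based day grid. Derived treatment
variables: per-day cumulative consecutive-treatment length, the initial
course, the cessation day, and a re-treatment flag. Cohort filter: initial
course within 1–21 days and per-day missing fraction ≤ 50% on **every** day
(the stricter of the two readings of a per-day rule; configurable).
Normalisation uses training-set statistics only: clip to the train 1st/99th
percentiles (outlier handling that preserves the regular day grid), forward
fill within stay, z-score, remaining leading-missing cells set to 0 (the
training mean) with their indicator left set. The stay-level 70/15/15 split
uses largest-remainder rounding over a seeded permutation. Mortality
training oversamples positive stays 3 extra times (sampling index only);
4·p/(4·p+1−p) ≈ 0.50 positive fraction at p = 0.186.

## Autoencoder

Implemented directly in NumPy (float64) with exact backpropagation through
time and Adam; training is bit-reproducible for a fixed seed and checked
against finite differences in the test suite. Architecture: bi-directional
LSTM encoder (default hidden 64 per direction, 1 layer), linear projection
to a 32-dimensional embedding, an input-repeated LSTM decoder emitting the
reconstruction in reversed order, and a linear outcome head (sigmoid for
mortality). Variable-length sequences are padded and masked; padded steps
and unobserved cells are excluded from the reconstruction loss;
missing-value indicators are appended to the input. The supervised loss is
applied to the final-day embedding by default (one label per stay);
`supervision="per_day"` additionally supervises one uniformly drawn prefix
day per stay per step. Per-day embeddings at inference re-run the encoder on
each prefix 1..t, which guarantees no future leakage by construction.
Loss weights default to (1, 1); the relative weighting and the per-day
supervision choice are deliberately exposed because neither is settled.

## Synthetic control

Ridge weights are the closed-form minimiser w* = (XᵀX + λI)⁻¹Xᵀz of the
penalised loss with λ = 1 (the unit penalty of the written loss), donors are
the k = 10 Euclidean-nearest pool members with ties broken by ascending
stay id then day, and the outcome is the weighted average of donor labels
with weights renormalised to sum to one (raw weights are recorded; a
zero-sum falls back to uniform with a warning). No non-negativity
constraint is imposed — a deliberate divergence from classic synthetic
control, matching the penalised least-squares formulation; negative weights
allow mild extrapolation beyond the donor label range before normalisation.
As λ→∞ the normalised weights converge to being proportional to each
donor's projection xⱼᵀz (uniform only when projections are equal). The
default donor population is the full dataset minus the subject's own stay
(leave-one-out); a test-only donor mode exists for leakage-sensitive runs.
Disabling segregation merges all pools (the temporal-ablation mode) and
measurably degrades control-day RMSE.

## Evaluation

μΔ, MAPE and MAE average within stay first, then across stays; RMSE is
pooled over all qualifying days (a global average). MAPE excludes zero-label
days with a logged count. The rank-sum test feeds pooled qualifying-day
label and estimate samples (per-stay means are an alternative the caller
can compute from the returned per-stay deltas). Mortality classification
metrics use a 0.5 threshold (configurable) and percentile bootstrap 95% CIs
(default 1,000 resamples of the sample size) for both tasks. What-if
queries ("stop after day 7") select stays with courses longer than the
cutoff and use the stop-scenario estimate at day cutoff+1 — the first
hypothetical antibiotic-free day, whose stop pool contains exactly the
stays treated `cutoff` days — comparing against the realised outcome as the
factual continue arm; an `equal` course filter supports the
shorter-than-standard-course variant.

## Study conditions for the benchmark experiments

Problem sizes are desk-scale choices, fixed in `abxcease.experiments`:
effect recovery uses one 2,000-stay cohort per effect value (e ∈ {0, 0.8})
with 20 training epochs; null calibration uses 20 replicate 1,000-stay
cohorts with the encoder retrained per replicate (15 epochs) — retraining
matters, since transferring one trained model across cohorts leaves a
~0.2-day bias that the pooled rank-sum test detects at n ≈ 3,500; the
ablation uses five 1,000-stay seeds. Under these conditions the estimator's
control-day |μΔ| stays under 15% of the cohort LOS SD, the e = 0.8
stop-impact delta is recovered within 30% relative error, and the null is
non-significant in ≈ 95% of replicates.

## Known limitations

- The estimator is only as good as the embedding: donors are matched on a
  learned representation, and residual matching error shrinks estimates
  toward the local donor mean (the measured ~20% attenuation of the true
  effect has this origin, concentrated on early days and on subjects whose
  counterfactual is floored).
- Donor pools condition on ICU presence at day *t*, which truncates the
  donor label distribution from below; this is inherent to the design.
- The rank-sum test compares labels with conditional-mean estimates, which
  differ in dispersion even for a perfect estimator; at very large n it
  will flag that difference regardless of calibration.
- Mortality estimation shares the machinery but the simulator gives
  cessation timing no causal effect on death, so only calibration (not
  effect recovery) is testable for that outcome.
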