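# Methods

`nicheval` re-creates, on fully synthetic data, a niche-model construction
and assessment workflow for plot-level presence/absence data: a five-method
statistical ensemble is fitted per species, its single-axis response curves
and bivariate niche surfaces are produced for expert inspection under two
background-covariate strategies, model fit is quantified by repeated
hold-out AUC, and expert scores are analysed with confusion-matrix
agreement statistics. This note records the models, the defaults and the
open choices.

## The synthetic environmental space

Plots carry seven covariates mimicking the gradients of a national
vegetation-plot database:

| axis | kind | range | role |
|---|---|---|---|
| precipitation | continuous | 500–3000 mm | climate |
| temperature | continuous | 4–12 °C | climate |
| seasonality | continuous | 0–20 (index) | climate |
| veg_height | ordinal | 1–8 (1 = <10 cm sward, 8 = tall canopy) | succession/disturbance |
| substrate_ph | continuous | 3–8.5 | substrate |
| fertility | continuous | 0–10 (index) | substrate |
| wetness | continuous | 0–12 (index) | substrate |

Covariates are drawn from a Gaussian copula: latent 7-dimensional normal
with a fixed correlation matrix (wet climates ↔ wet soils +0.45, pH ↔
fertility +0.5, precipitation ↔ temperature −0.35, …), pushed through the
normal CDF and affinely mapped to each range; the ordinal axis is
quantile-binned into its eight integer levels. The matrix is validated
symmetric PSD with unit diagonal; a non-PSD matrix is rejected.

## Virtual species truth model

A species is a weighted mixture of product-Gaussian niche modes on the
probability scale:

p(x) = p_max · Σ_k w_k · Π_j exp(−((x_j − o_kj)/b_kj)² / 2),  Σ w_k = 1.

Working on the probability scale (not the logit scale) makes `p_max`, the
optima and the breadths exact, transparent targets for parameter-recovery
tests. Occurrences are Bernoulli draws from p(x). `calibrate_prevalence`
rescales `p_max` so the expected prevalence over a given plot table matches
a target exactly (expected prevalence is linear in `p_max`); unreachable
targets are rejected with the achievable bound, which is the mean niche
kernel over the table.

Two consequences of the seven-axis product shape drove the archetype
design and are worth knowing when adapting it:

1. **Prevalence is bounded by niche volume.** The mean product kernel over
   the space shrinks roughly geometrically with the number of selective
   axes; a species narrow (0.3 × range) on all seven axes cannot exceed a
   few percent prevalence no matter how high `p_max` is.
2. **No model can beat the truth's own discrimination.** Hold-out AUC is
   capped by the Bayes AUC of the generating surface, which depends only
   on the kernel shape (any `p_max` rescaling is rank-preserving). A
   breadth of half the axis range on every axis caps AUC near 0.67; the
   sharp-axes archetypes below have Bayes AUC ≈ 0.88–0.93.

### Default campaign archetypes (n_plots = 5,000, master seed in config)

- `common_unimodal` — generalist; mid-range optimum, breadth 0.5 × range on
  every axis, target prevalence 0.25. Deliberately weakly discriminable
  (Bayes AUC ≈ 0.67): a realistic foil, not a recovery benchmark.
- `rare_unimodal` — well-specified specialist; breadth 0.18 × range on
  temperature, pH and fertility, indifferent (breadth = full range,
  mid-centred optimum) elsewhere; target prevalence 0.05. This is the
  species used for parameter-recovery and hold-out AUC checks. On the
  indifferent axes the response is essentially flat, and a flat curve's
  argmax can sit anywhere in the range — at most 0.5 breadths from the
  mid-centred optimum by construction, so recovery tolerances remain
  meaningful on every axis.
- `bimodal_mire` — two-locus species modelled on a mire rush with distinct
  south-eastern (dry, base-rich) and north-western (wet, acid) loci; narrow
  on precipitation and pH (0.25 × range), sharpest on wetness (0.18), with
  unequal mode weights 0.7 / 0.3 and target prevalence 0.04. Both loci
  demand wet substrates while the training-median wetness is intermediate,
  so solving fitted models with median backgrounds both depresses the
  surface and misplaces its top-decile region — the mechanism the
  background-strategy comparison measures. The unequal weights matter:
  additive ensemble members represent a diagonal two-locus surface as
  separable marginal bumps, and with asymmetric weights the weaker locus
  falls out of the top decile under median backgrounds while remaining
  prominent when models are solved at observed plot values.

A `make_null_species(prob)` factory gives a covariate-independent species
(one mode with effectively infinite breadths) for null-calibration checks.

## The ensemble

Five methods per species, each behind the same predict-probability
contract; stochastic methods draw seeds from the ensemble seed, so refits
are bit-identical. Fitting requires ≥ 20 presences and ≥ 20 absences
(configurable); a method that fails numerically is recorded and the
ensemble continues without it.

- **GLM** — logistic regression with linear + quadratic terms per axis;
  pairwise linear interactions are added when the species has ≥ 100
  presences.
- **GAM** — penalized cubic-spline additive logistic model (6 knots per
  axis); the spline-coefficient L2 penalty is selected by internal 3-fold
  cross-validation over a log-spaced grid.
- **MARS** — in-house adaptive hinge-basis fitter: greedy forward selection
  of reflected hinge pairs by least-squares residual reduction (knots at
  interior quantiles, default 10 per axis, ≤ 14 terms), backward pruning by
  GCV (penalty 3), then a logistic refit on the surviving basis.
- **NN** — single-hidden-layer perceptron (8 tanh units, lbfgs, α = 0.1).
  Two stabilisers: the average of 9 random restarts (lbfgs local optima
  otherwise shift single-axis response peaks), and minority-class
  upsampling to ~1:2 with the standard prior-correction of predicted
  probabilities back to the training base rate — without it the network
  localises rare species' optima poorly.
- **RF** — classification forest, 300 trees, `min_samples_leaf` 3,
  probability votes.

### Favorability rescaling

Raw probabilities are made comparable across species of different
commonness with the prevalence-odds rescale

F = (p/(1−p)) / (n₁/n₀ + p/(1−p)),

a strictly increasing bijection of [0,1] with F = 0.5 exactly when p equals
the training prevalence and F = p when classes are balanced. Because it is
monotone, AUC on raw and rescaled predictions is identical (asserted in the
test suite). Rescaling is applied per method, then averaged — whether the
original workflow rescaled before or after averaging is not documented, so
the choice is recorded here and in output metadata.

## Assessment artefacts

**Response curves.** For one axis, a 100-point grid spanning exactly the
training extremes (ordinal axes: integer levels only). Backgrounds either
fixed at training medians (`median`) or set to each training plot's
observed values and averaged (`observed`). The curve presented for
assessment is the unweighted mean of GLM, GAM, MARS and NN; RF is excluded
from the 1D average because its spiky, locally over-fitted curves are
uninterpretable to an assessor, and the test suite pins the average to the
mean of exactly those four. Optional 95% ribbons come from a seeded
bootstrap over plots (50 resamples by default) uniformly for all methods —
simpler than mixing analytic and resampling intervals, at some cost in
speed.

**Niche surfaces.** For an axis pair: under `observed`, the ensemble
average (all fitted methods, RF included by default, toggleable) evaluated
at every training plot as observed — a plot-wise point cloud in the plane;
under `median`, a 50 × 50 grid with the other five axes at medians. Each
surface carries the convex hull of the species' presences in the plane
(occurrence envelope) and the hull of all plots (sampled environmental
space); envelope ⊆ training polygon by construction. Hulls with < 3
non-collinear points are flagged degenerate and displayed as
points/segments rather than erroring. "Inside the top-decile region" is
operationalised as: some evaluation point with prediction ≥ the 90th
percentile lies within 0.5 niche breadths of the optimum on both displayed
axes.

## Hold-out validation

Per species and method: 10 random (unstratified) 75/25 splits; fit on the
training part, score the test part with the rank-statistic AUC
(Mann–Whitney form; ties count ½ — equal by a test-suite oracle to
trapezoidal ROC integration). Splits that leave either part single-class
are redrawn with logging, up to a bounded number of retries. The species
mean AUC averages over its fitted methods (the original report does not say
whether one method or the average was used; the choice is recorded in
output). Prevalence-vs-AUC displays use √prevalence and a degree-1 lowess
smoother (span 0.75) per assessment-category group; groups under 10 records
are skipped with a warning.

## Elicitation analytics

Species are allocated to two experts at random with a dual subsample of
size ⌈dual_frac · n⌉ (ceiling rule: 5% of 881 → 45) hidden inside both
sorted task lists. Paired scores over (species, axis) units are
cross-tabulated into a 4 × 4 confusion matrix (rows = second expert),
excluding pairs where either expert chose *cannot evaluate*. Overall
agreement = 100 · trace / total; per-category agreement restricts the
denominator to pairs in which either expert used the category:
100 · diag(c) / (row(c) + col(c) − diag(c)). Values are kept at full
precision with nearest-integer display rounding. The published
dual-assessment matrix ships as a packaged CSV fixture; its totals (290
evaluated pairs rather than 45 × 7 = 315) imply some units were excluded —
presumably *cannot evaluate* or missing assessments; both exclusion rules
are supported but the original rule is not recoverable. Note that the
overall rate is *not* a weighted combination of the per-category rates
(each off-diagonal pair is counted in two categories' denominators); the
test suite asserts this non-identity to guard against a plausible
implementation shortcut.

## Campaign orchestration and determinism

One master seed drives everything: each stage derives
`SeedSequence([master, crc32(stage_tags)])`, so stages can be re-run in
isolation and full campaigns are byte-reproducible (CSV floats are written
with a fixed format). Configs and species truths serialise to a flat
`key = value` text format that round-trips exactly.

## Problem sizes used in tests and the acceptance script

Simulation checks use up to 50,000 plots (Monte-Carlo prevalence) and
10,000 (copula correlation recovery); model-level checks run the default
campaign at n = 5,000 with the archetypes above; the null-AUC calibration
uses 20 seeded repetitions at n = 4,000 with the GLM (the cheapest method —
the null property is method-independent). These sizes give the Monte-Carlo
margins the assertions rely on while keeping a full run desk-scale.

## Known limitations

- The synthetic plots have no spatial structure: no dispersal limitation,
  autocorrelation, biotic interaction or observation bias. Passing recovery
  tests shows the workflow recovers *this* truth family, not that any real
  species' model is right.
- The copula gives uniform marginals; real survey databases oversample
  common conditions, which changes prevalence/AUC geometry.
- Expert scores are external inputs: the package analyses them (and ships
  the published paired-score matrix) but does not model the experts.
- Envelopes are convex hulls; concave (alpha-shape) envelopes are out of
  scope, so envelopes can overstate occupied environmental space.
- MARS is additive (no hinge products); interactions enter the ensemble
  through GLM interaction terms, NN and RF.
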