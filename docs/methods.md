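# Methods

This note documents the models implemented in `cpfe_progression`, the
assumptions behind them, the synthetic-cohort generator that exercises them,
and the numerical choices that a maintainer would otherwise have to reverse
engineer.

## The scientific setting

In idiopathic pulmonary fibrosis (IPF), 1-year relative decline in forced
vital capacity (FVC) is the standard surrogate for mortality. When emphysema
coexists with fibrosis (combined pulmonary fibrosis and emphysema, CPFE),
fibrotic traction can ventilate emphysematous airspaces, artificially
preserving expiratory volumes and superimposing heterogeneity on FVC
trajectories. The package implements the full analysis chain used to test
whether DLco (gas transfer) decline is the better mortality surrogate in
patients with extensive (≥10%) emphysema: CPFE classification from visual
lobar CT scores, unsupervised subtyping of fibrosis/emphysema progression,
mixed-model decline estimation, and adjusted survival modelling.

## Linear z-score subtype-and-stage model (`sustain`)

Twelve biomarkers — fibrosis and emphysema extent (% of lobe) in six lobes,
the lingula counted as the sixth — are z-scored by dividing by the
interobserver single-determination SD of each biomarker. Each biomarker is
modelled as a monotonically increasing piece-wise linear function of an
unobserved integer stage. A *z-score event* is the crossing of one grid
value z₁ < z₂ < … ≤ z_max; a subtype is an ordering S of all N events. At
stage k, biomarker i's expected value interpolates linearly between its
event anchors, is 0 before its first event, and ramps to z_max at stage N
only when z_max exceeds the last grid value.

Subject likelihood marginalises the stage with a uniform prior over
{0, …, N}:

  p(z | S) = (1/(N+1)) Σₖ Πᵢ Normal(zᵢ; g_i(S, k), σᵢ)

with σᵢ = 1 after z-scoring (measurement noise equals interobserver
variability; configurable). A C-subtype model is a mixture over orderings
with fractions f.

**Fitting.** Hierarchical: the 1-subtype solution is best-of-`n_startpoints`
greedy ascent (single-event relocation within the feasible window that
preserves within-biomarker grid order); the C-subtype solution is
initialised by splitting the (C−1)-solution's largest-variance cluster into
random halves and fitting each, then refined by
expectation-maximisation (responsibilities and fractions in closed form;
orderings by weighted greedy ascent — a generalised EM, so the observed
log-likelihood is non-decreasing, which is property-tested). The final
solution is polished by Metropolis-Hastings over orderings (symmetric
single-event relocation proposals, fractions held fixed); the reported model
is the best state visited. Defaults: 25 start points, 10⁴ MCMC iterations —
desk scale, exact on ≤8-event problems against exhaustive enumeration
(tested to 1e-6).

**Model size.** Event grids default to integer z-scores {1, …, z_max} with
z_max the 95th percentile of the observed z rounded up to the next integer
(at least 1); recovery studies pin z_max to the generator's value (3) so
fitted and generating event sets coincide.

**Subtype count.** Subject-level K-fold cross-validated log-likelihood per
candidate C, with a one-standard-error rule breaking near-ties toward fewer
subtypes. CV refits use reduced search settings (documented in the call
sites); the pipeline also exposes a forced C=2 mode mirroring the clinical
analysis.

**Assignment.** Posterior over (subtype, stage) computed in log space;
subjects receive the marginal MAP subtype and the posterior-expected stage.
Label switching in recovery metrics is handled by scoring the best label
permutation.

**Inherent assignment ceiling.** Any two orderings agree at stage 0 (all
biomarkers 0) and approach each other at stage N (all biomarkers at z_max),
so subjects near either end are intrinsically ambiguous. With the
well-separated generator pair (fibrosis-first vs emphysema-first), unit
noise and uniform stages, the Bayes-optimal assignment accuracy measured on
500-subject cohorts is ≈0.88–0.92 depending on the realisation; fitted
models come within ~0.01 of that ceiling. Reported recovery accuracies must
be read against this bound, not against 1.

## Decline estimation (`decline`)

Eligibility: a baseline measurement within ±91 days of the baseline CT
(nearest; earlier on ties), at least one later measurement, horizon 548
days. Calendar phrases are fixed as 3 months = 91 days, 18 months = 548
days, 1 year = 365.25 days. Relative decline works on the
percent-of-baseline scale (each value divided by the subject's baseline
value × 100); absolute decline on the raw scale (ml for FVC; ml/min/mmHg for
DLco).

The mixed model per measure and scale has fixed effects age, sex, smoking
ever/never, antifibrotic ever/never, baseline percent-predicted value of the
same measure, and time since baseline CT; and a correlated random intercept
and random time slope per subject, fitted by REML (statsmodels `MixedLM`,
lbfgs/bfgs). A near-singular random-effects covariance triggers a refit with
the intercept–slope correlation pinned to zero, flagged in the fit.
Constant covariates in a partition are dropped with a warning. An optional
partition column (e.g. centre) fits one model per level.

Per-subject predictions are conditional (fixed + empirical-Bayes random
effects): relative 1-year decline = 100 − predicted percent-of-baseline at
365.25 days; absolute decline = minus the subject's raw-scale slope.
Threshold flags (FVC ≥5/≥10%, DLco ≥10/≥15%, inclusive) are computed on the
decline rounded half-up to 2 decimals — the precision at which the tables
print it — so a trajectory sitting exactly on a threshold is not lost to the
optimiser's final 1e-5.

**What recovery can and cannot show.** With measurement noise of 3% of
baseline and four visits over 18 months, the slope-likelihood SE is
3/√3.5 ≈ 1.60 %/yr against a 2 %/yr between-subject SD, so the
posterior-mean estimator's error SD is ~1.25 %/yr: the per-subject MAE floor
is ≈0.999 points and the attainable truth-correlation ≈0.78. Dividing by a
*noisy measured* baseline degrades this further by sharing the baseline
error across all follow-ups. Group-level quantities (mean declines,
threshold proportions) are far better behaved than per-subject estimates.

Group summaries report n-with-data/n-total, counts and printed-precision
percentages above each threshold, and mean absolute decline; pairwise
chi-squared tests carry Bonferroni adjustment over the pairwise comparisons,
and mean absolute decline is compared by one-way ANOVA with Tukey HSD.

## Survival analysis (`survival`)

Kaplan-Meier curves and the k-sample log-rank test come from lifelines.
Adjusted Cox models include age, sex, smoking ever/never, antifibrotic
ever/never and baseline percent-predicted DLco (the severity adjuster for
FVC models too), plus one decline covariate per model; the
8-events-per-covariate rule is enforced before fitting and failing models
are reported ineligible rather than fitted.

The centre random intercept is a log-normal shared frailty: centre effects
are coefficients penalised by a Gaussian prior with variance θ, maximised by
Newton-Raphson on the Efron-tie penalized partial likelihood (own
implementation, verified against lifelines to 1e-5 in the unpenalised
limit); θ maximises the Laplace approximation to the marginal likelihood
(bounded scalar search on log θ ∈ [log 1e-4, log 4]). With a single centre
or frailty disabled the model is a plain lifelines Cox fit. Wald CIs on the
log-HR scale; hazard ratios are per 1% of annual decline for continuous
covariates (the ≈1.03-per-percent scale) and per group for binary flags.
Harrell's C-index uses the model's linear predictor including centre
effects. The p<0.01 significance convention is applied only when annotating
reports.

Proportional hazards are tested with the Grambsch-Therneau scaled-Schoenfeld
score test against the rank transform of event time (own implementation;
per-covariate statistics agree with lifelines' `proportional_hazard_test`,
and the global test is calibrated to 2–8% null rejection in simulation).
Schoenfeld residuals use the Breslow risk-set form, standard for this
diagnostic; for frailty fits the centre effects enter the risk weights as
offsets.

## Synthetic cohorts (`simulate`)

The generator produces the structure the analysis assumes, with a truth
table for recovery testing:

- **Lobar scores.** A subject draws a subtype (default fractions 0.6/0.4)
  and a uniform stage; extent % = trajectory z × interobserver SD +
  truncated Gaussian noise, clamped to [0, 100]. Default interobserver SDs:
  10% (fibrosis), 5% (emphysema) — fibrosis is scored over a wider dynamic
  range. Default noise SD equals the interobserver SD, making the z-scored
  noise SD exactly 1. The default orderings mirror the clinical subtypes
  (fibrosis-dominant: fibrosis lower-lobes-first, emphysema late; matched:
  both processes interleaved with emphysema relatively heavier late); a
  well-separated pair (fibrosis-first vs emphysema-first with reversed lobe
  order) exists for recovery studies where identifiability must not be
  limited by shared structure.
- **Non-CPFE component.** A configurable fraction (default 0.35, matching a
  ~37% non-CPFE IPF cohort) progresses along the fibrosis ordering with
  emphysema structurally zero; these subjects are excluded from subtyping by
  the any-lobar-emphysema rule, exactly as in the pipeline.
- **Lung function.** Subject slopes on the percent-per-year scale are
  bivariate normal across FVC and DLco (defaults −6 ± 2 %/yr, correlation
  0.7); visits at 0/6/12/18 months with small Gaussian day jitter;
  measurement noise 3% of baseline; follow-ups missing completely at random
  (default 15%). An optional setting inflates FVC noise in subjects with
  ≥10% lung emphysema — the expiratory-volume heterogeneity mechanism —
  without touching DLco.
- **Covariates.** Smoking probability is logistic in lung emphysema %
  (more smokers at higher extents); baseline percent-predicted DLco
  declines linearly with emphysema extent; age, sex, antifibrotic use are
  independent draws.
- **Survival.** Weibull proportional hazards (scale 6 y, shape 1.3,
  administrative censoring at 5 y, ≈60–75% deaths) with linear predictor
  over centred covariates and the *true* relative declines, plus a Gaussian
  centre intercept (default SD 0.3). The semi-parametric Cox model is
  agnostic to the Weibull choice.

Everything is drawn from one seeded generator in a fixed order, so a config
plus seed reproduces the cohort bit for bit. What the generator does *not*
emulate: informative missingness, competing risks, measurement error in the
CT scores' spatial structure, and non-linear lung-function trajectories —
recovery results say nothing about those.

## Problem sizes used by the verification suite

The test suite and `scripts/acceptance.py` run everything at desk scale:
subtype recovery on one 500-subject cohort (25 start points, 10⁴ MCMC
iterations; subtype-count CV at 2 folds with reduced search), decline
recovery at n=200 × 6 replicates, Cox calibration at 500/200/500 replicates
(n=300/1000/200), and the surrogacy contrast at 100 cohorts of 300 subjects
with declines estimated cohort-wide and Cox models fitted in the
≥10%-emphysema subgroup (≈110 subjects, mirroring the clinical subgroup
sizes; the DLco hazard coefficient, 0.05 per percent of annual decline, is
calibrated so the subgroup association strength matches the reported one).
These sizes were chosen so each stage's sampling error is small relative to
the property being checked.

## Known limitations

- Per-subject decline estimates operate near their information bound at the
  default visit schedule and noise; see the decline section.
- The frailty θ search treats the Laplace approximation as exact; for very
  few centres (<3) θ is weakly identified and the estimate should be read
  as regularisation, not as a variance component of scientific interest.
- The subtype model fixes σ = 1 rather than estimating noise per biomarker;
  with badly mis-specified interobserver SDs the stage posterior would be
  over- or under-confident.
- `select_n_subtypes` compares in-family models only; it cannot flag that
  the z-score trajectory family itself is wrong.
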