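# Methods

This note documents the statistical machinery in `dietscore`: the
models and their assumptions, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical choices that affect results.

## Diet scores

### Dietary Inflammatory Index

Each component's daily intake is standardised against a *global*
reference mean and SD (literature-derived, not sample-derived), mapped
to a percentile with the standard normal CDF, centred to (−1, 1) by
`2·Φ(z) − 1`, multiplied by the component's inflammatory effect score,
and summed. Consequences used by the test suite:

* DII = 0 exactly when every intake equals its reference mean;
* |DII| is strictly below Σ|effect score| for finite intakes;
* the score is additive over components and strictly monotone in each
  intake (direction given by the sign of the effect score).

The percentile transform is the normal CDF (the canonical construction;
it makes scores smooth and independent of the analytic sample). An
alternative order of operations — multiplying the effect score into the
z-score *before* the percentile transform, which one reading of the
method's verbal description implies — is available as
`compute_dii(..., effect_inside_z=True)`; the default is the bounded
canonical construction. The DII remains valid on a subset of components
(the `components` argument); a component named in the active table but
absent from the intake data is an error, never a silent zero, because
silent imputation hides data bugs. No energy adjustment is applied:
total energy intake enters later as a model covariate.

The shipped 26-component parameter table is a **synthetic stand-in**
(`dii_parameters_synthetic.csv`): component list, units and magnitudes
are representative of the published global reference database, but the
file was not transcribed from an authoritative source and real analyses
should supply their own table.

### Dietary Oxidative Balance Score

Seventeen components: 14 anti-oxidants and 3 pro-oxidants (total fat,
iron, alcohol). Tertile-scored components use the analytic sample's
tertiles (linear-interpolation quantiles at 33⅓% and 66⅔%); ties at a
cutpoint go to the lower tertile, which is deterministic and
order-independent. Anti-oxidants score 1→3 ascending, pro-oxidants
4 − tertile. Alcohol is categorical: nondrinker (exactly 0 g/day) 3,
nonheavy 2, heavy 1; the heavy threshold is 15 g/day, the conventional
cutoff for women in the oxidative-balance literature (the method
description names the categories but not the gram value). Tertiles are
unweighted by default — survey-weighted cutpoints are available via
`assign_tertiles(values, weights=...)` — because the source analyses do
not state weighted tertiles.

Vitamin C, beta-carotene and vitamin B12 carry a log flag for fidelity
to the published recipe. Log transformation is monotone, so it cannot
change tertile membership; the implementation uses `log1p` (intakes of
zero are legal) and the flag only matters if a user switches to a
non-quantile scoring rule.

Joint classification: DII tertile 3 with DOBS tertile 1 →
pro-inflammatory/pro-oxidative; DII tertile 1 with DOBS tertile 3 →
anti-inflammatory/anti-oxidative; otherwise composite. The three labels
partition the cohort.

## Cohort preparation

Eligibility filters run sequentially — males, age outside 20–45,
missing any active diet component, missing any outcome or mediator
(infertility, SHBG, TT, E2, BMI, WC) — and each step's removals are
counted so a participant-flow chart can be reconstructed and asserted
against planted fixtures. The filters are idempotent.

Derived variables: HOMA-IR = insulin (mU/L) × glucose (mmol/L) / 22.5;
obesity at BMI ≥ 30.0 kg/m² and high waist circumference at ≥ 88 cm
(both boundary-inclusive). Hormone outcomes are dichotomised at the
**survey-weighted** median by default (the weights carry the survey's
representativeness; an unweighted split is available), with values
exactly at the cutpoint assigned to the low group and the cutpoint
reported for reproducibility.

Covariate codings use fixed level orders whose first level is the
regression reference: race (4 levels), education (4), marital (2),
income-to-poverty ratio (<1 / ≥1 / an explicit `miss` level so missing
income never drops a participant), smoking (3), physical activity
dichotomised at 600 MET-min/week (boundary in the active group). The
`core` covariate set is age, race, education, marital status, PIR,
smoking, physical activity and total energy; `extended` adds total
cholesterol, triglycerides, LDL, HDL and HOMA-IR.

## Survey-weighted estimation

`SurveyDesign` carries positive sampling weights and, optionally,
stratum/PSU identifiers. The default variance mode treats observations
as independent with known weights (linearised ratio-estimator variance
with an n/(n−1) factor, so equal weights reproduce classical formulas
exactly); Taylor linearisation across PSUs within strata is available
when design identifiers exist. All estimators are invariant to
rescaling the weights by a constant.

Group comparisons: continuous variables get a design-weighted Wald test
of equal means (two groups: t statistic with Welch–Satterthwaite
degrees of freedom, reducing exactly to the classical unequal-variance
t-test under equal weights; more groups: chi-square Wald). Categorical
variables get a Pearson chi-square on weighted proportions rescaled to
the sample size, divided by the Kish design effect `1 + cv²(w)` — a
first-order Rao–Scott-style correction that reduces to the ordinary
Pearson test under equal weights.

### Weighted GLMs

Gaussian (identity) and binomial (logit) families, fitted by weighted
maximum likelihood (IRLS on the estimating equation
Σ wᵢ(yᵢ−μᵢ)xᵢ = 0). Point estimates with equal weights match the
classical unweighted fits to numerical precision, and a frequency
interpretation holds for the coefficients (an observation with weight 2
equals two unit-weight copies).

The default covariance is the **leverage-adjusted sandwich**
A⁻¹(Σ uᵢuᵢ')A⁻¹ with uᵢ = wᵢrᵢxᵢ/(1−hᵢ), the GLM analogue of the HC3
heteroscedasticity correction, and inference uses t / F(q, n−p)
references. This combination was chosen for its small-sample test
size: over 20,000 null simulations (n = 500, gamma weights) the joint
Wald test of the spline curvature terms rejects at 5.2% against a
nominal 5%, where the plain HC1 sandwich with a chi-square reference
rejects at ~6.2%. For the gaussian family the default covariance
coincides exactly with the WLS HC3 sandwich; `robust_hc1` and
model-based covariances are available. Perfect separation in logistic
fits (fitted probabilities within 1e−8 of 0/1) raises an error rather
than returning a silent result, as does IRLS non-convergence.

### Restricted cubic splines

Natural cubic splines in the standard truncated-power form, normalised
by the squared knot span, linear beyond the boundary knots, C²
everywhere. Default 4 knots at the 5th/35th/65th/95th weighted
percentiles of the exposure (3 knots: 10/50/90; 5 knots:
5/27.5/50/72.5/95 — the conventional placements); knot count and
positions are configurable and recorded in output. `p_overall` is the
joint Wald test of all spline terms, `p_nonlinear` of the nonlinear
terms only. The dose–response curve reports log-odds (and odds ratios)
relative to a reference exposure value, the weighted median by default,
with pointwise Wald intervals from the robust covariance.

## Mediation

Two-model counterfactual estimator without exposure–mediator
interaction: a weighted linear model for the mediator and a weighted
logistic (or linear) model for the outcome. Uncertainty is propagated
quasi-Bayesianly — parameter vectors are drawn from each model's
asymptotic normal sampling distribution (robust covariance) — and each
draw simulates counterfactual mediator values under the control and
treated exposure levels, including the mediator model's residual noise
(shared across arms within a draw, which removes spurious Monte-Carlo
variance from the contrast), then averages potential outcomes over the
sample's covariate distribution with the survey weights.

Effects are reported on the risk-difference scale for binary outcomes
(mean difference for continuous), so ACME + ADE = total effect holds
exactly draw by draw and the proportion mediated ACME/total matches the
"% of the effect" framing used in applied work. The default exposure
contrast is one weighted SD of a continuous score (0 vs 1 for a binary
exposure); contrasts, draw counts (default 1,000; minimum 100) and the
seed are recorded in the results. When the total-effect interval covers
zero the proportion mediated is flagged unstable rather than trusted as
a point estimate.

Properties verified by the tests: with a linear outcome model the ACME
equals the classical a·b coefficient product; with no exposure→mediator
path the ACME interval covers zero; on synthetic cohorts with planted
paths the estimated proportion mediated recovers the generating model's
Monte-Carlo oracle. One calibration caveat worth knowing: **at the
exact null a = 0 the ACME interval is conservative** (empirical
coverage of zero ≈ 99% at nominal 95%). This is intrinsic to
product-type Monte-Carlo intervals — the a·b sampling distribution
concentrates near zero when either factor is null — and the same
behaviour is observed in the reference R implementation; the interval
never undercovers.

## Synthetic cohort generator

The generator emulates the survey setting the analysis targets: women
aged 20–45 with log-normal daily intakes (moment-matched to the DII
reference means/SDs, plus calcium and copper for the DOBS; a 45% point
mass of alcohol nondrinkers), i.i.d. gamma sampling weights with mean 1
(shape 4), balanced stratum/PSU blocks, and realistic demographic and
laboratory covariates. The causal structure is explicit:

* standardised DII (computed from the generated intakes) → BMI with
  slope `path_a` (default 0.8 kg/m² per score SD, Gaussian noise
  SD 6.5 around a baseline of 28 kg/m²);
* BMI → infertility logit with slope `path_b` (default 0.03, an odds
  ratio ≈ 1.03 per kg/m², the magnitude reported for BMI–infertility
  associations in survey data);
* direct diet → infertility effect `path_c` (default 0.18 per SD) and
  intercept −2.77, giving a realised weighted prevalence near 12.7%,
  the weighted infertility prevalence reported for US women of
  childbearing age;
* waist circumference derived from BMI (2.1 cm per kg/m², noise SD 4),
  so WC is a correlated proxy mediator, not an independent causal path;
* SHBG/TT/E2 from linear models in the diet score and BMI with
  Gaussian noise (SHBG default: 100 nmol/L intercept, −3 per score SD,
  −1.5 per kg/m², SD 25).

Under these defaults the generating model's BMI-mediated proportion of
the diet→infertility effect is ≈ 0.12. Each variable draws from its
own deterministically derived substream of the seed, so adding a
variable never perturbs existing draws, and identical configs produce
byte-identical cohorts.

`true_proportion_mediated` evaluates ACME/(ACME+ADE) of the generating
model on the risk-difference scale by Monte Carlo (default 400,000
draws, common random numbers across the four counterfactual arms); it
is exact at the two corners (0 when `path_b=0`, 1 when `path_c=0`).

**What passing tests on these cohorts do not show:** the generator has
no multistage cluster sampling (weights are i.i.d. and independent of
outcomes), no correlated recall error across nutrients, no seasonal or
weekday intake structure, and its covariates do not confound the
diet–outcome path unless explicitly configured. Recovery results
therefore validate the estimators' correctness, not their robustness
to design features real survey data may have.

## Problem sizes used in the checks

The shipped verification runs use: 5,000 null replicates of n = 500
for test-size calibration; 1,000 replicates of n = 300 for CI
coverage; five cohorts of n = 10,000 for mediation recovery; 500
replicates of n = 1,000 for null-ACME validity; and a 2,000-participant
cohort for the end-to-end pipeline determinism check. These sizes make
the Monte-Carlo error of each check small relative to the property
being asserted while keeping the full suite quick on a single CPU.

## Known limitations

* Weights-only variance treats PSUs as independent observations; with
  strong clustering, supply strata/PSU ids and use Taylor
  linearisation.
* The categorical group test's Kish correction is first-order; exact
  Rao–Scott second-order corrections are not implemented.
* The mediation estimator assumes sequential ignorability and no
  exposure–mediator interaction; no sensitivity analysis is provided.
* The shipped DII parameter table is a labelled stand-in; results on
  real data are only as good as the reference table supplied.
* Hormone models in the generator are linear with Gaussian noise;
  real hormone distributions are right-skewed.
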