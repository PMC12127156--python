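# dietscore

Tools for studying how the inflammatory and oxidative potential of a
woman's diet relates to reproductive health — infertility and serum sex
hormones — and how much of that relationship runs through obesity.

The package is aimed at nutritional epidemiologists working with
24-hour-recall survey data (NHANES-style tables with dietary day-one
sampling weights). It provides the two diet scores, the survey-weighted
modelling layer around them, and a synthetic-cohort generator so the
whole chain can be exercised and validated without access to restricted
survey files.

## What it computes

**Dietary Inflammatory Index (DII).** For component *i* with daily
intake *xᵢ*, global reference mean *μᵢ*, SD *σᵢ* and inflammatory
effect score *eᵢ*:

    zᵢ = (xᵢ − μᵢ)/σᵢ ,   DII = Σᵢ (2Φ(zᵢ) − 1) · eᵢ

where Φ is the standard normal CDF. Each term lies in (−eᵢ, eᵢ);
higher DII = more pro-inflammatory diet. A 26-component reference
parameter table ships with the package (a constructed stand-in with
values representative of the published global reference database — see
`data/dii_parameters_synthetic.csv`; supply your own table for real
analyses).

**Dietary Oxidative Balance Score (DOBS).** 17 nutrients — 14
anti-oxidants scored 1/2/3 by sample tertile, 3 pro-oxidants scored
inversely, with alcohol handled categorically (nondrinker 3, nonheavy
2, heavy 1). Totals range 17–51; higher = more anti-oxidative diet.
The joint **DII&DOBS class** labels women in DII tertile 3 ∧ DOBS
tertile 1 as pro-inflammatory/pro-oxidative, DII tertile 1 ∧ DOBS
tertile 3 as anti-inflammatory/anti-oxidative, everyone else composite.

**Survey-weighted models.** `SurveyGLM` fits gaussian and logistic
models by weighted IRLS with a leverage-adjusted sandwich covariance;
`RCSLogistic` adds restricted-cubic-spline dose–response with joint
Wald tests for any association (`p_overall`) and for curvature
(`p_nonlinear`); `MediationModel` decomposes a diet-score effect into
the part transmitted through BMI or waist circumference (ACME), the
direct part (ADE), and the proportion mediated, using the
quasi-Bayesian counterfactual estimator on the risk-difference scale.

**Synthetic cohorts.** `generate_cohort(CohortConfig(...))` draws an
NHANES-like cohort with planted paths *a* (diet→BMI), *b*
(BMI→infertility logit) and *c* (direct), and
`true_proportion_mediated` evaluates the generating model's
ACME/(ACME+ADE) exactly (by Monte Carlo), giving every estimator a
recovery oracle.

## Worked example

```python
import dietscore as ds
from dietscore.survey import SurveyDesign
from dietscore.mediation import MediationModel

cohort = ds.generate_cohort(ds.CohortConfig(n_participants=5000, seed=42))
f = cohort.frame
design = SurveyDesign(f["survey_weight"].to_numpy())

params, spec = ds.default_dii_params(), ds.default_dobs_spec()
dii = ds.compute_dii(f[params.components], params).dii
dobs = ds.compute_dobs(f[spec.components], spec).dobs
print("mean DII  %.2f   mean DOBS  %.1f" % (dii.mean(), dobs.mean()))

df = f.assign(dii_std=(dii - dii.mean()) / dii.std(ddof=0))
res = ds.SurveyGLM.from_dataframe(
    df, "infertility", ["dii_std"], design, family="binomial"
).fit()
print(res.summary().round(4))

med = MediationModel(
    f["infertility"], f["dii_std"], f["bmi"], design,
    outcome_family="binomial", contrast=(0.0, 1.0),
).fit(n_draws=500, seed=0)
print(med.summary().round(4))
print("generating-model truth:",
      round(ds.true_proportion_mediated(cohort.truth, seed=0), 4))
```

Output:

```
mean DII  0.36   mean DOBS  34.3
           estimate      se  ci_low  ci_high       p      or  or_low  or_high
Intercept   -1.8503  0.0475 -1.9434  -1.7571  0.0000  0.1572  0.1432   0.1725
dii_std      0.1771  0.0482  0.0826   0.2717  0.0002  1.1938  1.0861   1.3121
          effect  estimate  ci_low  ci_high      p
0           acme    0.0027  0.0013   0.0043  0.002
1            ade    0.0191  0.0068   0.0319  0.002
2   total_effect    0.0219  0.0098   0.0347  0.002
3  prop_mediated    0.1244  0.0533   0.2979  0.002
generating-model truth: 0.1177
```

Reading it: one SD of DII raises the odds of infertility by a factor
1.19 (95% CI 1.09–1.31) in this simulated cohort. The mediation
decomposition attributes a risk difference of 0.0027 (per SD of DII)
to the BMI pathway out of a total 0.0219 — a proportion mediated of
12.4% (CI 5.3–29.8%), bracketing the generating model's true value of
11.8%.

A command-line layer mirrors the library
(`dietscore simulate|score|describe|fit|rcs|mediate|pipeline`); the
`pipeline` subcommand runs the whole analysis surface from one YAML
config and writes an exclusion flowchart, descriptive tables, tidy
coefficient tables, spline curves and mediation tables plus a
reproducibility manifest.

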