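# Methods

## Setting and assumptions

`pbastand` estimates the marginal causal effect of a binary exposure on a
rare binary outcome from an incident case-control sample, under three
assumptions:

* **Known sampling fractions.** The numbers of cases and of eligible
  non-cases in the study base are known, so sf_case = cases sampled /
  incident cases and sf_control = controls sampled / eligible base
  population are available. Everything downstream — the intercept
  correction ln(sf_case/sf_control), the inverse-fraction weights in the
  standardization, and the reconstructed-base observed risk — depends on
  them.
* **Non-differential misclassification.** One (Se, Sp) pair applies to
  cases and controls alike in any iteration. The correction and the
  predictive values are nonetheless computed *within* each group, because
  PPV and NPV depend on the group's exposure prevalence even when Se and
  Sp do not differ. Identifiability requires Se + Sp > 1.
* **Correct outcome model / no unmeasured confounding.** The logistic
  model of case status on exposure and the confounder set, after
  intercept correction, is treated as the population risk model; the
  g-formula averages its predictions over the sample's confounder
  distribution weighted up to the study base.

## Priors for the bias parameters

Three families express the same median + 95%-interval summary
(m, q2.5, q97.5) of a validation-literature estimate:

* **Triangular(min, max, mode) = (q2.5, q97.5, m).** The interval
  endpoints are read as the *support*, the standard convention when a
  pooled estimate with its CI is turned into a bounded prior. This is
  deliberately not a quantile fit: the implied 2.5th percentile of the
  triangular lies slightly inside its support (by
  sqrt(0.025(max−min)(mode−min)), ≈ 0.016 for the default sensitivity
  prior).
* **Beta(α, β)** by least-squares on the implied (2.5, 50, 97.5)
  percentiles, Nelder–Mead over (log α, log β) started from moment
  matching with sd = (q97.5 − q2.5)/3.92. The fitted quantiles land
  within a few 10⁻³ of the targets.
* **Logit-logistic**: a logistic distribution on the logit scale,
  location = logit(m); its central 95% interval maps exactly onto a
  symmetric interval, so the scale is the average of the two one-sided
  solutions (logit(q97.5) − location)/ln 39 and
  (location − logit(q2.5))/ln 39. Published "scale" values for this
  family are ambiguous across parameterizations, so the fitter always
  derives the scale from the quantile summary; explicit parameters can
  be passed verbatim when the user insists.

All sampling is inverse-CDF on uniforms from a `numpy.random.Generator`,
one code path for every family, which makes point-mass (degenerate)
priors and bit-for-bit reproducibility trivial.

Pooling across validation studies uses DerSimonian–Laird random effects
on the logit scale: τ² = max(0, (Q − (k−1))/C) with the usual
method-of-moments Q and C, then an inverse-variance mean with weights
1/(vᵢ + τ²), back-transformed by expit. A single study returns its own
estimate ± 1.96 SE.

## The Monte Carlo loop

Per iteration: draw (Se, Sp) → correct the within-group counts → derive
group PPV/NPV → re-impute every record's exposure by comparing one
uniform per record against its group's predictive value → refit the
outcome model → standardize. Iterations whose corrected cells are
non-positive, whose draw is non-identifiable, or whose logistic fit does
not converge (including separation, flagged when |β| > 50) are discarded
and redrawn; a cap of 10,000 attempts per iteration turns pathological
priors into a hard error carrying the offending counts. Discards are
counted and logged.

Fractional-polynomial age selection (powers from
{−2, −1, −0.5, 0, 0.5, 1, 2, 3}, age/10 to stabilise the powers, the
Royston–Altman closed test at α = 0.05: best FP2 vs no age term on 4 df,
vs linear on 3 df, vs best FP1 on 2 df) runs **once** on the observed
data and is held fixed across iterations. Re-selecting per iteration
would mix model-selection noise into the bias distribution and make
draws incomparable.

Random error is handled by nesting the loop in a stratified bootstrap:
cases and controls are resampled independently with their original group
sizes, preserving the case-control design (and hence the realized
sampling fractions). The default summary pools all n_boot × n_iter draws
and reports median and 2.5/97.5 percentiles (numpy linear interpolation
of order statistics, fixed because quantile conventions differ across
software). An alternative summary — percentiles of per-replicate
medians — is available (`summarize_per_bootstrap`, `summary:
per_bootstrap` in the config); pooling is the default because it yields
a single interval reflecting both error sources, which is how a combined
systematic-plus-random interval is usually reported.

Seed management: one master seed; `Generator.spawn` gives each bootstrap
replicate an independent substream, so results are identical for a given
seed regardless of `--jobs`.

## Attributable fraction

PAF = (Pr[Y=1] − Pr[Y^{a=0}=1]) / Pr[Y=1]. The observed risk defaults to
the count-based reconstruction (n_case/sf_case) / (n_case/sf_case +
n_control/sf_control) — the "(O − E)/O" reading — because it is
model-free where it can be; a switch (`paf_observed: model`) substitutes
the model-standardized observed risk, computed per draw at the imputed
exposure. PAF is evaluated once per Monte Carlo draw and summarised like
RR and RD.

## Synthetic data generator

The generator emulates the motivating study's design: a base of ~5.1
million residents aged 15–50 (truncated-normal age 31.3 ± 9.3, education
13.4 ± 3.2 years clipped to [0, 22]), binary confounders at the control
marginals (female 0.515, married 0.538, smoking 0.199, passive smoking
0.375, life events 0.819, vitamin D supplement 0.076), a logistic
exposure model with sex and smoking as the main confounding paths
(intercept calibrated so the base exposure prevalence is 0.10 — the
study never reports the true prevalence, and 0.10 is a defensible figure
for lifetime alcohol consumption in this population), and a logistic
outcome model whose conditional exposure log-OR defaults to ln 2 and
whose intercept is calibrated by root finding so the expected base risk
hits its target exactly (default 1.07×10⁻⁴). Confounders are generated
through an exchangeable Gaussian copula whose correlation defaults to 0
(only marginals are reported for the real study); the hook exists for
sensitivity analyses.

Oracle effects are computed by per-record counterfactual enumeration —
averaging expit predictions with exposure forced to 1 and 0 — not by
fitting anything, so they are exact ground truth for the generating
model.

What the generator does **not** emulate: telephone-sampling mechanics,
measurement error in the confounders, correlation between exposure and
confounder reporting errors, differential misclassification, and any
dose-response structure (exposure is binary). Passing recovery tests
therefore shows the pipeline undoes the biases it models — not that
those are the only biases in real data.

### Test problem sizes

The recovery suite scales the base population to 5×10⁵ while keeping the
sample sizes of the emulated study (~525 cases at sf_case = 0.96, ~1057
controls): the outcome risk target becomes 1.1×10⁻³, still deep in the
rare-disease regime. Keeping the sample sizes keeps the estimator's
sampling error realistic; shrinking the base only shrinks generation
cost. Recovery runs use n_boot = 20, n_iter = 100 over 10 seeds; with
~500 cases the corrected log-RR carries per-dataset sampling error of
roughly 0.3–0.4, so recovery is asserted on the across-seed median (and
on per-seed interval coverage), not on each seed's point estimate.

## Numerical choices and degenerate inputs

* Logistic fits: `statsmodels` Logit with Newton iterations; rank
  deficiency raises; separation and non-convergence are flagged (and
  redrawn inside the loop) rather than raised.
* Standardization weights are normalized to sum to one, so the scale of
  the sampling fractions cannot affect a mean; rescaling both fractions
  by a common factor provably changes nothing.
* Degenerate triangular priors (min = max = mode) are allowed as point
  masses; they are the reduction device that turns the whole pipeline
  into the conventional analysis (Se = Sp = 1) in tests.
* A degenerate quantile summary (q2.5 = q97.5) is rejected at
  construction; constant exposure or constant age raise immediately.
* Beta-fit optimisation tolerances: `xatol 1e-8`, `fatol 1e-14`,
  ≤ 2000 Nelder–Mead iterations — implied quantiles reproduce targets to
  well under the 0.015 the pipeline treats as acceptable prior error.

## Known limitations

* Only non-differential exposure misclassification is modelled; the
  machinery applies one (Se, Sp) per iteration to both groups.
* Se and Sp are drawn independently; a joint (correlated) prior is not
  implemented.
* Outcome misclassification and confounder measurement error are out of
  scope.
* The percentile bootstrap is the only random-error method provided.
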