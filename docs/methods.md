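# Methods

## The model

`birthmix` implements a two-stage framework for analyzing birthweight
distributions and birthweight-specific fetal-infant mortality.

**Stage 1 — birthweight mixture.** The birthweight density of a
population is a k-component normal mixture

    f(x) = sum_{j=1}^{k} p_j f(x; mu_j, sigma_j),

where `p_j` is the fraction of births in component j and `f(.; mu,
sigma)` is a normal density in grams.  Components are interpreted as
latent subpopulations (e.g. pregnancies compromised in different ways);
k can be chosen by an information criterion or fixed by the analyst.
Components are always labeled in increasing order of mean, so that
"component j" is comparable across repeated fits — a requirement for
the multi-sample combination below.

**Stage 2 — component-specific mortality (generalized PMLR).**  Within
component j, mortality risk at birthweight x is

    r_j(x) = logit^-1[ q_j(z_j) ],      z_j = (x - mu_j) / sigma_j,

with `q_j` a degree-4 polynomial (two possible changes of convexity,
enough for U-shapes with asymmetric arms).  The polynomials are fitted
by maximum likelihood *conditional on* the stage-1 estimates: a record
at birthweight x with death indicator d contributes a Bernoulli term
with success probability

    R(x) = sum_j tau_j(x) r_j(x),

where `tau_j(x)` is the posterior probability that a birth at weight x
arose from component j.  This is the marginal likelihood implied by the
mixture structure and the law of total probability; it generalizes the
two-component parametric mixtures of logistic regressions (PMLR) of
Gage to arbitrary k and quartic risk polynomials.

**Meta-sample inference.**  N_rep samples (possibly overlapping,
because the population is finite) are each fitted by both stages.  For
a scalar target theta — the logit of r_j(x0), or a difference of two
such logits (a log odds ratio) — the per-sample estimates
theta_hat_1..theta_hat_Nrep are combined as their mean theta_bar, with
meta-sample standard deviation S_theta, and the confidence interval

    theta_bar +/- { B_theta + C * S_theta / sqrt(N_rep) }.

`B_theta` is a simulation-based bias adjustment: data sets of the
original sample size are regenerated from the *overall* estimates
(averaged mixture, logit-averaged risk curves), refitted end to end,
and B_theta is the mean absolute deviation of the refitted estimates
from the overall estimate.  `C` is a calibration constant; when each
sample constitutes a fraction phi of a finite population, C is inflated
from its infinite-population value C_0 to

    C_phi = C_0 * phi * N_rep / { 1 - (1 - phi)^N_rep }.

Intervals for risks are back-transformed through the inverse logit;
odds-ratio intervals are exponentiated.  Between-population odds ratios
combine two independent meta-estimates, adding the two bias adjustments
and the standard errors in quadrature.

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| `degree` | 4 | risk polynomial degree in z |
| `C_0` (risk targets) | 4.0 | interval constant, calibrated by the coverage study |
| `C_0` (mixture parameters) | 2.5 | constant used for stage-1 parameter intervals |
| `n_sim` | 5 | simulated data sets in the bias-adjustment bank |
| `min_expected_deaths` | 5 | below this posterior-expected death count a component's curve is reported as unestimated |
| `SIGMA_FLOOR` | 1 g | variance floor in EM, guards degenerate spikes |
| curve support | mu_j ± 3 sigma_j | reporting range of each component curve |
| bins | 100 g, [a, a+100) anchored at 0 | crude-rate bins for empirical mortality |

## Numerical choices

* **EM.**  Stage 1 uses EM with responsibilities computed on the log
  scale, initialized from seeded k-means++/Lloyd clustering of the
  birthweights (a quantile-based start misses sub-1% components far
  from the bulk).  Convergence on the near-flat likelihood ridges
  produced by heavily overlapping components is accelerated with a
  guarded squared-extrapolation (SQUAREM) step; a proposal is accepted
  only if it does not decrease the observed log-likelihood, so the
  recorded likelihood trace is non-decreasing.  Stopping is at relative
  increment 1e-10 or 2000 likelihood evaluations.  Weights summing to
  within 0.01 of 1 (e.g. printed tables rounding to 0.999) are
  renormalized on construction.
* **PMLR optimization.**  The marginal likelihood is ridge-shaped
  wherever posterior membership columns are nearly collinear (low-mass
  components, crossing curves): fully converging a quasi-Newton method
  drives intercepts of weakly identified components to extremes (±30 and
  beyond on the logit scale).  The fitter therefore anchors at a stable
  initialization — each component fitted by a posterior-weighted
  polynomial-logistic regression, a concave surrogate with a unique
  maximizer — and then polishes all coefficients jointly on the marginal
  likelihood with a derivative-free Nelder-Mead search capped at 5000
  evaluations, mirroring the general-purpose-optimizer practice this
  kind of analysis has historically used.  The reported log-likelihood
  never falls below the initialization's.  Coefficients are bounded at
  ±50 on the logit scale.
* **Unestimable components.**  A component whose posterior-expected
  death count is below 5 cannot support a five-parameter curve; it is
  reported as unestimated and its posterior mass renormalized over the
  remaining components (precedent: analyses of this kind decline to fit
  curves for components carrying less than ~1/8700 of the mass).
* **Risk evaluation.**  Inverse logits are clamped so r_j(x) is
  strictly inside (0, 1) in floating point even at extreme z.
* **Quadrature.**  The within-component covariate probability
  `integral of r_j(x) f(x; mu_j, sigma_j) dx` uses adaptive quadrature
  over mu_j ± 8 sigma_j and errors out if the estimated absolute error
  exceeds max(1e-8, 1e-6·value).

## The synthetic-data generator

`four_component_scenario()` returns the reference data-generating
process used throughout: the four-component mixture
`.007 f(x;832,210) + .182 f(x;2772,740) + .758 f(x;3170,417) + .052
f(x;3804,413)` with quartic risk polynomials per component (intercepts
−4.6975, −4.0962, −5.7538, −5.3285 on the logit scale), mimicking the
birthweight/mortality patterns of white singletons born to heavily
smoking mothers.  The study design defaults are 25 samples of 50,000
drawn (with natural overlap) from a finite population of 200,000.

`simulate_records` draws a component per birth, a normal birthweight
within it (nonpositive draws rejected and redrawn — the affected mass is
below 1e-4), and a Bernoulli death from the drawn component's curve.
What the generator does *not* emulate: gram-level heaping of recorded
birthweights, covariate structure beyond a single optional binary,
temporal drift, and misclassification of outcomes.  Passing tests
therefore demonstrate the statistical machinery under the stated
mixture-of-logistics truth, not robustness to those artifacts of real
vital-records data.

## Identifiability and what the tests show

At n = 50,000 the reference mixture is weakly identified along a ridge
connecting (mu3≈3170, p3≈.76, mu4≈3804, p4≈.05) to configurations that
blend components 3 and 4; the log-likelihood varies by ~0.1 over this
ridge.  Per-sample PMLR estimates of component risks inherit this:
low-mass components (1 and 4) have large logit-scale sampling
variability, and estimates of minority-component risks are biased
toward the local marginal risk.  This is precisely why the framework
combines many samples on the logit scale and carries an explicit
simulation-based bias adjustment — the coverage study shows the
bias-adjusted intervals at C = 4 are calibrated while the unadjusted
ones undercover badly.  Parameter-recovery tests accordingly judge
estimates against the replicate (Monte-Carlo) spread of the estimator,
not against an idealized information-bound standard error.

## Study sizes used in the shipped tests

The full calibration study (samples of 50,000, N_rep = 25, 10 study
repetitions, a seven-point C grid, three population sizes) takes hours
on one CPU.  The shipped test suite and the acceptance script run the
same study at a desk scale the package treats as its standard quick
design: samples of 5,000, N_rep = 10, 5 study repetitions, an
effectively infinite population, C in {2, 3, 4, 5}.  At this scale the
qualitative calibration conclusions (bias adjustment necessary,
coverage monotone in C, C = 4 adequate) are reproduced; the exact
full-scale percentages are not asserted.  Recovery checks run on single
draws of 50,000 with a six-replicate Monte-Carlo spread.

## Design choices on genuinely open points

* **z convention.**  Risk polynomials are written in the
  component-standardized birthweight; this keeps coefficients
  comparable across components and conditions the optimization.
* **Interval denominator.**  The interval half-width divides S_theta by
  sqrt(N_rep) (standard-error form).  A `literal n_rep` reading would
  shrink half-widths by a further sqrt(N_rep) and is inconsistent with
  the coverage calibration; `ci_theta` nevertheless exposes the choice
  through its inputs (pass `c / sqrt(n_rep)` scaled constants if the
  literal form is wanted).
* **Shared bias bank.**  One bank of `n_sim` simulations serves all
  targets of a study repetition (grid points and odds ratios alike),
  since whole data sets, not targets, are refitted.
* **Odds-ratio bias.**  For within-population odds ratios the bias is
  computed for the composite target theta = logit r_j1(x0) − logit
  r_j2(x0) directly from the bank; for between-population odds ratios
  the two populations' biases are added.
* **Coverage-study scoring.**  k is fixed at the generating value
  inside the study (re-selecting k per sample would conflate selection
  error with interval calibration).  Truth is the logit of the
  generating risk functions at mu_j ± sigma_j and mu_j of the *true*
  mixture.  Targets whose component is unestimated in too many samples
  at the current scale are skipped and the interval totals reflect it.
* **Component-count selection.**  The selection criterion is pluggable
  (BIC default, AIC, ICL) and k can be forced; the original analyses
  used a flexible information criterion that is not reproducible here,
  and all downstream machinery is criterion-agnostic.
* **Finite population held fixed.**  A finite-population study draws
  one seeded population and holds it fixed across study repetitions.

## Known limitations

* Stage-2 maximum likelihood is reported at the polish stopping point,
  not a certified global maximum; on weakly identified ridges the
  estimator is anchored by its initialization (documented above).
* The EM non-convergence warning fires when the SQUAREM budget is
  exhausted; results are still valid likelihood ascents.
* Between-population odds ratios assume independent populations; the
  within-population overlap correction does not apply across
  populations.
* Eq-style simultaneous bands are not provided: bounds are pointwise
  limits connected across a grid.
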