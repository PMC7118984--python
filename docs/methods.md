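# Methods

## The problem and the method

Cancer registries record diagnoses, tumor characteristics and survival, but
not pre-diagnosis health behavior; health-behavior surveys record behavior
but cannot be linked to registry cases individually.  For a relatively rare
cancer, the overlap between the two collections is far too small for record
linkage.  The method implemented here shares information between the two
collections through the variables they have in common — demographics — in
three steps:

1. **Behavior model.**  On the survey, fit one logistic model per behavior
   (current smoking, heavy drinking, binge drinking, concurrent smoking and
   drinking, obesity, leisure-time exercise):

       logit P(behavior_i) = x_i' beta

   where `x_i` contains survey year (coded 0 for 2001 through 14 for 2015),
   the 5-year age-band index, sex, race, marital status and state (dummy
   coded against male / White / married / California), and three interaction
   blocks: age x sex, age x marital status, sex x marital status.  Year and
   age enter as numeric codes.  Fits are weighted by the survey's sampling
   weights and penalized by Firth's bias-reduction term (see below).
   Discrimination is summarized by the ROC AUC.

2. **Probability transfer.**  For each registry case, the demographic
   profile is backdated by a lag of 1, 5 or 10 years — year minus the lag,
   age band minus 0, 1 or 2 — and pushed through the fitted model:

       p_hat_j = expit(x_j(lag)' beta_hat)

   The lagged year must stay inside the survey era (2001-2015), so lag 5 is
   restricted to diagnoses 2006-2015 and lag 10 to 2011-2015.

3. **Survival model.**  Cox proportional-hazards models of survival months
   regress the hazard on `p_hat / 0.1` (so the coefficient is the log hazard
   ratio per 0.1 increase in estimated probability), without and with
   adjustment for the numeric age band and the 5-level stage category, for
   all cases and within the ESCC and EAC histology subgroups.

The estimated probability is a surrogate for behavior, so effects on the
probability scale are attenuated relative to effects of the actual behavior
and carry less power.  The package therefore ships a synthetic twin-data
generator with known truth, and an evaluation harness that *measures* the
attenuation, bias, CI coverage and type-I error of the whole chain rather
than assuming them.

## Weighted Firth-penalized logistic regression

The fitter maximizes

    l(beta) + 0.5 * log det I(beta)

where `l` is the weighted Bernoulli log-likelihood and
`I(beta) = X' diag(w p (1-p)) X` the weighted Fisher information.  The
penalty (a Jeffreys prior) removes the leading-order bias of ML and keeps
estimates finite under separation; in the intercept-only case it reduces to
adding half an event to each cell, which gives the closed form used in the
tests (3 of 10 successes fit to `log(3.5/7.5)`).

Choices that the weighted case forces:

- **Weights enter both the likelihood and the information** used in the
  penalty, and are rescaled to sum to the number of retained rows before
  fitting so the penalty's relative magnitude matches the unweighted case.
  Without rescaling, the penalty's weight would depend on the arbitrary
  scale of the sampling weights.
- **Optimizer**: Fisher-scoring Newton steps on the Firth-adjusted score
  `X'(w(y - p) + h(1/2 - p))`, with `h` the weighted leverages, and
  step-halving on the penalized objective.  Convergence requires
  max |adjusted score| < 1e-8 (default), max 100 iterations.
- **Covariance** is the inverse information at the optimum.  These are
  model-based SEs: the survey's design (clustering, raking) is out of scope,
  and with noisy, outcome-independent weights of squared coefficient of
  variation `c`, true sampling variance exceeds the model-based one by about
  `1 + c`.  The default synthetic weights (lognormal, sigma = 0.3, `c` about
  0.09) keep Wald coverage near nominal, which is what the coverage checks
  measure.
- **Rank deficiency** is detected up front via pivoted QR and reported with
  the names of the collinear columns.

AUC is computed unweighted (pairwise concordance with ties counting one
half); a weighted variant is available behind a flag.

## Cox model with heavy ties

Survival is recorded in whole months (floor(days / 30.4), capped at 179), so
ties are heavy — often hundreds of deaths share a month.  The fitter
maximizes the partial likelihood with **Efron's tie correction** (Breslow
behind a flag) by Newton-Raphson; the covariance is the inverse observed
information; inference is Wald.  Numerical choices:

- **Month-0 deaths are real events** (deaths within 30.4 days of diagnosis).
  All times are shifted by +0.5 month internally so these are orderable in
  risk sets; the shift is uniform and does not change risk-set membership
  among distinct months.
- The linear predictor is centered before exponentiation (an exact
  invariance of the partial likelihood) for overflow safety.
- Convergence: max |gradient| < 1e-7 x number of events, or a Newton step
  below 1e-10.  The gradient is a sum over thousands of terms, so its
  floating-point noise floor scales with the event count; the tolerance
  scales the same way.
- **Monotone likelihood** (separation within risk sets) is reported as
  `converged = False` — detected by a runaway coefficient with a collapsing
  information — never silently.
- Stage enters adjusted models as a 5-level category (reference stage I).
  Stage is unrecorded before 2004; by default those cases are folded into
  the `not_specified` level so they remain in adjusted fits, with a switch
  to drop them instead.  Dummy columns for levels absent from a subgroup are
  dropped rather than fitted as constants.

Verification is dual-route: the same partial likelihood is maximized
independently (derivative-free) in the tests, the log-likelihood is checked
against hand-built risk sets, and fits are cross-checked against lifelines.

## The synthetic world

The generator emulates the *joint structure* the method relies on, not any
real collection:

- **Demographics** are drawn from fixed marginals: 13 states, 4 races plus a
  3.1% mixed-race survey fraction (the registry has no mixed code, and the
  prep step excludes those respondents), 0.3% of registry cases under age
  35 (excluded by the eligibility filter), survey ages from 20 up (the
  under-25 band exercises the age filter), registry ages peaking at 60-79.
- **Behavior** is Bernoulli with inverse-logit probabilities from the same
  design as the analysis model.  Default coefficients follow well-documented
  surveillance gradients (smoking declines by year and age, is commoner
  among single people and in Kentucky; obesity rises by year and is commoner
  among Black respondents; heavy drinking is rare in Utah; binge drinking
  falls steeply with age), with intercepts placed so marginal prevalences
  land near surveillance levels (smoking 16%, heavy drinking 5%, binge 15%,
  concurrent smoking-and-drinking 5%, obesity 27%, exercise 73%).
- **Registry cases carry latent behavior** drawn from the same logistic law
  (the transportability assumption the method makes implicitly); a
  perturbation switch deliberately violates it for sensitivity studies.
  The analysis pipeline strips the latent columns on entry; only the
  evaluation harness reads them, for scoring.
- **Survival** is exponential in days with rate
  `baseline_rate / 30.4 * exp(lp)`, where `lp` combines the latent effect
  behavior (default log-HR 0.4), the age band (0.03 per band) and the stage
  category (0.35 / 0.80 / 1.30 / 0.60 versus stage I); censoring is an
  independent exponential clock (rate 0.023/month) plus the 180-month
  administrative horizon, and times are discretized to whole months.  The
  defaults give a median survival near 7 months and about 18% censoring.
  The real follow-up's censoring mechanism is not documented anywhere we
  could copy it from; independent exponential censoring is an assumption.
- **Sampling weights** are lognormal noise, independent of behavior by
  default (an informative-weight switch exists).  This isolates the
  weighting machinery from confounding: with noise weights, weighted and
  unweighted fits estimate the same parameters, so recovery and coverage
  checks have a well-defined truth.  sigma = 0.3 keeps model-based Wald
  coverage near nominal (see above).

What the generator does *not* emulate: multistage telephone sampling or
raking (and the 2011 weighting change), real stage/histology coding detail,
cohort effects in behavior (no year-interaction terms), or correlation
between the six behaviors beyond what shared demographics induce.  Passing
tests therefore demonstrate the *statistical machinery* is correct under the
stated generative law, not that any substantive epidemiological estimate
from real data would be unbiased.

## Evaluation harness and problem sizes

`evaluate` replicates generate -> prep -> fit -> transfer -> survive and
scores, per exposure mode (estimated probability vs true latent behavior):
replicate mean/SD, rejection rate at alpha = 0.05, and for the true-exposure
mode bias, RMSE and CI coverage against the generating log-HR; for the
probability mode the **attenuation ratio** (mean per-unit-probability
estimate over the true per-unit-behavior log-HR) with its Monte-Carlo SE.
Replicate seeds are spawned from a master seed, so every cell is
independently reproducible.  Replicates that fail to converge are counted
and the scenario is flagged invalid above a 10% failure fraction.

Problem sizes used by the test suite and the acceptance script are chosen to
make each Monte-Carlo check's noise small relative to its tolerance while
keeping a laptop-scale runtime: coverage uses 200 surveys of n = 20,000;
Cox recovery 200 registries of n = 50,000; the type-I error check 400
replicates of an 8,000-respondent survey with a 2,000-case registry; the
power grid three effect sizes (0.4, 1.2, 2.4 per unit behavior) at 100
replicates each.  The default `TruthParams` scale (50,000 / 5,000) is the
desk-scale world for interactive runs.

## Known behaviors worth knowing

- The **unadjusted** probability-exposure estimate is confounded by age in
  the default world (smoking probability falls with age while the hazard
  rises), and can even change sign relative to the true behavior effect;
  adjustment for age and stage restores the expected direction.  This
  mirrors the unadjusted/adjusted inversion the method is designed to
  expose, and it is why the validity surface (power, attenuation) is
  measured on the adjusted model.
- The attenuation ratio of the adjusted probability-exposure estimator is
  measured, not assumed: in the default world it sits well below 1 and
  shrinks further as the true effect grows (the exposure-outcome relation is
  nonlinear in p).
- Lag-1 eligibility: the lagged year for 2001 diagnoses (2000) precedes the
  survey era.  The default restricts lag 1 to 2002-2015 diagnoses; a switch
  (`allow_2001_lag1`) permits extrapolation to year code -1 instead.  Lagged
  age bands that fall below the survey's fitted range (under 25) mark the
  case ineligible rather than clamping.
- Weight trimming drops rows strictly below the 0.5th or strictly above the
  99.5th empirical percentile (linear-interpolation quantiles, ties at the
  threshold retained, no renormalization afterwards), computed on the
  post-eligibility table once per behavior fit.
- `PrepReport` attributes every removed row to exactly one filter, in the
  documented order (year, age, state, mixed race), so run logs reconcile
  exactly.
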