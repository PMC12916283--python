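# Methods

`bsdrisk` implements a prognostic-modelling pipeline for the onset of
bipolar-spectrum disorder (BSD) in a right-censored adolescent
inpatient cohort: univariate Cox screening, an L1-penalized (lasso) Cox
model with imputation nested inside the validation loop, time-resolved
discrimination, minimum-AIC risk stratification, and the published
four-item risk calculator. This note records the model, the choices
made where the design was open, and what the synthetic experiments do
and do not establish.

## Outcome model and screening

Follow-up is measured in months from baseline (values reported in
years are months/12). Each subject contributes an observed time — BSD
onset, loss to follow-up, or the administrative 60-month horizon,
whichever comes first — and an event indicator.

Screening fits one Cox proportional-hazards model per baseline
predictor by Newton–Raphson with step-halving on the Breslow
partial likelihood (convergence when the log-likelihood gain falls
below 1e-9, at most 50 iterations). Covariates are standardized
internally; a fit whose standardized slope exceeds 10 in absolute value
is flagged *divergent* (complete separation: the likelihood increases
without bound, the pattern behind zero-event cells that print HR 0 with
p ≈ 1), and a constant covariate yields a flagged *non-estimable*
result (HR 1, infinite CI) rather than an exception. Wald 95% CIs are
symmetric on the log-hazard scale; all p-values are two-tailed at
alpha = 0.05. Screening is complete-case; only the multivariable
pipeline imputes. Kaplan–Meier estimation (via lifelines) handles
event/censoring ties events-first.

## Penalized solvers

All three lasso families minimise (negative log-likelihood)/n +
lambda·Σ|beta_j| on predictors standardized to mean 0 and *population*
SD 1 (divisor n); zero-variance columns are dropped with a warning, and
coefficients are reported on both the standardized scale (on which the
relevance metric is defined) and the original scale. The solver is
cyclic coordinate descent with active-set cycling; binomial and Cox
wrap it in an outer quadratic approximation (IRLS; Breslow partial
likelihood with a diagonal Hessian for Cox). Because plain IRLS is not
monotone — near-separated data can cycle between linearizations — the
outer step backtracks along the proximal-Newton direction whenever the
full step would raise the penalized objective; a converged solution is
certified by its Karush–Kuhn–Tucker conditions (subgradient residual
at most ~1e-6 on well-conditioned problems). Final fits converge when
the largest coefficient change falls below 1e-7; exploratory fits along
a cross-validation path use 1e-4, matching the effective tolerance of
the standard penalized-regression software this analysis mirrors.

Lambda is chosen by seeded inner k-fold cross-validation on deviance
with the "min" rule, on a log-spaced grid descending from lambda_max
(the smallest penalty that zeroes every coefficient): by default
10 folds and 100 grid points over 4 decades for the prognostic Cox
model. Cox CV deviance uses the Verweij–Van Houwelingen construction,
−2·(ℓ_all(beta_k) − ℓ_train(beta_k)), which remains defined when a
held-out fold carries few or no events. Two guards keep the path
well-posed in this p ≫ events regime: the path is frozen at the last
stable fit once it diverges or saturates (for Cox, once the active set
exceeds the event count, the partial likelihood's degrees of freedom),
and if the CV minimum falls in the frozen tail the final refit backs
off to the largest lambda with a stable full-data fit.

**Calibration finding.** The min rule is anti-conservative under the
null: on signal-free cohorts (n = 105, p = 20, ~20% events) the
selected model has at most one active predictor in only ~72–74% of
seeded runs — and R glmnet's `lambda.min` behaves the same way (~67%
on identical data). Tests therefore bound the null behaviour at the
rate the method actually attains (active ≤ 1 in ≥ 60% of runs, mean
active size ≤ 2) rather than at a nominal sparsity no min-rule
implementation reaches; a 1-SE rule would be sparser but is not the
rule this pipeline defines.

## Nested imputation and out-of-sample validation

The pipeline's central guarantee is structural: no subject's risk score
is ever produced by a model — imputation or Cox — whose training rows
included that subject.

Within each training sample, one lasso per incomplete predictor
(gaussian for continuous/ordinal, binomial for binary) regresses it on
all other predictors, never the outcome, after a single mean-fill pass
over the covariates; the m completions differ only in originally
missing cells, drawn stochastically (prediction + Normal(0, residual
SD), or Bernoulli at the predicted probability) so imputation
uncertainty propagates. m = 10 by default (the desk profile uses 5):
standard multiple-imputation practice balancing Monte-Carlo error
against cost. Columns with fewer than 10 observed training rows — or
binary columns whose minority class has fewer than 8 — fall back to a
marginal draw: a regression on that little information is pure noise. Imputation-model lambdas are selected with a
deliberately light rule (3 folds, 10 grid points, 1 decade): with ~90
predictor columns all carrying missingness, a full-depth search per
nuisance imputer per fold would cost far more than it could change the
completed values.

Leave-one-out cross-validation fits the imputation models and m
multiply-imputed Cox lassos on the n−1 other subjects (one Cox fit per
completed dataset, all sharing one inner-CV fold assignment so that a
complete dataset makes every imputation identical), imputes the
held-out subject with the training-fitted models, and averages the m
linear predictors into one out-of-sample score. Bootstrap out-of-bag
validation repeats the same pipeline on B = 1000 with-replacement
resamples (desk: 100), scoring the subjects left out of each bag;
per-subject scores average over the replications in which the subject
was out-of-bag (replications continue past B until every subject has
been scored at least once), and per-replication scores are retained for
interval construction. The score is the raw-scale Cox linear predictor
(log relative hazard); any monotone transform leaves every downstream
AUC and split unchanged.

Randomness is organised as one master seed spawning named substreams
per fold, replication and imputation (`numpy` SeedSequence), so any
fold can be re-executed independently and must reproduce its score
bit-for-bit — the leakage test exercises exactly that.

## Discrimination over time and risk stratification

Discrimination at month m is the cumulative-case/dynamic-control AUC:
cases are subjects with onset by m, controls are subjects still at risk
at m, ties count one half. Subjects censored earlier without an event
are excluded at that month — the simplest defensible handling, exactly
verifiable against brute-force pair enumeration; an
inverse-probability-of-censoring-weighted variant sits behind a flag
for sensitivity analysis. The monthly grid runs from month 1 to the
floor of the longest follow-up. Bands are percentile 95% intervals:
across bootstrap replications when per-replication scores exist (the
point estimate is then the mean of per-replication AUCs), otherwise
across a seeded bootstrap over subjects (500 resamples). A month is
flagged significant when its interval excludes 0.5 (two-tailed);
months with fewer than three cumulative onsets are flagged
low-confidence.

Risk stratification dichotomises the score at the threshold minimising
AIC = 2 − 2·ℓ of a one-parameter Cox model on the high/low indicator,
over midpoints between consecutive distinct scores with both groups
kept at ≥ 5 subjects (guarding against degenerate strata). The chosen
partition depends on score ranks only.

## The published calculator

The calculator is the linear score 0.833·[grandiosity present] +
0.079·[racing thoughts present] + 0.030·[overtalkativeness severity] +
0.035·[increased-energy severity], evaluated in decimal arithmetic at
the published precision; scores strictly above 0.172 are high-risk
(the boundary itself is low-risk — the published cutoff does not
define the tie, so the conservative side was chosen). The cross-validated
model also carries a negligible mood-lability term (beta = 0.001); the
published formula omits it and the calculator follows the formula. For
description only, a logistic regression of observed 20-month status on
log(score + 1e-16) maps scores to onset probabilities; the epsilon
guards zero scores, subjects censored before 20 months without onset
are excluded from the fit, and the intercept/slope are refit on
whatever cohort is supplied since they are not part of the published
model.

## The synthetic cohort

The generator emulates the study conditions the pipeline was built for,
not any particular patient population: 105 subjects, a baseline hazard
calibrated by bisection (closed-form expectation under competing
exponential event/censoring with a 60-month administrative cutoff) to
an expected 18 onsets, and exponential dropout at 0.04/month. That
dropout rate is what reconciles three published facts — ~17% crude
incidence, Kaplan–Meier cumulative risks of ~22%/36% at 2/4 years, and
a mean follow-up near 1.5 years — and the generated cohorts reproduce
all three to first order (KM risks ≈ 10/20/28/38% at 1–4 years under a
constant hazard, which cannot also bend the first-year curve the way
the real cohort's did).

Symptom severities come from a latent-Gaussian factor model (separate
mania/depression/general factors, default loading 0.5) thresholded to
the 0–6 ordinal scale with item means/SDs matched loosely to the
published baseline table; prevalence flags are severity ≥ 2 with 5%
flag noise that never asserts a symptom rated absent; YMRS and MADRS
totals load on the matching factors. Demographics, diagnosis and
medication flags are drawn at the published marginal frequencies
(joint dependence among the 30+ diagnoses is deliberately not
modelled). The generating signal defaults to the four published
calculator coefficients on their items; everything else is null.
Missingness is injected completely at random at 10% of numeric
predictor cells (a CGI-S-driven missing-at-random switch exists for
robustness checks); the categorical race column stays complete because
the gaussian/binomial imputation families do not cover multinomial
columns.

**What passing tests show.** Parameter recovery, support selection,
null calibration and the leakage guarantee are demonstrated under this
generator — proportional hazards, constant baseline hazard, MCAR
missingness, modest predictor correlation. Real cohorts can violate
each assumption (non-proportional hazards, informative dropout,
structured missingness, stronger collinearity), so green tests certify
the pipeline's internal correctness and calibration, not model
performance on clinical data. A further honest limit: under the default
generating signal (the published betas), even the true linear predictor
has a large-sample cumulative/dynamic AUC of only ~0.63, so at n = 105
the pipeline frequently and correctly returns an empty or near-empty
model; power properties are therefore tested under a strong-signal
configuration (the same beta pattern scaled ×3, true AUC ≈ 0.84,
inside the 0.72–0.86 discrimination range the method targets).

## Problem sizes used in tests and analyses

Module tests run the nested pipeline on 18–44-subject cohorts with
m = 2 and small bootstrap counts; the end-to-end acceptance run uses
the full study-scale cohort (n = 105) under the desk profile (B = 100,
m = 5, 25-point/2.5-decade Cox grid with 4 inner folds). Large-sample
checks use n = 5,000 (parameter recovery, missingness accounting) and
n = 100,000 (calibration closed form, where the 2% tolerance spans
three binomial SDs). Null calibration uses 50 seeded cohorts at
n = 105. The strategy-comparison harness defaults to desk scale
(3 replicates, B = 25) against a 10,000-subject oracle test set.

## Known limitations

- The constant baseline hazard makes calibration analytic but cannot
  reproduce the accelerating first-year risk the real cohort showed.
- Bootstrap bags with fewer than three in-bag events are recorded but
  contribute no scores; at study scale this is rare.
- The min-rule lambda selection over-selects under the null (see the
  calibration finding above); treat small selected models near the
  noise floor with caution.
- The 20-month probability mapping is descriptive: its logistic
  intercept and slope depend on the supplied cohort and carry no
  published reference values.
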