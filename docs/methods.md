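# Methods

## The problem

Cohort studies with a time-to-event outcome often also collect a
longitudinal predictor at intermittent visits — in the motivating setting,
ultra-high-risk psychiatric patients followed for transition to psychosis
with monthly symptom scores.  The conventional analyses feed the observed
measurements into Cox regression, either the baseline value alone or all
values via last observation carried forward (LOCF).  Both treat an
error-prone, intermittently sampled quantity as if it were the true
current value, which attenuates the estimated effect and can distort
confidence-interval coverage.  Shared-random-effects joint models address
this by modelling the longitudinal process and linking the hazard to its
latent value.  This package implements a simulation laboratory that
quantifies the comparison, together with from-scratch implementations of
all competing estimators.

## Data-generating model

For subject i with group indicator u_i ∈ {0, 1}:

* latent trajectory: m_i(t) = a0 + a1·t + b0_i + b1_i·t with
  (b0, b1) ~ N(0, D);
* observations: y_i(t) = m_i(t) + ε, ε ~ N(0, σ²), at day 0 and every 30
  days;
* daily hazard: h_i(t) = exp(λ0 + λ1·m_i(t) + τ·u_i) for integer days
  t = 0, …, 364.

Event times are piecewise exponential: within day t the hazard is constant
at h_i(t); a waiting time w ~ Exp(h_i(t)) is drawn and the event occurs at
t + w if w ≤ 1, otherwise the clock advances a day.  Survival to day k is
exp(−Σ_{t<k} h_i(t)) exactly, and event times are continuous so
partial-likelihood ties have probability zero.  Censoring is continuous
Uniform(1, 364) under the monotone regime.  Under the non-monotone regime
the 12 nominal post-baseline visits are jittered by an integer uniform on
[−7, 7], a uniformly-sized (0–12) random subset of occasions is missing,
and censoring is the day of the last non-missing assessment (day 0, with
the baseline visit retained, when every occasion is missing) unless the
event came first.  Post-event and post-censoring observations are
discarded.

Default parameter values: a0 = 40; a1 ∈ {0.02, 0.1} per day; σ² ∈ {16, 4};
λ0 = −4.8; λ1 = −0.03 per predictor unit; τ ∈ {0, −0.5}; four covariance
forms for D (Var b0 ∈ {32, 8}, Var b1 ∈ {0.002, 0.0005}, correlations
0.03–0.32); 150 subjects per group.  The canonical grid numbers the 32
zero-τ scenarios with monotone sets first, error variance varying slowest
(16 then 4), then slope (0.02 then 0.1), then covariance form (a–d); sets
33–36 clone sets 3, 7, 19, 23 with τ = −0.5.  These values emulate a
twelve-month transition-to-psychosis study in which the predictor behaves
like a global-functioning score.

Randomness is organised as one `SeedSequence` keyed on (root seed,
scenario set, replicate index), so replicates are independent,
reproducible, and identical no matter how work is distributed across
workers.

What the generator deliberately does not emulate: informative censoring,
competing risks, more than one longitudinal predictor, visit schedules
tied to disease state, or non-Gaussian measurement error.  Passing tests
therefore demonstrate estimator behaviour under a correctly specified
latent-Gaussian world, not robustness to those violations.

## Estimators

**Cox partial likelihood.**  Both conventional analyses reduce to the
Breslow partial likelihood on a counting-process table of (start, stop]
intervals, with a subject at risk at event time t when start < t ≤ stop.
The baseline-value analysis carries the day-0 measurement on a single
interval per subject; the LOCF analysis carries each visit's value until
the next visit.  The two-coefficient problem (predictor, group) is solved
by Newton–Raphson with analytic gradient and Hessian, step-halving, and a
diverging-coefficient guard for monotone likelihoods; standard errors come
from the inverse observed information and intervals are Wald.  Breslow tie
handling is essentially free here because simulated times are continuous;
for day-gridded cohort data it can differ slightly from Efron-based
software.

**Linear mixed model.**  The random-intercept/slope submodel is fitted by
direct ML (not REML, for comparability with the joint likelihood).
Because the fixed- and random-effect designs are both (1, t), each
subject's marginal likelihood depends on the data only through six
sufficient statistics, and the fixed effects are profiled out in closed
form via the Woodbury identity, making evaluation O(n) in subjects.  D is
parameterized by the log-Cholesky factor to enforce positive
semi-definiteness; time enters in units of 100 days so intercept- and
slope-type parameters are comparably conditioned (everything is reported
on the day scale).  Starting values come from the spread of per-subject
OLS lines.  Empirical Bayes modes and curvatures are the exact Gaussian
conditionals.

**Joint model.**  The hazard is h_i(t) = h0(t)·exp(γ·u_i + α·m_i(t))
(current-value association) with the trajectory model above.  Each
subject's marginal likelihood integrates the product of the survival and
longitudinal conditional likelihoods over (b0, b1) on a 9×9 tensor
Gauss–Hermite grid.  The rule is pseudo-adaptive: nodes are shifted and
scaled per subject by the empirical Bayes mode and curvature of the
preliminary LMM fit, then held fixed for the whole optimization.  Fixed
nodes buy two things: the α = 0 factorization of the likelihood into
LMM × survival parts is exact (the centred integrand is exactly
Gaussian), and the analytic gradient of the approximated log-likelihood
is simply the posterior-node-weighted complete-data score, which makes
quasi-Newton (L-BFGS-B) fits take a few seconds at n = 300.  A
non-adaptive variant (nodes centred at zero with the LMM covariance) is
available; it converges noticeably more slowly in the node count.

Two baseline hazards are provided.  Weibull: h0(t) = e^η·k·t^(k−1), with
the cumulative hazard times exp(α·m(s)) integrated by a fixed composite
Gauss–Legendre rule (15 panels × 5 points) applied after the substitution
s = v³, which removes the t^(k−1) endpoint singularity for any shape
> 1/3 (relative error ≲ 1e−7 for shapes in [0.7, 3]).  Piecewise
constant: six intervals with knots at equally spaced quantiles of the
observed event times; because m is linear in t the cumulative hazard is
closed-form on each interval via (e^{db} − e^{da})/d, with series
expansions guarding the d → 0 limit.

Initialization: longitudinal block from the LMM, γ from a LOCF Cox fit,
α = 0, baseline from the occurrence/exposure rate.  Convergence uses
L-BFGS-B defaults with relative tolerance 1e−8 and up to 200 iterations;
non-convergence is data, reported as a flagged fit and an NA cell
downstream, never an exception.  Standard errors for (α, γ) come from the
inverse of the observed information computed by central differences of
the analytic gradient (step 1e−4 on the internal scale).  Internally α is
scaled by 10 and slope-type parameters by the 100-day time unit for
conditioning; all reported values are on natural scales.

## Evaluation metrics

Per scenario × method the study reports, over converged replicates only:
coverage of the 95% Wald interval (closed interval, so a truth on the
endpoint counts as covered) and the percentage of estimates strictly
below the true value — near 50 for an unbiased, symmetric estimator.
Cells are flagged when coverage < 90 or the percentage leaves [40, 60].
Boundary conventions (closed CI, strict inequality) are immaterial under
continuous estimators but fixed here for determinism.  Non-converged
replicates are excluded from denominators and counted separately; a cell
with no converged replicates is NA.

## Cohort-data stage

The period-record reader accepts one row per assessment period (subject,
family history yes/no, start day, end day, transition status, HAMD score
0–96), validates contiguity and the status-only-on-last-row invariant,
and converts to the internal pair of tables: the score on a period is
treated as measured at the period's start day (the counting-process
convention for when the assessment was made), each subject's first period
start is the time origin, and follow-up may exceed the simulator's
one-year horizon.  All estimators then run unchanged, with family history
as the group covariate and the depression score as the longitudinal
predictor.  Because the original study file is not redistributable, the
module ships a synthetic stand-in generator with the same schema and
broadly similar magnitudes, used by the tests and examples; it is clearly
labelled synthetic and is not a calibrated reproduction.

## Problem sizes and numerical notes

The shipped study runs use 100 replicates per scenario for the Cox
methods and for the Weibull joint model (a joint fit takes ~1 s at
n = 300, so no scale-down is needed); the large-sample recovery check
uses a single n = 3000 replicate.  Quadrature resolution is validated by
9-vs-15 and 9-vs-25 node comparisons (≤ 1e−3 and ≤ 1e−4 on a 20-subject
fixture) and the Gauss–Legendre rule against adaptive quadrature.
Exponent arguments are capped at 700 to avoid overflow during early
optimizer exploration; the LMM objective returns a large finite penalty
instead of NaN when 2×2 determinants cancel catastrophically at extreme
parameters.

## Known limitations

* The unspecified-baseline (nonparametric) joint fit, B-spline baselines,
  bootstrap standard errors, lagged and slope association structures, and
  Bayesian estimation are out of scope.
* The pseudo-adaptive centring comes from the longitudinal fit only; for
  data where the survival information about (b0, b1) is much sharper than
  the longitudinal information the fixed grid can be mis-centred.  The
  node-count convergence checks guard against this in the settings used
  here.
* For the large-error monotone scenarios the baseline-value Cox bias
  diagnostic produced by this generator is a few points stronger than the
  reference values the acceptance checks target; the discrepancy is
  consistent across seeds (see the README's reproduction section) and is
  analysed quantitatively in the repository's review notes.
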