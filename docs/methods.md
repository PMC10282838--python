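# Methods

This note documents the model, the numerical choices, and the deliberate
design decisions behind `panssboost`, in the spirit of a statistical
package's model documentation.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Outcome model

A PANSS factor with *n* items has an integer total *y* ∈ [*n*, 7*n*].  Totals
are mapped to the unit interval by `y_rescaled = (y − n + 1)/(6n + 1)`, which
is strictly positive at the floor and exactly 1 at the ceiling.  The ceiling
is representable but rejected by model fitting: the beta likelihood needs the
open interval, and ceiling scores are clinically rare (the generator never
produces them; real data containing them should be flagged, which the model
constructor does with an explicit error).

The rescaled outcome is modelled as Beta(μ, σ) in the mean/scale
parameterization: E = μ, Var = μ(1 − μ)σ², both parameters in (0, 1) and
logit-linked to additive predictors.  The classical shapes follow as
α = μs, β = (1 − μ)s with concentration s = (1 − σ²)/σ² — the unique
parameterization consistent with the stated variance function and a
logit-linked scale.  Gradients of the log-likelihood with respect to both
predictors are analytic (digamma terms composed with the chain rule through
the shape map and logistic links) and are verified against central finite
differences to 1e−6 relative error in the permanent test suite.  Inside
gradient and risk evaluation μ and σ are clipped to [1e−10, 1 − 1e−10];
clipping is logged.  The log-likelihood is concave in η_μ near the optimum
but not globally (the score saturates in the tails); the damped updates keep
fitting stable.

## Covariate encoding and base learners

Nine binary covariates are 0/1 dummies (uncentered); eight numeric
covariates (year, age, PDD:DDD, five admission totals) are mean-centered,
and the training means are stored so held-out data are centered identically.
Every covariate receives an intercept-free linear base learner; every
numeric covariate additionally a P-spline.  All learners are calibrated to
**one effective degree of freedom** — trace of the smoother matrix — so
selection cannot favor flexible components.

P-splines are cubic B-splines on 20 equally spaced knots over the observed
range with a second-order difference penalty.  Because that penalty has a
two-dimensional null space (constant + linear), the raw parameterization
cannot reach df = 1 (its trace is bounded below by 2).  We therefore use the
centered reparameterization standard in boosting software: the null space —
whose job is already done by the model offset and the linear learner — is
removed via the eigendecomposition of the penalty, and the remaining
directions carry a ridge penalty whose λ is found by bisection on log₁₀λ
(bracket [−12, 12], widened if needed; tolerance well below 1e−8).  df is
defined as trace(S); the alternative trace(2S − SᵀS) is not used.  Outside
the training range the basis is extended linearly (value + derivative at the
boundary), which keeps held-out folds and partial-dependence grids from
polynomial extrapolation.

A dedicated intercept base learner (a df-1 projection onto the constant
column) joins the candidate set for each predictor.  The model offsets are
initialized once by a method-of-moments intercept fit — logit of the sample
mean, and logit of σ̂ with σ̂² = s²/(ȳ(1 − ȳ)) clipped to [1e−6, 1 − 1e−6] —
and never refit.  That initial σ̂ absorbs the *marginal* outcome variance,
which includes the location-signal variance, so as the location model
improves, the best-fitting scale level drifts downward.  Without an
intercept component that drift is soaked up by whichever covariate learner
best mimics a constant, misattributing a global adjustment to an arbitrary
variable; with it, level adjustments are labelled as such.  The intercept
component is not a covariate and is excluded from selection frequencies.
Constant covariate columns (possible in tiny CV folds) are skipped with a
warning.

## Boosting

Both predictors start at the offsets.  Each iteration computes the
negative-gradient vectors for η_μ and η_σ, fits every base learner to each
by penalized least squares, and forms damped candidates η + ν·fit with
ν = 0.1.  The accepted update is the single (predictor, learner) candidate
with the lowest realized empirical risk (summed negative log-likelihood) —
an exhaustive greedy rule, evaluated with a vectorized batched likelihood.
Exactly one predictor changes per iteration; ties (risk difference below
1e−12 across predictors) resolve to μ, and within a predictor to the earlier
learner index, so fits are deterministic.  The risk sequence is
non-increasing by construction.  Empirical risk is the sum (not mean) of
negative log-likelihoods; the constant factor is fixed for reproducibility
of logged values.  With persistent updates the path converges to the
penalty-free maximizer spanned by the selected columns; with one linear
learner per predictor plus the intercept component this is exactly the joint
four-parameter maximum-likelihood beta regression, which the acceptance
checks verify against an independent numerical optimizer.

`mstop` (capped at 1,000) is tuned by k-fold cross-validation of the mean
held-out negative log-likelihood, recorded along the boosting path of each
fold (equivalent to, and verified against, refitting from scratch at each
grid point); the default grid is every integer up to the cap, ties go to
the smallest value.

## Internal validation

Nested cross-validation repeats the whole procedure: each outer fold tunes
`mstop` on its training part by inner k-fold CV (inner folds re-randomized
per outer fold from the master seed via seed-sequence spawning), refits, and
records pseudo-R² (squared Pearson correlation between logit(y) and η̂_μ;
zero, flagged, for constant vectors), RMSE on the logit scale, per-variable
selection flags, and the held-out PIT intervals.  Optimism is reported as
train − test for pseudo-R² and test − train for RMSE, so positive values
mean the apparent fit flatters the model.  Failed folds are logged, counted
and excluded.

Probabilistic calibration uses the non-randomized PIT for discrete
outcomes: a fitted beta is discretized by slicing its CDF at edges midway
between consecutive rescaled scores, with the outer edges pinned at exactly
0 and 1 (the masses then telescope to one by construction).  Each
observation spreads unit mass uniformly over its CDF jump
[P(Y ≤ y−1), P(Y ≤ y)]; a calibrated model yields a uniform histogram, and
depleted top bins signal over-forecasting.  Note the rescaled lattice is
right-shifted (its maximum is exactly 1), so at μ = 0.5 the discretized pmf
is symmetric across its regular interior bins while the two extreme scores
differ by half a bin of tail mass; the uniform special case makes this
exact: masses 1.5/(6n+1), 1/(6n+1)…, 0.5/(6n+1).

Smooth summaries use a locally weighted least-squares smoother (tricube
weights, local quadratic, span 0.75, 100-point grid), verified against a
direct weighted least-squares solve.

## Interpretation

Variable selection frequency is the fraction of refitted models in which any
base learner of a variable updated a given predictor at least once.  Partial
dependence follows Friedman: set the variable to a grid value in every
training row (numeric grids: 50 points between the 1st and 99th percentile;
binary: {0, 1}), predict, and average over the empirical covariate
distribution — either the predicted parameter itself or, after
discretization, the probability of each integer score.

A caution that the synthetic experiments in the test suite make concrete:
at-least-once selection frequencies are liberal.  With ~15 candidate
covariates at n = 320, the largest chance covariate–outcome correlation is
around 0.13, and cross-validated early stopping — which keeps iterating
while genuine signal and the scale-level adjustment still improve held-out
risk — does not stop before such a covariate is picked up at least once in
most of the heavily overlapping refits.  High selection frequency is
therefore evidence of *stability of selection*, not of effect size; the
partial-dependence curves, which are near-flat for such covariates, are the
complementary check.  (Stabilized selection procedures are out of scope.)

## Synthetic cohorts

The generator emulates the published admission cohort: Bernoulli binaries at
the printed percentages; year and age normal, PDD:DDD log-normal, each
matched to the printed median and interquartile range; admission factor
totals drawn by discretizing factor-specific betas whose quartiles are fitted
to the printed quartiles, coupled by a Gaussian copula (default correlation
0.4 between the negative and disorganized factors, echoing their mutual
cross-prediction; other pairs independent — true correlations in the source
cohort are unknown).  Age and year are rounded to one decimal, PDD:DDD to
two, mirroring the recorded precision; extreme ages are not truncated.

Discharge totals come from a configurable true model: linear coefficient
maps on raw covariates centered at fixed population constants (the printed
medians), a continuous beta draw, and the nearest-attainable-score map
(ties toward the smaller score) — the same discretization the analysis side
uses.  Draws are capped just below the ceiling score, mirroring its absence
in the source cohort and keeping every generated row fittable.  The default
truth makes each factor's own admission total the dominant location
predictor (0.12 per raw point, about ±0.5 logits over the admission IQR),
adds a 0.05 cross-effect between the negative and disorganized factors, and
keeps the scale constant at σ = 0.3; intercepts place the marginal discharge
medians at the published values.  Under these defaults the nested-CV
out-of-sample pseudo-R² for the negative factor lands near the published
internal-validation value, which is what makes the generator a meaningful
stand-in.  What it does **not** emulate: item-level structure, longitudinal
within-admission dynamics, diagnosis-specific subgroups, nonlinear or
heteroscedastic true effects.  Passing tests therefore demonstrate that the
pipeline recovers the structure this generator encodes, not that the
clinical findings themselves replicate.

## Problem sizes and determinism

The full published protocol (inner 10-fold CV, outer 100×10-fold, mstop up
to 1,000) remains the package default.  The test suite and the acceptance
script run the same code at reduced sizes chosen as sensible defaults for a
single workstation: 5 repeats × 5 folds with inner k = 5 and an mstop grid
to 200 for the recovery study (cross-validated optima on the default cohort
fall well inside that grid), and two three-fold runs at n = 120 for the
determinism check.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning; identical seeds give byte-identical
result bundles, and each run's manifest records seed, settings and package
version.

## Known limitations

- Offsets are never refit; level adaptation happens through damped intercept
  updates, so very early stopping can leave the scale level biased upward.
- Selection frequencies overstate weak effects (see above).
- The pseudo-R² is computed on the logit scale, matching the RMSE scale; a
  proportion-scale variant would differ.
- The discretization's outer bins are asymmetric by construction; predictive
  masses for the floor score are slightly inflated relative to a symmetric
  scheme.
- P-spline knot count, penalty order and the df formula are conventional
  choices; the method's behavior is insensitive to them at df = 1, but they
  are not tuned.
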