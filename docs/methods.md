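# Methods

## Setting and data-generating model

We consider a platform trial that starts with one experimental arm (k=1) and
a control (k=0); after `N1` patients a second experimental arm (k=2) enters,
so the trial has two periods (the machinery generalises to S periods; the
period factor then has S-1 indicator contrasts with period 1 as reference).
Patients enrol one per time unit, so the patient index `j` doubles as
calendar time. Outcomes are generated from

    g(E[Y_j]) = eta0 + theta_{k_j} + f_{k_j}(t_j)

with identity link and i.i.d. N(0, sigma^2) residuals for continuous
endpoints, and logit link with Bernoulli outcomes for binary endpoints.
Treatment effects are mean differences (continuous) or log odds ratios
(binary; supplied as odds ratios and converted internally). Time trends
`f_k` are arm-specific multiples `lambda_k` of one of three shapes:

- linear ramp `(j-1)/(N-1)`,
- step `I(j > N1)`,
- inverse-U `(j-1)/(N-1) * (I(j <= Np) - I(j > Np))`, which flips sign at
  the turning point `Np` and is therefore discontinuous there.

The inverse-U is implemented exactly in this discontinuous form; a
continuous tent variant with the same peak exists behind
`continuous_inverse_u=True` for sensitivity checks only, because the
discontinuous form is the defined scenario. `lambda_k` is on the model
scale: outcome units (continuous) or log-odds (binary). Negative values give
a U shape. Entry times default to `t_j = j`; an optional mode replaces them
by N sorted Uniform(1, N) draws, our stand-in for random accrual (the exact
distribution is a design choice; results are insensitive to it).

## Randomisation

Default allocation is permuted blocks within periods: each full block is a
uniform random permutation of the block composition implied by the period's
allocation ratio (blocks of 4 at 1:1 in period 1; blocks of 12 at 2:1:1 in
period 2, with the late arm carrying the double weight — the per-period
sample sizes identify it unambiguously). Period sizes need not divide the
block size: we fill complete blocks and then draw one truncated block as a
random permutation of exactly the residual labels, so realised cell counts
always equal the design counts. This truncation rule is our choice; it
preserves the fixed-cell-count algebra the closed-form estimator relies on.

"Simple" randomisation is implemented conditionally on the final counts (a
random permutation of the period's label multiset), again keeping `n_{k,s}`
fixed. An unconditional Bernoulli mode exists behind a flag; it is the
setting in which residual-variance heterogeneity across periods can distort
the linear model's t-test, which is why block randomisation is the default
and the recommendation.

## Analysis methods

All methods test the one-sided null `H02: theta_2 <= 0` (larger is better)
at alpha = 0.025 by default. Continuous endpoints: ordinary least squares
with the classical covariance and a t-test on the residual degrees of
freedom — `pooled` and `separate` thereby coincide with the equal-variance
two-sample t-test (Welch available via a flag). Binary endpoints:
maximum-likelihood logistic regression by Newton/IRLS with a Wald z-test.
Wald (rather than likelihood-ratio) inference is a documented choice.

Numerical choices for the logistic fits: score-norm tolerance 1e-8, at most
50 iterations, intercept initialised at the empirical logit. A fit that
fails the tolerance, produces a singular information matrix, or "converges"
with linear predictors beyond +-20 (fitted probabilities within ~2e-9 of 0
or 1, the signature of separation — the MLE is at infinity) is flagged
non-converged and carries no estimate. Non-converged replicates are excluded
from operating characteristics and counted separately. Linear-time models
use the raw index `j` as regressor; centring would change only the
intercept.

Degenerate inputs: a missing control or tested arm raises an error before
fitting; collinear or empty design cells raise (continuous) or flag
non-convergence (binary); zero residual degrees of freedom raise.

## Closed-form estimator and rho

For continuous data the all-arm step model's `theta2` estimate equals a
weighted sum of cell means with weights `(-rho, -(1-rho) | +rho, -rho | 0, +1)`
and `rho = (1/n02) / (1/n01 + 1/n11 + 1/n02 + 1/n12)`. This general form is
not printed in our source material; it is adopted because the test suite
verifies it against a brute-force least-squares oracle (the hat-row of the
theta2 coordinate summed within cells) over random count grids, and any
discrepancy would be resolved in favour of the oracle. Equivalently
`theta2~ = ybar22 - y02~` with the model-based period-2 control estimate
`y02~ = (1-rho) ybar02 + rho [ybar01 + (ybar12 - ybar11)]`, and `rho` is
exactly the fractional variance reduction of `y02~` versus `ybar02`. Under
equal control/arm-1 randomisation it reduces to `(1/2) n01/(n01+n02) < 1/2`.

Analytic power calculators calibrate scenarios: exact noncentral-t power for
the pooled t-test, and a normal-approximation two-proportion z-test power
with unpooled variance by default (the pooled-p̄ variant is exposed too; at
the calibration point n=250/group, delta=0.25, sigma=1 and p0=0.7, OR=1.8
both land at 80 % within a fraction of a point).

## Simulation engine

Replicate `r` of a run draws from an independent RNG stream keyed by
`SeedSequence(base_seed, spawn_key=(..., r))`, so results are deterministic,
independent of execution order, and any replicate can be reproduced in
isolation. Within a replicate every requested method is fitted to the same
dataset (paired design), which removes shared Monte-Carlo noise from method
comparisons. Reported per method: rejection rate with binomial Monte-Carlo
SE, bias and RMSE of the effect estimate, mean reported SE, and converged
replicate counts. Scenario grids take the Cartesian product over trend
pattern, per-arm strengths, turning point and hypothesis; sweeps expressed
as "arm-1 period-2 level X" convert to `lambda1` on the model scale via
`lambda1 = X - eta0 - theta1` (continuous) or
`logit(X) - logit(p0) - log(OR1)` (binary).

Default problem sizes: the canonical design (125/125 per period for control
and arm 1, 250 for arm 2; N = 750) and 10,000 replicates per scenario. We
chose 10,000 as the package default because it gives a Monte-Carlo SE of
~0.0016 on a 2.5 % rejection rate — small enough to resolve every effect the
test suite asserts — while keeping full scenario sweeps at desk scale; all
stochastic tolerances are stated as multiples of the Monte-Carlo SE actually
realised. The empirical check of the variance-reduction identity uses 20,000
simulated null trials with batch-based Monte-Carlo SEs.

## What the generator does and does not emulate

The generator reproduces the structural features that drive the statistics
of interest: staggered arm entry, fixed cell counts under block or
conditional simple randomisation, additive (on the link scale) arm-specific
time trends, and homoscedastic Gaussian or Bernoulli outcomes. It does not
emulate patient covariates, missing data or intercurrent events, interim
analyses or adaptive stopping, non-additive trends (ceiling effects),
time-to-event or count endpoints, or accrual that varies in rate. Passing
tests therefore demonstrate the estimators' properties under the stated
model — unbiasedness and level control require *equal, additive* trends, and
the suite also exercises violations of that assumption — but say nothing
about robustness to features outside the model, which real trials may have.

## Known limitations

- The closed-form weight machinery covers the two-period, three-arm layout;
  more periods or concurrent arms are handled numerically by the model fits.
- Logistic level control is asymptotic; at small cell sizes the Wald test
  can be conservative or anticonservative.
- The heteroscedastic variant of the linear model (different residual
  variances per period) is not implemented; block randomisation is the
  supported remedy.
- The inverse-U discontinuity is intentional (see above); users wanting a
  smooth bump should use the tent variant knowingly.
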