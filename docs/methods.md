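# Methods

## Trial model

We study a two-stage multi-arm trial: `K` experimental arms plus a shared
control recruit through stage one; at the end of stage one (after
`N_1 = sum_k n_k1` patients) a new experimental arm `K+1` joins with
`n_{K+1,2}` patients, and all arms recruit to completion in stage two.
The *timing* of addition is the fraction `n_01/n_0` of control patients
already enrolled when the arm joins; control data split accordingly into
non-concurrent (stage one) and concurrent (stage two) with respect to the
new arm.

Responses are continuous, `X_j = mu_{T_j} + tau(j) + eps_j` with
`eps_j ~ N(0, sigma^2)` i.i.d. and `sigma^2` known. The enrolment index
`j` runs globally across stages (stage two continues from `N_1 + 1`),
which matters because the linear trend normalises by the full-trial
denominator: `tau(j) = lambda (j-1)/(N + n_{K+1,2} - 1)`. The step trend
is `tau(j) = lambda c_j` with `c_j` the stage-two indicator. `lambda` is
in response units — a fraction of one standard deviation when
`sigma^2 = 1` — and may be negative; both trends are monotone in
enrolment order, emulating drifts such as improving standard of care or
shifting case mix.

Allocation is restricted randomization within each stage, implemented as
one uniformly random permutation of the stage's allocation multiset. This
is the weakest scheme that makes per-arm per-stage counts exact in every
realisation, which is the property the stage-wise analyses rely on; any
finer blocking would only reduce within-stage imbalance in `j`, which
enters no estimator except through the `Ma1`/`Mb1` covariate.

## Analyses

All hypothesis tests are marginal, one-sided superiority tests at level
`alpha` with no multiplicity adjustment, using the known `sigma^2`.

* **Z-tests.** `Xbar_k - Xbar_0` with variance `sigma^2/n_k + sigma^2/n_0`
  (all-control scope), or for the added arm the concurrent version
  `Xbar_{K+1,2} - Xbar_{0.2}`.
* **Stage-wise GLS (`WLS_all`, `WLS_s2`).** The observed stage-wise mean
  differences `Xbar^(k)_s = Xbar_{k.s} - Xbar_{0.s}` (k = 1..K, both
  stages) are stacked with the added arm's contrast — against the
  stage-two control mean (`s2`) or the overall control mean (`all`) — and
  fitted by generalized least squares:
  `delta_hat = (D' S^-1 D)^-1 D' S^-1 y`, `cov = (D' S^-1 D)^-1`. The
  covariance `S` has `sigma^2/n_ks + sigma^2/n_0s` on the diagonal,
  `sigma^2/n_0s` between same-stage contrasts (the shared control cell),
  zero across stages, and `sigma^2/n_0` between the overall-control
  contrast and every stage contrast, since
  `Xbar_0 = (n_01 Xbar_{0.1} + n_02 Xbar_{0.2})/n_0`.
* **Patient-level regressions.** `Ma1`/`Ma2` regress all responses on an
  intercept, arm indicators (control as reference) and either the raw
  enrolment order `j` (`Ma1`) or the stage indicator `c_j` (`Ma2`).
  `Mb1`/`Mb2` do the same on the control + added-arm subset only.
  Coefficient covariance is `sigma^2 (Z'Z)^-1`. `Mb2` is a saturated
  three-cell model, so its treatment coefficient is exactly the
  concurrent contrast; and `Ma2`'s inference on every `delta_k` is
  numerically identical to `WLS_s2` (asserted to 1e-9 in the tests): the
  stage effect absorbs all the stage-one control information the added
  arm could otherwise borrow. We treat that equivalence as exact, since
  the estimates agree realisation by realisation, not merely in
  distribution.

The unknown-variance t-test variants, simultaneous (Dunnett-type)
critical values, and trend-detection diagnostics are out of scope.

## Metrics and closed forms

Per method and hypothesis we report bias, rejection rate (type-I error
under the null regime, marginal power under the alternative), and
`rMSE = sqrt(bias^2 + variance)`. Because `sigma^2` is known, a trend
moves only the bias, never the estimator's variance. The analytic module
evaluates Z-test power
`Phi(delta / sqrt(sigma^2/n_k + sigma^2/n_0) - Phi^-1(1-alpha))`, GLS
marginal power from the diagonal of `(D' S^-1 D)^-1`, and the
borrowing-of-strength `BoS = (V_0 - V_a)/V_0`, where `V_0` and `V_a` are
the added arm's GLS variances under concurrent-only and all-control
scopes. `BoS` is defined only for the added arm — initial arms have no
non-concurrent controls. Fig-1-style curves default to a timing-grid step
of 0.05.

## Default study conditions

The simulation study grid fixes `K = 1`, `n_0 = n_1 = 550` (sized for 80%
Z-test power at `delta = 0.15`, `sigma^2 = 1`, one-sided `alpha = 0.05`),
effects `delta_1 = delta_2 = 0.15` (alternative) or 0 (null), timings
{0.25, 0.5, 0.75}, added-arm sizes {`n_02`, `n_0`, `2 n_0`} and trend
magnitudes `lambda` in {0.02, 0.04, 0.06, 0.08} for each family. Headline
Monte-Carlo quantities use 10,000 replicates per scenario: the Monte-Carlo
standard error on a 5% rejection probability is then about 0.002 and on a
bias about 0.001–0.002, sufficient for every value we report at its
printed precision. Unit and property tests use smaller designs and
2,000–4,000 replicates with 3-standard-error tolerances.

## Numerical conventions

* **Fractional stage splits.** `n_01 = round(timing * n_0)` with half-up
  rounding (so timing 0.25 of 550 gives 138); initial arms follow the
  control split. A one-patient shift changes no reported quantity at its
  displayed precision, which the variance formulas confirm directly.
  Timings that would leave zero concurrent or zero non-concurrent
  controls are rejected.
* **Degenerate variance.** With `sigma^2 = 0` the Z statistic is defined
  as `sign(estimate) * inf` (0 when the estimate is 0) rather than NaN.
* **Zero reporting.** In the bias table, aggregated |bias| below 1e-3 is
  reported as 0: unbiased estimators show the same magnitude with no
  trend, so it is Monte-Carlo noise at this replication level.
* **Raw `j` covariate.** The enrolment-order covariate enters `Ma1`/`Mb1`
  uncentred; centring would change only the intercept.
* **Seeding.** Every stochastic routine takes an explicit seed or
  generator. Grid scenarios derive seeds as
  `SeedSequence(master, spawn_key=coords)` with string coordinates hashed
  by CRC-32, so scenarios reproduce independently of execution order. The
  Monte-Carlo engine vectorises replicates in chunks; results are
  bit-reproducible given (seed, chunk size), and the chunk size is
  therefore part of the reproducibility contract.
* **Vectorised engine.** The scenario runner reduces every method to cell
  means or small per-replicate cross-product systems solved in batch; a
  test feeds the same realisation through this path and the per-trial
  estimators and requires agreement to machine precision. The per-trial
  GLS is additionally checked against an independently fitted generalized
  regression (statsmodels GLS) to ten significant digits, and the
  contrast covariance `S` against the empirical covariance of simulated
  contrasts.

## What the generator does and does not emulate

The generator reproduces the idealised conditions of the analytic theory:
normal responses, known and homogeneous variance, exact within-stage
randomization, simultaneous completion of all arms, and deterministic
trends that are identical across arms. Passing tests therefore certify
the estimators' behaviour *under these conditions* — they do not speak to
real trials with unknown or heteroscedastic variance, binary or survival
outcomes, staggered arm completion, patient covariates, or trends that
differ by site or arm. In particular, the finding that a linear-term
adjustment fails under a step trend generalises to any misspecified trend
shape, but the magnitudes reported here are specific to the grid above.

## Known limitations

Two stages and a single added arm only; marginal inference without
multiplicity adjustment; no interim analyses or early stopping; no
response-adaptive randomization; trend effects on power/type-I error are
studied by simulation only (no closed form under a trend is attempted).
Published simulation values are matched statistically, within Monte-Carlo
error — the original random streams are unknowable, so bit-for-bit
agreement with any external table is out of reach by design.
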