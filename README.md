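# platformtrial

Simulation and analysis of two-stage platform trials that add a new
experimental arm mid-trial, for trial statisticians weighing a recurring
design question: **should the analysis of a newly added arm use the
non-concurrent control data** (control patients enrolled before the arm
joined), or only the concurrent controls?

Using all control data buys precision — but if patient outcomes drift over
time, the non-concurrent controls are drawn from a different outcome level
than the new arm's patients, and the extra data buys bias instead. This
package quantifies both sides of that trade, analytically where closed
forms exist and by Monte-Carlo simulation where they do not.

## The model

A trial starts with `K` experimental arms and a shared control (arm 0),
`n_k` patients per arm. After a fraction `n_01/n_0` of the control patients
— the *timing* of addition — stage one ends and arm `K+1` joins with
`n_{K+1,2}` patients. Patient `j`'s response is

```
X_j = mu_{T_j} + tau(j) + eps_j,    eps_j ~ N(0, sigma^2) iid
```

where `T_j` is the allocated arm (restricted randomization within each
stage: exact per-arm counts) and `tau(j)` is an optional time trend, either
**linear** (`lambda * (j-1) / (N_total - 1)`, a drift from 0 up to `lambda`)
or **step** (`lambda` added to every stage-two response). All tests are
one-sided superiority tests of `H_0k: mu_k = mu_0` at level `alpha` with
`sigma^2` known.

Eight analyses are implemented: independent Z-tests (concurrent-only or
all control data); the stage-wise mean-difference GLS model in its
all-control (`WLS_all`) and concurrent-only (`WLS_s2`) variants, with the
shared-control covariance `cov(Xbar^(l)_s, Xbar^(k)_s) = sigma^2 / n_0s`;
and four patient-level regressions (`Ma1`, `Ma2` on all arms; `Mb1`, `Mb2`
on control + added arm only) adjusting for a linear enrolment-order term
(`*1`) or a stage indicator (`*2`). The borrowing-of-strength measure
`BoS = (V_0 - V_a) / V_0` is the proportional reduction in
`var(delta_hat_{K+1})` from including non-concurrent controls.

## Worked example

```python
>>> import platformtrial as pt
>>> design = pt.TrialDesign(K=1, n_arm=(550, 550), timing=0.5, n_new=275)
>>> design.n_ks          # per-arm stage-wise sample sizes
array([[275, 275],
       [275, 275],
       [  0, 275]])
>>> pt.ztest_power(0.15, 1.0, 550, 550, 0.05)   # the design basis
0.8003
>>> pt.borrowing_of_strength(pt.TrialDesign(1, (550, 550), 0.9, 55))
0.2903
```

With 550 patients per initial arm and an effect of 0.15 standard
deviations, the Z-test has 80% power; adding the new arm at timing 0.9
with a concurrent-sized arm, non-concurrent controls cut its estimate's
variance by 29%.

A Monte-Carlo scenario — step trend of 8% of a standard deviation, arm
added at timing 0.5, 10,000 replicates:

```python
>>> effects = pt.EffectSpec.uniform(1, 0.15)
>>> summary = pt.run_scenario(design, effects, pt.TrendSpec("step", 0.08),
...                           n_reps=10_000, seed=42)
>>> summary.table[summary.table.param == "delta_2"]
      method   param    bias  reject_rate   rmse
Z_concurrent delta_2  0.0002       0.5471 0.0856
       Z_all delta_2  0.0398       0.8243 0.0839
     WLS_all delta_2  0.0398       0.8243 0.0839
      WLS_s2 delta_2 -0.0001       0.5928 0.0797
         Ma1 delta_2  0.0124       0.6726 0.0789
         Ma2 delta_2 -0.0001       0.5928 0.0797
         Mb1 delta_2  0.0148       0.6473 0.0827
         Mb2 delta_2  0.0002       0.5471 0.0856
```

The all-control GLS estimate absorbs a bias of `lambda * n_01/n_0 = 0.04`
— exactly the non-concurrent fraction of the trend step — which inflates
its rejection rate from 0.59 to 0.82. The concurrent-scope analyses
(`WLS_s2`, `Ma2`, `Mb2`) stay unbiased; the linear-adjustment models
(`Ma1`, `Mb1`) remove only part of a *step* trend. Note `Ma2` reproduces
`WLS_s2` line for line: adjusting for a stage effect is the same analysis
as using concurrent controls only.

A `platformtrial` command-line tool wraps the same library:

```sh
platformtrial simulate --timing 0.5 --n-new 275 --trend step --lambda 0.04 --seed 1 --out-dir out
platformtrial oc --out-dir out                      # analytic power/BoS curves
platformtrial grid --reps 10000 --seed 1 --out-dir out
platformtrial table1 --reps 10000 --seed 1 --out-dir out
```

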