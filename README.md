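# ncctrends

Simulation and analysis of **platform trials that use non-concurrent
controls**, for trial statisticians weighing the efficiency of a shared
control arm against the risk of bias from time trends.

In a platform trial, experimental arms enter and leave over time while
sharing one control arm. For an arm that joins late (arm 2), control patients
recruited *before* its entry are **non-concurrent controls (NCC)**; those
recruited alongside it are **concurrent**. Using NCC data increases power and
shrinks the required sample size — but outcomes drift over calendar time
(changes in standard of care, population shifts, seasonal effects), and an
unadjusted comparison against pooled controls can be badly biased.

## The model

Patients `j = 1..N` enrol one per time unit; a second experimental arm joins
after `N1` patients, splitting the trial into periods `s = 1, 2`. The package
fits and evaluates regression adjustments of the form

```
g(E[Y_j]) = eta0 + theta_1 I(k_j = 1) + theta_2 I(k_j = 2) + nu I(j > N1)
```

with the identity link and a t-test for continuous endpoints, the logit link
and a Wald z-test for binary endpoints, and the one-sided null
`H02: theta_2 <= 0`. Variants include an arm-1 x period interaction
(`ALLTCI-step`), a linear time term `gamma * j` instead of the step, fits on
the control + tested arm only (`TC-*`), and the unadjusted `pooled` /
`separate` comparisons.

For continuous data the all-arm step model has a closed weighted-means form

```
theta2~ = (ybar22 - ybar02) + rho [ (ybar11 - ybar01) - (ybar12 - ybar02) ],
rho     = (1/n02) / (1/n01 + 1/n11 + 1/n02 + 1/n12),
```

so the NCC information enters with weight `rho`, which is also exactly the
fractional variance reduction of the model-based period-2 control estimate:
`1 - Var(y02~)/Var(ybar02) = rho`. With equal cells of 125 (arm 2: 250),
`rho = 0.25` — a 25 % variance reduction.

A simulation engine measures type-1 error, power, bias and RMSE of the
estimators over scenario grids with step, linear or inverse-U time trends,
equal or arm-specific trend strengths `lambda_k`, and permuted-block or
simple randomisation.

## Worked example

```python
import ncctrends as nt

design = nt.make_design([[125, 125], [125, 125], [0, 250]])
print(nt.weights(design).rho)          # 0.25

scenario = nt.ScenarioSpec(
    design=design,
    trend=nt.TrendSpec("step", 0.15),  # equal step trend in every arm
    endpoint="continuous",
    eta0=0.0, effects=(0.25, 0.25), sigma=1.0,
    allocation="block", block_sizes=(4, 12),
)
data = nt.simulate_trial(scenario, seed=42)
print(nt.fit_model(data, "ALLTC-step").summary())
```

```
Platform trial treatment-effect analysis
========================================================
method:    ALLTC-step         endpoint: continuous
nobs:      750                tested arm: 2
test:      one-sided H0: theta2 <= 0 at alpha = 0.025
--------------------------------------------------------
coef          estimate     std err
eta0           -0.0497      0.0790
theta1          0.3118      0.0912
theta2          0.2284      0.1020
nu2             0.2155      0.0912
--------------------------------------------------------
theta2 = 0.2284 (SE 0.1020), stat = 2.239 (df 746), one-sided p = 0.0127
reject H0: True
```

The fitted step `nu2 = 0.216` absorbs the simulated drift of 0.15, and the
treatment estimate 0.228 sits close to the true `theta_2 = 0.25` with a
smaller standard error than a concurrent-only comparison would give.
Operating characteristics over 2,000 replicates of the same scenario:

```python
oc = nt.run_scenario(scenario, ["ALLTC-step", "ALLTCI-step", "separate", "pooled"],
                     n_reps=2000, base_seed=42)
print(oc[["method", "reject_rate", "bias", "rmse", "mean_se"]].round(4))
```

```
     method  reject_rate    bias   rmse  mean_se
 ALLTC-step       0.6985 -0.0026 0.0996   0.0999
ALLTCI-step       0.6080 -0.0060 0.1100   0.1094
   separate       0.6000 -0.0060 0.1100   0.1094
     pooled       0.9610  0.0735 0.1146   0.0895
```

The step model gains ~10 points of power over the concurrent-only analysis
at essentially zero bias; naive pooling is biased by the trend (its apparent
power is bought with a badly inflated type-1 error). The interaction model
tracks the separate analysis, because with the interaction term the NCC no
longer contribute to the estimate.

The same workflows are scriptable from the shell (`ncctrends simulate`,
`analyse`, `run`, `plot`) with YAML configurations; see
`ncctrends run --help` and the schema in `ncctrends/config.py`.

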