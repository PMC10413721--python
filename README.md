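# longmatch

Longitudinal matching methods for treatments that start at different times.

In observational studies of a static treatment that patients can initiate at
any point during follow-up — a preventative cardiac intervention, a targeted
therapy after genomic testing — covariates that influence both *when*
treatment starts and the outcome keep changing between baseline and the
treatment date.  Matching ever-treated to never-treated patients on a
baseline propensity score ignores that drift and yields biased effect
estimates (including immortal-time bias).  `longmatch` implements and
compares three matching strategies on simulated panel data with exactly this
structure:

1. **Baseline propensity-score matching** — 1:1 nearest neighbour on
   `Pr(z=1 | x at t0)` from a logistic model, the common but naive approach;
2. **Sequential risk-set matching** — at each interval `t`, newly treated
   subjects are matched to not-yet-treated subjects in the risk set `R_t` on
   the linear predictor `β'x(t)` of a Cox model with time-dependent
   covariates (a *proxied* time-dependent propensity score, since the hazard
   is not a probability);
3. **Longitudinal genetic matching** — within each risk set, matching on a
   weighted generalized Mahalanobis distance
   `d(x_i, x_j; W) = sqrt((x_i−x_j)' (S^{−1/2})' W (S^{−1/2}) (x_i−x_j))`
   whose diagonal weights `W` are chosen by an evolutionary search that
   lexically maximizes the sorted vector of covariate-balance p-values
   (bootstrapped Kolmogorov–Smirnov and paired t-tests) — automated balance
   tuning instead of manual model re-specification.

A Monte Carlo framework generates the panels: twelve binary/continuous,
time-invariant/time-dependent covariates (Gaussian-copula correlation,
AR(1)/MA(1) dynamics), logistic interval-by-interval treatment assignment
(at most once per subject, calibrated to a 1/3 ever-treated rate), and a
continuous outcome with a true additive treatment effect of 1.  Seven
scenarios (base, A–F) vary the functional form of the assignment model,
pairwise correlation, autocorrelation structure, and covariate marginals.
Methods are compared on covariate balance (standardized differences,
KS/paired-t p-values) and on bias, variance, and RMSE of the effect
estimate across replicates.  See `docs/methods.md` for the full model.

## Worked example

Compare baseline and time-dependent propensity-score matching on 20
base-case replicates of 1,000 subjects:

```sh
longmatch simulate --scenario base --method baseline_ps --method td_ps \
    --replicates 20 --seed 11 --out results/demo
```

which prints

```
 base baseline_ps  mean effect +1.3861  pct bias  38.61%  rmse 0.3995
 base td_ps        mean effect +1.0286  pct bias   2.86%  rmse 0.0832
```

The true effect is 1.  Matching on the baseline score overstates it by
~38% — treated subjects' time-dependent covariates (x5, x10) have drifted
upward by their treatment date in ways their matched never-treated controls'
have not — while sequential risk-set matching on the time-dependent score
removes nearly all of that bias.  Per-replicate estimates and summaries are
written under `results/demo/`.

The same comparison is available as a library:

```python
from longmatch import (calibrated_scenario, generate_dataset, fit_td_cox,
                       sequential_rsm, estimate_effect)

config = calibrated_scenario("base", master_seed=11)   # intercept -> 1/3 treated
dataset = generate_dataset(config, replicate_id=0)
cohort = sequential_rsm(fit_td_cox(dataset), dataset)
print(estimate_effect(cohort, dataset).theta_hat)
```

Genetic matching runs the same way with `--method genmatch` (tunable via
`--population`, `--generations`, `--ks-boot`, `--loss`, `--include-ps`); it
is the most expensive method — seconds to minutes per replicate depending on
the search budget.

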