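# regmsar

Bayesian regularized estimation of **two-level Markov-switching AR(1)
models** (MSAR(1)) for intensive longitudinal data — many repeated
measurements on many individuals, with a discrete latent two-state
process driving regime changes in each individual's series.

The package is aimed at quantitative researchers in psychology,
education and adjacent fields who model phenomena like student dropout
risk, inattention or affect dynamics, and who need to answer a variable
selection question: *which individual-level covariates predict the
latent state transitions?*  The number of candidate predictors `P` is
often large relative to the information in the data, so the transition
slopes call for shrinkage priors and a disciplined comparison of them.

## The model

For individual `i` at occasion `t`, the latent series follows a
state-switching autoregression,

    η_y,it | S_it = s  ~  N(A_s + B_s η_y,it−1 + γ η_z,it, σ_ε²),
    A_1 = B_1 = 0                         (anchored reference state)

and the two-state chain `S_it` starts in state 1 and moves with

    P(S_it = 1 | S_it−1 = 1) = logistic(η̃_it),
    P(S_it = 1 | S_it−1 = 2) = 0.05                (fixed return rate)
    η̃_it = β0 + β_x'η_x,i + ε0_i  [+ (β_z + β_xz'η_x,i) η_z,it  + lag terms]

with a random intercept `ε0_i ~ N(0, σ0²)`.  The slope vector
`β* = (β_x, β_z, β_xz, β_y, β_xy)` is estimated under one of four
regularizing prior families — **ridge**, **Bayesian Lasso**,
**adaptive Bayesian spike-and-slab Lasso** and the **regularized
horseshoe** — each with the sensitivity variants catalogued in
`regmsar priors list`.  The discrete chain is marginalized out of the
likelihood with the Hamilton forward filter, so the posterior is a
smooth function of the continuous parameters; sampling uses ensemble
MCMC (emcee) with rank-normalized split R-hat / ESS diagnostics
(arviz).  See `docs/methods.md` for the full account.

## Worked example

Simulate one cell of the time-invariant study design (5 covariates, two
true effects ±0.5, design SNR ≈ 0.08) and fit it under the default
ridge prior:

```python
from regmsar import (Sim1Design, generate_sim1, build_log_posterior,
                     sample_posterior, SamplerConfig, summarize)

sim = generate_sim1(Sim1Design(N=50, T=25, P=5, zero_rate=0.5, seed=7))
model = build_log_posterior(sim.data, "ridge-0")
draws, diag = sample_posterior(model, SamplerConfig(chains=4, seed=7))
print("converged:", diag.converged, " max R-hat:", round(diag.max_rhat, 3))
print(summarize(draws).round(3).to_string(index=False))
```

which prints

```
converged: True  max R-hat: 1.057
 parameter   mean    sd  lower  upper
        a2  2.974 0.025  2.925  3.023
        b2  0.801 0.003  0.796  0.806
 sigma_eps  0.248 0.005  0.238  0.257
     beta0  3.148 0.333  2.545  3.848
sigma_eps0  1.533 0.391  0.858  2.383
     gamma  0.477 0.007  0.464  0.490
   beta[1]  0.834 0.343  0.164  1.518
   beta[2] -0.608 0.361 -1.334  0.100
   beta[3] -0.350 0.353 -1.060  0.326
   beta[4] -0.230 0.313 -0.847  0.373
   beta[5] -0.448 0.347 -1.142  0.234
```

Reading the output: the within-level dynamics (`a2`, `b2`, `sigma_eps`,
`gamma`; truths 3, 0.8, 0.25, 0.5) are recovered sharply because every
occasion informs them.  The transition slopes `beta[1..5]` (truths 0.5,
−0.5, 0, 0, 0) are far noisier — at `N = 50` individuals and SNR 0.08
the 95% intervals span about ±0.7, and only `beta[1]` is selected under
the credible-interval rule.  This weak-signal behavior is exactly the
regime the replication harness quantifies: at larger `N`, `T` the
intervals tighten around the truths (the test suite checks recovery
within ±0.25 at `N = 100, T = 50`).

The same workflow is scriptable from the shell:

```sh
regmsar simulate --design sim1 --n 50 --t 25 --p 5 --seed 7 --out data/
regmsar fit --data data/ --prior ridge-0 --seed 7 --out fit0/
regmsar evaluate --fits fit0/ --truth data/truth.json --out metrics.csv
regmsar grid --config grid.yaml        # replication studies over design cells
```

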