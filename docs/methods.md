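# Methods

## The model

`regmsar` fits a two-level Markov-switching autoregressive model of
order 1 for intensive longitudinal data: `N` individuals observed over
`T` occasions, each carrying a latent two-state chain `S_it ∈ {1, 2}`.

**Within level.** Given the state, the (latent) series follows a
state-dependent AR(1):

    η_y,it | S_it = s  ~  Normal(A_s + B_s η_y,it−1 + Γ η_z,it, Σ_ε)

State 1 is the anchored reference state with `A_1 = 0`, `B_1 = 0`; the
state-2 intercept carries a positivity (half-normal) prior.  Together
these anchor the state labels, so no post-hoc relabeling is performed.
`Γ = (γ, 0, …, 0)` lets the time-varying covariate `η_z` act on the
first series component only.  For multivariate series, `Σ_ε` is
parameterized by a SD vector and a correlation Cholesky factor; all
shipped study designs are univariate (`K = 1`).

**Between level and transitions.** The chain starts in state 1 and
evolves with

    P(stay in 1) = logistic(η̃_it),      P(2 → 1) = p21 = 0.05 (fixed)

where the predictor decomposes as `η̃_it = μ0_i + μ1_it + μ2_it−1`: a
random intercept `μ0_i = β0 + β_x'η_x,i + ε0_i` with `ε0_i ~ N(0, σ0²)`,
an optional time-varying part `μ1_it = (β_z + β_xz'η_x,i) η_z,it`, and an
optional lagged-series part `μ2` (Kronecker Q-major interaction
ordering).  The slope vector `β* = (β_x, β_z, β_xz, β_y, β_xy)` of
length `P` is the target of sparse estimation.

**Likelihood.** The discrete chain is marginalized by the Hamilton
forward filter.  The filtered probabilities start at `ξ_i1 = (1, 0)`
(the chain is known to start in state 1) and the likelihood accumulates
the one-step predictive densities from the second occasion onward — the
first observation is conditioned on, since the model assigns no marginal
density to `η_y,i1`.  This convention is the only one consistent with
the fixed `ξ` initialization, and it is pinned by tests against an exact
path-enumeration oracle (`brute_force_loglik`, feasible for `T ≤ 15`).
The transition into occasion `t` uses covariates at `t` and the lagged
series at `t − 1`.

## Priors

Regularizing priors act on `β*` only; everything else gets standard
weakly informative choices: half-Cauchy(0, 2.5) for all SDs,
half-normal(0, 10) for `β0` and `A_2`, standard normal for `B_2` and
`γ`, half-normal(0, 1) for free loadings, LKJ(4) for the residual
correlation (K > 1).

Four families, addressable as named presets (`prior.preset`):

| preset | hierarchy |
|---|---|
| `ridge-0` | `β_p ~ N(0, ση²/λ)`, `ση = 1, λ = 1` (standard normal) |
| `ridge-1` | as above with `ση = 2` (variance 4) |
| `b-lasso` | `β_p ~ Laplace(0, ση/λ)`, `λ ~ C⁺(0, 2.5)`, `ση` linked to `σ0` |
| `b-lasso-1` | fixed `ση = 1` |
| `abss-lasso-0/1/2` | `β_p = β̄_p ν_p`, `β̄_p ~ Laplace(0, ση/λ_p)`, `ν_p ~ Beta(½, ½)`, `λ_p ~ C⁺(0, 2.5)`; `ση` linked to `σ0` / 1 / 2 |
| `reg-hs-0` | regularized horseshoe: `λ_p ~ C⁺(0,1)`, `τ ~ C⁺(0, τ0)`, `c² ~ IΓ(½, ½)`, `τ0 = π/√(3NT)` |
| `reg-hs-1` | lighter slab tails, `c² ~ IΓ(2, 8)` |
| `reg-hs-2` | additionally `τ ~ t⁺₃(0, τ0²)` with `τ0 = 2/√(NT)` |

Notes on genuinely open choices:

* Two formulas for the horseshoe global scale circulate, `π/√(3NT)` and
  `π/√(NT)`.  We default to `π/√(3NT)`, which follows from the generic
  `τ0 = (P0/(P−P0))·ση/√(NT)` with `ση = π/√3` (the logistic residual
  SD) and the default prior guess `P0 = P/2`; the other variant is
  available through `tau0_numerator`/`tau0_sigma_eta` overrides.
* The aBSS-Lasso spike is the constant 0 (continuous inclusion weight),
  not a discrete Dirac mixture — the discrete form is incompatible with
  the continuous samplers used here and is deliberately out of scope.
* A Beta prior for the state-2 AR coefficient of univariate models is
  sometimes suggested; its hyperparameters are underdetermined, so the
  standard normal is used and the option left unimplemented.
* All positive prior variables are sampled on the log scale (inclusion
  probabilities on the logit scale) with Jacobian corrections; reported
  densities are over the constrained variables.

## Inference

The posterior is sampled with an affine-invariant ensemble MCMC
(`emcee`), which needs only posterior evaluations.  Two consequences:

* **Random intercepts are marginalized, not sampled.**  `ε0_i` enters
  the likelihood additively in `η̃`, so each individual's likelihood is
  integrated over `ε0_i ~ N(0, σ0²)` by Gauss–Hermite quadrature
  (default 15 nodes; accuracy is tested against adaptive quadrature to
  1e−6 on small panels).  This keeps the sampled dimension at
  `O(P)` instead of `O(N)` and removes the funnel geometry the random
  intercepts would otherwise create.  Sampling `ε0` explicitly
  (non-centered) remains available via `marginalize_eps0=False`.
* **Move mixture.**  Differential-evolution moves (80% DE + snooker)
  mix far better than the stretch move on this model's correlated
  scale/slope geometry; a 20% stretch component is kept because it
  recovers walkers stranded by an early large jump.  The
  `preset="brute_force"` sampler configuration doubles walkers and steps
  as a conservative fallback for poorly mixing posteriors.

Defaults: 4 independent ensembles ("chains") of `2·dim + 2` walkers,
2000 steps each with the first 1000 discarded.  Diagnostics use the
rank-normalized split-chain definitions (arviz).  R-hat treats each
independent ensemble as one chain (walkers pooled in step-major order,
so the split still contrasts early versus late steps): per-walker
chains are short relative to the ensemble autocorrelation time, which
inflates split R-hat even at stationarity.  ESS is computed on the
per-walker chains, the conservative choice.  Because an ensemble
occasionally strands a single walker far below the posterior bulk
(where difference moves can no longer rescue it), outlier walkers are
re-initialized onto bulk positions at the end of warmup, and a run
whose final state still contains such a stray is never declared
converged — pooled R-hat alone can average over one stuck walker.
Convergence is declared when all R-hat < 1.1 (and no strays), with
precision flags at ESS cutoffs {100, 400, 1000}.  Replication metrics
use converged replications only.

Initialization is a small Gaussian ball around a moment-based start:
states guessed by thresholding the series, per-individual empirical
stay fractions regressed on the between-level covariates through the
logit (this mainly shortens burn-in; the posterior does not depend on
it).  Posterior summaries report the mean, SD and 95% equal-tailed
interval by default (HPD by flag); the joint posterior mode is found by
quasi-Newton ascent from the posterior-mean start.

## Synthetic study designs

The generator reproduces two designs used to compare the priors:

* **Time-invariant transitions** (`Sim1Design`): `β0 = 3`; nonzero
  slopes alternate ±0.5 with a 50% or 75% zero rate over
  `P ∈ {5, 15, 25}` equicorrelated (unit variance, 0.3) covariates;
  `N ∈ {50, 75, 100}`, `T ∈ {10, 25, 50}` (54 cells).  Within level:
  `A_2 = 3`, `B_2 = 0.8`, `γ = 0.5`, `σ_ε = 0.25`; `η_z ~ N(0, 1)`.
* **Time-varying transitions** (`Sim2Design`): `N = 100`, `P = 15` as 7
  time-invariant slopes `(0.5, −0.5, 0.5, 0, 0, 0, 0)`, one
  time-varying slope `β_z = 0.5` and 7 cross-level interactions with
  nonzeros `(0.5, −0.5, 0.5)` in the trailing slots; `T ∈ {30, …, 70}`.

Design SNR is `β*'Φ β* / (σ0² + σ_s²)` with the full-predictor
covariance `Φ` built blockwise and the logistic residual variance
`σ_s² = π²/3`.  The random-intercept SD is fixed at `σ0 = 1`, the value
consistent with the design SNR ≈ 0.08 of the smallest cell.  At `P = 5`
the SNR is 0.0816 — a deliberately weak signal regime in which shrinkage
priors are known to bias slope estimates toward zero.

The generator emulates latent series directly (loadings 1, zero
measurement error), matching the study setting where observed items
equal the latent variables.  It does **not** emulate multivariate
measurement structure, ordinal items or missingness — passing tests
therefore speak to the estimation machinery under the stated designs,
not to robustness against real-data measurement pathologies.

## Numerical choices

* Filter arithmetic: the reference recursion works in log space with
  `logaddexp`; the sampler's hot path uses an algebraically equivalent
  scaled probability-space recursion (per-occasion max normalization,
  renormalization every 8 steps) that is ~2× cheaper and agrees with the
  reference to ~1e−14.  An observation impossible under both states
  yields −inf, which the sampler treats as a rejected region and the
  public filter reports as a located error.
* The brute-force oracle refuses `T > 15` (2^(T−1) paths).
* Text output uses 17 significant digits, making dataset round trips
  bitwise exact.
* Per-replication seeds are `base_seed + replication_index`.

## Problem sizes used in the shipped checks

The full replication study behind the prior comparison (200 replications
× 54 conditions × 4 priors) is a cluster-scale computation of several
CPU-months and is not reproduced here.  The shipped test suite instead
uses: exact filter/oracle agreement at `N = 3, T = 10` (100 randomized
draws); recovery fits of three replicate datasets at
`N = 100, T = 50, P = 5` under `ridge-0` with 4×(1000 + 1000) steps each
— three replicates because at SNR 0.08 the across-dataset SD of a
slope's posterior mean (~0.15) makes any single-draw ±0.25 recovery
check essentially a coin flip, so the property is asserted for a
majority of replicates; and reduced convergence harnesses (6
time-invariant replications at `N = 50, T = 10` with 2×(1000 + 1000)
steps; 3 time-varying replications at `N = 30, T = 20` with
2×(1500 + 1500)), chain lengths sized to the ensemble sampler's mixing
speed.  The `grid` runner scales the same code to arbitrary cell lists
and replication counts.

## Known limitations

* The sampler path supports univariate series (`K = 1`); multivariate
  types and densities exist but are not exercised by the shipped
  designs.
* Missing data, more than two states, categorical items, backward
  smoothing/Viterbi decoding and variational initialization are out of
  scope.
* Ensemble MCMC needs more iterations than gradient-based samplers for
  the same effective sample size; heavy-tailed hierarchies (B-Lasso at
  small data) can require the `brute_force` preset or longer chains.
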