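# noisyar

**n = 1 autoregressive time-series modeling that takes measurement error
seriously.**

Intensive longitudinal data — daily mood diaries, symptom logs, repeated
cognitive tasks — are routinely analyzed with a first-order autoregressive
model, whose coefficient φ is read as *inertia*: how strongly today's state
carries into tomorrow. But the plain AR(1) model conflates two very different
error sources. *Innovations* ε_t (dynamic errors) perturb the process itself
and propagate through φ; *measurement errors* ω_t touch a single observation
and vanish. When a share λ of the total variance is measurement error, the
naive AR(1) estimate converges to (1 − λ)φ — inertia is systematically
understated, and in psychological data λ can plausibly be a third to a half.

`noisyar` implements the two standard remedies and the machinery to study
them, for a single subject's equally spaced series:

- **Models.** AR(1); AR(1)+WN
  (`y_t = μ + x_t + ω_t`, `x_t = φ x_{t−1} + ε_t`,
  ε_t ~ N(0, σ²_ε), ω_t ~ N(0, σ²_ω)); and ARMA(1,1), with the exact
  parameter bridge between AR(1)+WN and its equivalent constrained ARMA(1,1)
  (σ²_ω = −θσ²*_ε/φ, σ²_ε = (1+θ²)σ²*_ε − (1+φ²)σ²_ω) and the validity check
  for the reverse direction.
- **Estimation.** Exact Kalman-filter Gaussian likelihood (stationary
  initialization, native missing-data support) maximized by bounded L-BFGS-B
  from multiple starting points, with Wald and χ² intervals and detection of
  boundary ("Heywood") variance solutions; and MCMC with uniform variance and
  coefficient priors and a low-precision normal prior on μ, with Gelman-Rubin
  diagnostics and per-draw derived noise variances for the ARMA route.
- **Study harness.** Replicated simulation experiments over three condition
  grids (noise share, autoregression strength, series length) reporting
  bias, mean absolute error, 95% interval coverage, Heywood rates and
  failure counts — plus a generator of realistic mood-diary-like fixtures.

See `docs/methods.md` for the model details and design decisions.

## Worked example

Simulate a noisy series with inertia φ = 0.5 where 43% of the variance is
measurement error (σ²_ε = σ²_ω = 0.5), then fit the naive and error-aware
models:

```python
import noisyar as na

p = na.ARWNParams(mu=2.0, phi=0.5, sigma2_eps=0.5, sigma2_omega=0.5)
ts = na.inject_missing(na.simulate_arwn(p, 500, seed=7), 9, seed=8)

ar1  = na.fit_ml("AR1",  ts, n_starts=5, seed=1)
arwn = na.fit_ml("ARWN", ts, n_starts=5, seed=1)
post = na.fit_bayes("ARWN", ts, na.PriorSpec(var_prior_upper=20.0),
                    n_chains=3, n_iter=4000, seed=2)
```

This prints (via the obvious `print` calls):

```
lambda (true): 0.43
AR1   phi: 0.306 CI (0.221, 0.391)
ARWN  phi: 0.452 CI (0.197, 0.706)
ARWN  s2_eps: 0.556  s2_omega: 0.338  heywood: {'sigma2_eps': False, 'sigma2_omega': False}
              median   mean     sd  ci_lower  ci_upper   rhat
parameter
mu             1.805  1.806  0.067     1.674     1.936  1.000
phi            0.447  0.453  0.105     0.273     0.668  1.005
sigma2_eps     0.576  0.583  0.199     0.233     0.960  1.007
sigma2_omega   0.335  0.330  0.173     0.025     0.654  1.007
```

The naive AR(1) lands at φ̂ ≈ 0.31 — right where the attenuation formula
(1 − 0.43) × 0.5 ≈ 0.29 predicts, and its tight 95% interval *excludes* the
truth. The AR(1)+WN fits (ML and Bayesian alike) recover φ ≈ 0.45 with
honest, wider intervals that cover 0.5, and estimate a measurement-error
share of about a third. Note the ML interval for σ²_ω can collapse to the
zero bound on unlucky series (a Heywood case, flagged in `heywood`); at
n = 200 this happens in roughly a fifth to a quarter of replications.

The same workflow is available from the shell:

```sh
noisyar simulate --mu 2 --phi 0.5 --sigma2-eps 0.5 --sigma2-omega 0.5 \
    -n 200 --missing 9 --seed 42 -o mood.csv
noisyar fit mood.csv --model ARWN --estimator ml --seed 1
noisyar study config.yaml -o metrics.csv   # replicated grids from YAML
noisyar report metrics.csv                 # pivot to summary tables
```

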