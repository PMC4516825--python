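# Methods

## The models

`noisyar` is about a single person's equally spaced time series — diary mood
ratings, daily symptom scores, repeated reaction times — modeled with a
first-order autoregression while acknowledging that the measurements are
noisy. Three nested views of the same data are implemented.

**AR(1).** Observations decompose into a stable mean and a state that
regresses on itself:

    y_t = μ + x_t,      x_t = φ x_{t-1} + ε_t,      ε_t ~ N(0, σ²_ε).

The innovations ε_t are *dynamic* errors: their influence is carried forward
through φ. A positive φ is read as inertia (resistance to change).

**AR(1)+WN.** Measurement error is occasion-specific and never carried
forward. Adding a white-noise term to each observation,

    y_t = μ + x_t + ω_t,      ω_t ~ N(0, σ²_ω),

separates the two error sources. The observed process has total variance
σ²_tot = σ²_ε/(1−φ²) + σ²_ω, and we write λ = σ²_ω/σ²_tot for the
measurement-error share. The model is identified only through the dynamics:
at φ = 0 the two error variances are indistinguishable, and identification
improves gradually as |φ| grows ("empirical identification").

**ARMA(1,1).** Every AR(1)+WN process is a constrained ARMA(1,1)
(x_t = φ x_{t-1} + θ ε*_{t-1} + ε*_t). Fitting the unconstrained ARMA model is
the classical indirect route to handling measurement error; the implied error
variances are recovered afterwards via

    σ²_ω = −θ σ²*_ε / φ,
    σ²_ε = (1+θ²) σ²*_ε − (1+φ²) σ²_ω,

which exist (are non-negative) only when 1/(1+φ²) > [θ/(1+θ²)]·(−1/φ) ≥ 0.
The reverse map takes θ as the invertible root of
θ/(1+θ²) = −φσ²_ω / (σ²_ε + (1+φ²)σ²_ω); both maps and the validity check
live in `noisyar.bridge`. The root is evaluated in the rationalized form
2c/(1+√(1−4c²)) and σ²*_ε in a form where σ²_ω cancels analytically, so the
maps stay exact down to subnormal noise variances.

**Attenuation.** Ignoring measurement error biases the AR(1) estimate toward
zero: the probability limit of the naive estimator is (1−λ)φ, so its bias is
−λφ. `attenuated_phi` exposes this closed form; the simulation harness
reproduces it empirically.

## State-space form and the likelihood

All three models are cast as a time-invariant linear-Gaussian state-space
model with the mean in the observation intercept. AR(1) and AR(1)+WN are
scalar-state; ARMA(1,1) uses the 2-dimensional Harvey form with transition
[[φ, 1], [0, 0]], loading [1, 0] and innovation covariance HᵀH,
H = [σ*_ε, θσ*_ε]. This representation was validated against the closed-form
ARMA autocovariances (γ₀ = σ²*(1+θ²+2φθ)/(1−φ²), γ_h = φ^{h−1}γ₁), a check
that is invariant to the representation chosen.

The log-likelihood is the exact prediction-error decomposition from a Kalman
filter initialized at the stationary state distribution (discrete Lyapunov
solve). Because every admissible parameter point is stationary, this equals
the joint Gaussian log-density of the observed values — the property the test
suite exploits by comparing against a brute-force multivariate-normal oracle
built from the autocovariance function (tolerance 1e-8, series up to n = 20,
with and without missing occasions). Missing occasions skip the measurement
update, which is exact marginalization. A readable matrix implementation
(`noisyar.statespace`) is the reference; two numba-compiled kernels
(`noisyar._kernels`) are the hot path for estimation and are tested against
it and against statsmodels' SARIMAX filter.

## Maximum likelihood

L-BFGS-B over the box |φ|, |θ| ≤ 1−1e-6, variances ≥ 0, μ free. Variances are
optimized on their natural scale deliberately: a solution at the zero bound
(a Heywood case) is a substantively meaningful outcome — it is what a
practitioner would see and misread as "no measurement error" — so it must be
representable, not transformed away. A variance estimate below 1e-6 times the
sample variance counts as a boundary solution.

Starting values: the first start is method-of-moments. For AR(1)+WN the ratio
γ̂₂/γ̂₁ estimates φ untouched by measurement error (the white noise only
inflates γ̂₀), after which the autocovariances at lags 0–1 split the two
variances; the ARMA start maps this through the bridge. Remaining starts
(default 5 total) are seeded random restarts spreading φ over (−0.9, 0.9) and
the variance split over (0.1, 0.9) of γ̂₀. Failures of all starts raise a
distinct error and are excluded-but-counted by the study harness; Heywood
fits are retained-and-counted, mirroring how such runs are conventionally
reported.

Intervals: Wald from the inverse numerical Hessian (central differences,
nudged just inside the box at a bound) for μ, φ, θ, with φ/θ intervals
truncated to [−1, 1]; χ²_{n−1} intervals ((n−1)s²/q_{1−α/2}, (n−1)s²/q_{α/2})
for variances, with n the number of observed occasions. Fits with non-finite
Wald standard errors are treated as failures (the analogue of a negative
standard error from a ragged Hessian).

## Bayesian estimation

Priors: uniform(0, U) on each variance, uniform(−1, 1) on φ and θ,
Normal(0, precision 0.001) on μ. U is deliberately a **required** argument
(`PriorSpec.var_prior_upper`): it must sit well above the plausible variance
scale of the data, e.g. 20 on a unit-variance simulation scale but 500 on a
1–100 diary scale, so no single default is correct.

The sampler is a collapsed Metropolis-within-Gibbs on the marginal
(states-integrated) likelihood. Since the marginal likelihood is an exact
quadratic in μ, three filter evaluations identify μ's Gaussian full
conditional, which is sampled directly; φ, θ and the variances take
random-walk Metropolis steps truncated to their supports, with proposal
scales adapted toward 0.44 acceptance during burn-in under a diminishing
schedule and frozen afterwards (so the retained draws use a fixed, valid
kernel). Latent states and missing observations are integrated out exactly by
the filter — distributionally equivalent to sampling/imputing them, with much
better mixing. Correctness is checked against ML on a long series (posterior
medians within 2 ML standard errors) and against the bridge roundtrip.

Defaults are 3 chains × 4,000 iterations with the first half discarded — a
desk-scale profile; 3 × 40,000 is available through the same arguments for
full-scale runs. Point estimates are posterior medians (robust to the heavy
right tails of variance posteriors); intervals are central 2.5/97.5
percentiles. Convergence is judged per parameter by the classical
Gelman-Rubin factor R̂ = √[((n−1)/n·W + (1+1/m)·B/n)/W] with the rule
R̂ ≤ 1.1, plus chain autocorrelations stored on the result.

For the ARMA model the bridge is applied to *every retained draw*, giving
posterior distributions of σ²_ω and σ²_ε. Draws outside the valid region
yield negative variances and are retained (the credible intervals may include
negative values — exactly the pathology the comparison is meant to surface);
draws where φ is numerically zero are excluded from summaries and counted.

## The simulation study

Data are always generated from AR(1)+WN with the latent state started in its
stationary distribution (no burn-in; exact stationarity from t = 1). Three
grids, all with μ = 2:

1. **Noise share.** φ = 0.5, σ²_ε = 0.5, n = 100; σ²_ω over
   {0, 0.1, 0.2, 0.3, 0.5, 0.7, 1, 2, 4, 12}, i.e. λ from 0 to 0.95.
2. **Autoregression.** λ fixed at 0.3, σ²_ω = 0.5, n = 100; φ over
   ±{0.75, 0.5, 0.25} and 0, with σ²_ε = (1−φ²)·0.5·(0.7/0.3) solved from the
   fixed share. (σ²_ω is not pinned down by the published design; 0.5 is the
   value the other two grids share, and the solved σ²_ε magnitudes match the
   published set. The derivation makes σ²_ε *decrease* as |φ| grows, which is
   the only pairing consistent with a constant λ.)
3. **Sample size.** φ = σ²_ε = σ²_ω = 0.5 (λ = 0.43), n ∈ {100, 200, 500}.

Per replication the harness simulates, fits each requested model × estimator,
and records estimates, 95% intervals and boundary flags; per condition it
aggregates bias, mean absolute error, interval coverage, Heywood rate and
failure count. Seeding uses one root `SeedSequence` spawned per condition
(keyed by a CRC of the condition name) and per replication, so any condition
is reproducible in isolation and independent of execution order.

Problem sizes: the full design (1,000 replications per condition) is the
config default; the bundled tests and the acceptance script use a desk-scale
profile — 300–500 ML replications per condition and Bayes checks on single
long series — chosen so the whole suite runs in a few minutes on one core.
Monte-Carlo error at 300–500 replications (binomial SE ≤ 2.7 points on a
coverage rate) is the price of that profile and is reflected in the test
tolerances.

## The mood-diary fixture generator

`make_mood_fixtures` emulates a small diary cohort: per person a series
length uniform on [90, 107], about nine missing days (Poisson, interior
occasions only, missing-uniformly-at-random), and generating parameters drawn
uniformly from ranges typical of AR(1)+WN fits to daily mood on a 1–100
scale (μ ∈ [55, 76], φ ∈ [−0.03, 0.69], σ²_ε ∈ [16, 101], σ²_ω ∈ [10, 112]),
which put most persons' λ in roughly 0.3–0.55. Scores are rounded to integers
and clipped to [1, 100]. The rounding/clipping deliberately violates the
Gaussian model a little — it emulates the discreteness and boundedness of
real diary data — so these fixtures exercise robustness and plumbing; the
estimator-correctness tests use exactly-Gaussian simulations instead. What
passing fixture tests shows is that the workflow recovers plausible error
shares on realistic-looking data, not that real diaries satisfy the model.

## Numerical choices and edge cases

- Filter initialization is stationary, never diffuse; non-stationary
  parameter points return −∞ likelihood and are rejected/penalized.
- Ties between equally good optimization starts are broken first-found.
- A constant (zero-variance) series raises a distinct degenerate-process
  error in both estimators.
- φ = 0 makes the AR+WN↔ARMA maps undefined (identification error); the
  harness's ARMA truth at a φ = 0 generating condition uses the white-noise
  limit (θ = 0, σ²* = σ²_ε + σ²_ω).
- Wald intervals for φ abutting ±1 are truncated to [−1, 1].
- The `t,y` CSV layer writes 17 significant digits and reads with
  round-trip float parsing, so I/O is bit-exact for observed values.

## Known limitations

- Equally spaced occasions only; no continuous-time or multivariate models,
  and no multilevel pooling across persons.
- No model-selection machinery (information criteria, Bayes factors).
- Wald/χ² intervals inherit their known finite-sample defects — that is part
  of what the study quantifies, not a bug, but it means the ML intervals
  should not be used uncritically at n ≈ 100.
- The adaptive random-walk sampler is adequate for these 3–4 parameter
  models; it is not a general-purpose MCMC engine.
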