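# Methods

## The model

Response times are modelled per condition cell as ex-Gaussian: X = G + E
with G ~ N(µ, σ²) and E ~ Exponential(mean τ), all in milliseconds. The
density and CDF are

```
f(x) = (1/τ) exp((µ−x)/τ + σ²/(2τ²)) Φ(z),      z = (x−µ)/σ − σ/τ
F(x) = Φ((x−µ)/σ) − exp((µ−x)/τ + σ²/(2τ²)) Φ(z)
```

and the moment identities are mean = µ+τ, variance = σ²+τ²,
skewness = 2τ³/(σ²+τ²)^{3/2}. RTs pooled across participants within a cell
are treated as i.i.d.; participant-level variation is deliberately not
modelled (no random effects), matching the pooled-fit design this package
reproduces.

The log-density is always evaluated in the log domain,
log f = −log τ + (µ−x)/τ + σ²/(2τ²) + log Φ(z) with `scipy.special.log_ndtr`.
For σ/τ up to at least 10³ the two exponents (±σ²/2τ² and log Φ(z) ≈ −z²/2)
cancel analytically before exponentiation, so neither pdf, CDF, nor
likelihood overflows; the naive product form overflows already at σ/τ ≈ 40.

## Preprocessing

Trials with RT strictly below 250 ms or strictly above 1500 ms are
excluded (the bounds themselves are kept), then incorrect responses are
dropped; for distractor stimuli a "correct" response is a correct
rejection. The two filters commute, so their order is immaterial. An
exclusion fraction of ≥5% raises a `TrimWarning` but never aborts — the 5%
figure is an aim, not a validity bound. Hit rates are computed per cell on
all trials *before* RT trimming, so a fast-guess trial counts toward
accuracy even if its RT is excluded from the fit.

The descriptors use population (1/n) moments: M = mean,
S = √(Σ(x−M)²/n), t = (Σ(x−M)³/n)/S³. The 1/n convention (rather than
n−1) keeps the moment inversion used for starting values exactly
self-consistent.

## Maximum-likelihood fitting

Starting values invert the moment identities: τ₀ = S·(t/2)^{1/3},
µ₀ = M − τ₀, σ₀ = √(S² − τ₀²). Two fallbacks absorb samples outside the
invertible region: t ≤ 0 gives a Gaussian-dominant start (τ₀ = 0.1·S), and
σ₀ is floored at 0.05·S when S² − τ₀² would be at or below that floor
(which happens whenever t ≥ 2, the skewness ceiling of the pure
exponential).

The search is maximum ascent on the log-likelihood with an analytic
gradient,

```
∂ℓ/∂µ = n/τ − Σ h(z_i)/σ
∂ℓ/∂σ = nσ/τ² − Σ h(z_i)·((x_i−µ)/σ² + 1/τ)
∂ℓ/∂τ = −n/τ + Σ(x_i−µ)/τ² − nσ²/τ³ + σ/τ² Σ h(z_i)
```

where h(z) = φ(z)/Φ(z) is evaluated as exp(log φ − log Φ). Each iteration
ascends along the gradient preconditioned by the local inverse negative
Hessian (central differences of the analytic gradient; fixed
dispersion-based per-parameter scales whenever the Hessian is not negative
definite, e.g. far from the optimum), with a backtracking line search that
halves the step until the likelihood improves. The strong negative
sampling correlation between µ̂ and τ̂ makes the likelihood surface a narrow
curved ridge; without curvature preconditioning a diagonal-scaled ascent
stalls orders of magnitude short of the stopping rule.

Convergence is declared when the Euclidean norm of the gradient — in the
original (µ, σ, τ) space, no reparameterisation — drops below ε = 10⁻⁸
(`max_iter` 10⁵; non-convergence is reported in the result, never hidden).
Near the maximum the likelihood gain of a step can fall below the
floating-point resolution of the summed log-likelihood while the analytic
gradient is still computable to ~10⁻¹⁴; there the line search accepts
likelihood-neutral steps that strictly shrink the gradient norm. Steps
that would push σ or τ to ≤10⁻⁶·S are rejected by the line search. Samples
whose MLE sits on the σ→0 boundary (possible for small n) therefore
honestly report `converged=False`, and pipeline cells degrade to a
`not_converged` status. Samples with n < 10 or zero variance are refused.

The likelihood is the plain (untruncated) ex-Gaussian likelihood: the
250–1500 ms trimming is treated as data cleaning, not as censoring, so no
truncation correction is applied.

## Goodness of fit

D = sup_x |ECDF(x) − F̂(x)|, computed at the sorted sample as
max(i/n − F̂(x_i), F̂(x_i) − (i−1)/n). Because F̂ was estimated from the same
data, the KS null tables do not apply; the p-value is the fraction of 1000
parametric-bootstrap samples (same n, drawn from F̂) whose D exceeds the
observed one, ties counted toward the larger p. With `refit=True` each
bootstrap sample is refitted before computing its D (the Lilliefors-style,
statistically conservative variant); the default `refit=False` compares
all bootstrap samples against the one fitted parameter triple. Reports
print p to two decimals, so a computed 0.004 prints as 0.00.

## Iso-likelihood-surface uncertainties

The surface {θ : ℓ(θ) = ℓ_max − Δ} with Δ = 0.5 bounds the single-parameter
~68% likelihood-ratio region (2Δ = 1, one degree of freedom). It is sampled
by ≥1000 rays from the MLE: directions uniform on the sphere after per-axis
scaling by the curvature standard errors √diag((−H)⁻¹) so the elongated
µ–τ ridge is sampled evenly, then bisection along each ray to
|ℓ − (ℓ_max − Δ)| ≤ 10⁻⁷. Rays that leave the σ, τ > 0 domain before
crossing are redrawn; a ray still above the target after 10³ scaled units
raises a surface-failure error (flat likelihood).

The 1σ uncertainty of each parameter is **half the coordinate range** of
the surface points along that axis — the Monte-Carlo estimate of the
profile-likelihood bound, which equals the Wald standard error when the
log-likelihood is quadratic. The dispersion is deliberately *not* the
standard deviation of the coordinates: for a quadratic likelihood each
curvature-scaled coordinate of a uniformly-directed surface point is
uniform on [−1, 1], so the coordinate SD is the Wald SD divided by √3 and
±1 coordinate-SD intervals would cover ~44% instead of the nominal ~68%.
With the half-range reading, simulated coverage at n=500 is ~66–68% (1σ)
and ~92–95% (1.96σ). 95% intervals are MLE ± 1.96 × the 1σ value.

## Synthetic cohorts

The generator emulates the masked-priming study the analysis was built
for: 50 participants per country, 16 cells per participant (own country ×
2 target natures × 2 roles × 4 primes), 14 trials per cell = 224 trials,
matching 28 test + 28 distractor stimuli with repeated measures per task.
The 14-per-cell split of the 224 is a design choice (the source design
states only the totals); practice trials are assumed excluded from the
224. Per-cell generating parameters and hit rates default to the reference
fitted components, so closed-loop recovery against the defaults is
meaningful. Correctness is Bernoulli at the cell hit rate, independent of
RT. A contaminant fraction (default 2%) replaces the RT by a uniform draw
on [80, 250) ∪ (1500, 2500] ms; this contaminant model is synthetic-only —
it exists to exercise the trimming stage, not to model real anticipations
or lapses. Each participant draws from a dedicated `SeedSequence([seed,
pid])` substream, so cohorts are bit-reproducible and stable under partial
regeneration.

What passing tests on these cohorts do **not** show about real data:
participant heterogeneity (pooling mixes genuinely different individual
distributions, which can inflate τ̂), RT–accuracy dependence, sequential
effects, and any prime–timing effects are all absent by construction.

## Problem sizes and numerical choices

Validation studies use 50 replicates of n=1000 for parameter recovery
(Monte-Carlo SE of the mean estimate ≈ 1–2 ms, comfortably inside the ±5/±6
ms recovery bands) and 200 replicates of n=500 with 1024 surface points for
interval coverage (binomial SE ≈ 1.5–3 percentage points). Default
tolerances: gradient stop ε = 10⁻⁸; surface root 10⁻⁷ in log-likelihood;
bootstrap 1000 samples. Ties in the bootstrap count and tie-breaks in the
line search are documented where they occur in the code.

## Known limitations

- Pooled fitting only; no hierarchical/random-effects variant.
- No alternative RT distributions (shifted Wald, lognormal) and no
  Bayesian posterior.
- The bootstrap p with `refit=False` is anti-conservative when the
  parameters were estimated from the data being tested; the `refit=True`
  flag exists for when calibration matters more than fidelity to the
  reference procedure.
- Boundary-MLE samples (σ̂ → 0) are reported as non-converged rather than
  fitted under a reparameterised boundary model.
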