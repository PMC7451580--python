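# Methods

## The model

The type-I heavy-tailed (TI-HT) family augments a baseline lifetime law
with cdf `F(x; ξ)` on `(0, ∞)` by a tail parameter `θ > 0`:

```
G(x; θ, ξ) = 1 − [ (1 − F) / (1 − (1 − θ) F) ]^θ ,
g(x; θ, ξ) = θ² f (1 − F)^(θ−1) / [1 − (1 − θ) F]^(θ+1) .
```

The construction arises from composing an exponential "transformer"
density with the monotone map `K[F] = −log[((1−F)/(1−(1−θ)F))^θ]`; the
package takes the resulting closed-form cdf as definitional and does not
implement the generic transformer integral. At `θ = 1` every quantity
collapses to the baseline (we dispatch explicitly when `|θ−1| < 1e−12`,
which makes the reduction exact to machine precision and removes the
removable singularity of the quantile formula's denominator).

With the **rate-form Weibull** baseline `F = 1 − exp(−γ x^α)` (note:
`γ` multiplies `x^α`; not the `(x/scale)^α` scale form — all reported
estimates use the rate form, with labelled converters to the scale form)
the TI-HT-Weibull survival function satisfies

```
sf(x) / exp(−θ γ x^α)  →  θ^(−θ)          (x → ∞),
```

so `θ` rescales the Weibull tail *rate*: `θ < 1` produces a strictly
heavier tail (every quantile above `u ≈ 0.7` exceeds the Weibull one),
`θ > 1` a lighter one. For `α < 1` the law is heavy-tailed in the strict
sense that `sf(x)·e^{px} → ∞` for every `p > 0`. For `α = 1` the tail is
exponential with rate `θγ` and that divergence holds only for `p > θγ` —
a boundary case worth keeping in mind when `θ` is interpreted as a
"heavy-tail" knob.

### Parameters

| parameter | meaning | domain | typical defaults in the studies |
|-----------|---------|--------|---------------------------------|
| `α` | Weibull shape (tail power) | `> 0` | 0.8 / 1.4 |
| `γ` | Weibull rate (units `x^−α`) | `> 0` | 1.0 |
| `θ` | tail re-weighting | `> 0` | 0.5 / 0.9 (heavy) |

## Numerical conventions

- **Survival, never `1 − cdf`.** All tail quantities evaluate
  `[(1−F)/(1−(1−θ)F)]^θ` through the baseline log-survival function
  (`exp(θ(log S − log(θ + (1−θ)S)))`), preserving precision to VaR levels
  of 0.999 and beyond.
- **Quantiles.** `Q(u) = F⁻¹(((1−u)^{1/θ}−1)/((1−θ)(1−u)^{1/θ}−1))`,
  computed with `expm1`/`log1p`; for levels where the inner cdf argument
  would round to 1, the baseline inverse-survival function is used with
  the stable survival form `θs/(1−(1−θ)s)`, `s = (1−u)^{1/θ}`. The
  round-trip `G(Q(u)) = u` holds to 1e−9 across `(0, 1−1e−12]`.
- **Random variates** come from quantile inversion of uniforms drawn from
  an explicitly seeded `numpy` generator; no global RNG state is touched.
- **Moments.** The canonical r-th moment is adaptive quadrature of
  `Q(u)^r` over `(0,1)` (the exact substitution `u = G(x)`), tolerance
  1e−10. The series cross-check expands the transform denominator as
  `Σ_i binom(i+θ, θ)(1−θ)^i F^i` (valid for `θ ∈ (0,2)`) and evaluates
  `λ_{r,i} = ∫ Q_W(u)^r u^i (1−u)^{θ−1} du` with the algebraic endpoint
  weight handled by QUADPACK. The `(1−u)^{θ−1}` kernel is the exact sum
  of the generalized binomial j-series `Σ_j binom(θ−1, j)(−u)^j` (a
  finite sum when `θ` is a positive integer); resumming it under the
  integral is essential because the truncated alternating j-tail decays
  only like `j^−θ` — hopeless at `θ = 0.5` for 1e−4 accuracy. Truncation
  rule: stop when the last ten i-terms contribute < 1e−12 relative,
  cap 500 terms.
- **TVaR.** Canonical method: `∫_q^1 Q(u) du / (1−q)` by adaptive
  quadrature (no infinite-domain truncation). The series cross-check uses
  the same i-expansion plus a binomial k-expansion of `F^i`, producing
  upper-incomplete-gamma terms
  `(θ+k)^{−1−1/α} Γ(1+1/α, γ(θ+k)VaR^α)`; the `1/(1−q)` normalization and
  the `((θ+k)γ)^{−1/α}` substitution factors are carried explicitly.
- **mgf.** Quadrature of `exp(tQ(u))`; for `α < 1` with `t > 0` (or
  `α = 1` with `t ≥ θγ`) the integral diverges and NaN is returned with a
  warning rather than a number.

## Maximum likelihood

The log-likelihood

```
ℓ = 2n log θ + Σ log f + (θ−1) Σ log(1−F) − (θ+1) Σ log(1−(1−θ)F)
```

is maximized over log-parameters (unconstrained) by a Nelder–Mead start
followed by an L-BFGS-B polish with the analytic score; the score's
`(∂F/∂ξ)/(1−F)` ratios are simplified analytically so nothing degrades
when the Weibull survival underflows. The likelihood surface has a long
curved ridge trading `γ` against `θ` (heavier tail ↔ smaller rate), so
cold-started fits run a short deterministic multi-start over
`θ₀ ∈ {0.3, 0.6, 1, 2.5}`, pairing each with `γ₀ = γ_W/θ₀` to stay near
the data's tail rate (`γ_W` from a profile-equation Weibull MLE).
Standard errors come from the inverse observed information (central
finite differences of the score, step `1e−5(1+|θ̂|)`); Wald intervals are
deliberately **not truncated at zero** for positive parameters, matching
the reporting convention of the simulation studies this mirrors.

## The simulation harnesses

`run_mle_simulation` draws `reps` inversion samples per sample size,
refits each, and reports per parameter the replicate mean, bias, MSE,
mean Wald interval, coverage, and Monte-Carlo standard errors of the mean
and of the MSE. Three conventions deserve explicit statement:

1. **Truth initialization.** Replicate fits start at the generating
   parameters (the standard recovery-study convention). A cold global
   search instead measures "which ridge mode the optimizer finds", whose
   replicate mean is badly biased away from the truth (mean `θ̂ ≈ 0.72`
   at n = 900 under truth `θ = 0.5`) and is not the quantity such studies
   report.
2. **Failed fits are excluded and counted, never replaced by the truth**
   (substitution would silently bias the MSE downward). Failure means
   non-convergence or non-finite estimates/standard errors. An optional
   stricter rule (`identification_z`) also fails replicates whose Wald
   interval for `θ` crosses zero; it is off by default because at small n
   such intervals are routine noise, not failures.
3. **Substream seeding.** Replicate r at sample-size index j uses
   `SeedSequence(seed, spawn_key=(j, r))`, so results are independent of
   iteration order and stable under parallelization.

A known property of this family is that a small fraction (≲1%) of
replicates at moderate n have their local optimum far along the ridge
(`θ̂ > 1.5` under truth 0.5). These runaways dominate the replicate MSE
of `θ̂` and `γ̂` and make those MSEs noisy across meta-seeds; the
replicate means of `α̂` are much more stable. The reported aggregates
include the runaways. The same skewed ridge geometry makes the
untruncated Wald intervals undercover `γ` slightly (≈0.84 at n = 900
versus the 0.95 nominal level) — a finite-sample property of the
estimator, not a numerical defect.

Default study sizes (chosen to match the designs the package reproduces):
1000 replicates; sample sizes 600 and 900 for the headline tables; the
risk study uses n = 100 with 1000 repetitions in its full form (tests run
scaled-down repetitions of the identical code path).

## Goodness of fit

AIC/BIC plus the standard Cramér–von Mises, Anderson–Darling and
Kolmogorov–Smirnov statistics on the probability-integral transform. The
KS p-value uses the asymptotic Kolmogorov distribution **without**
correction for estimated parameters; with fitted models it is liberal
(biased upward), which matches the convention of the comparison tables
this module mirrors — treat it as descriptive, not inferential.
Comparison tables tolerate and propagate non-finite statistics rather
than failing. Ranking is by AIC, ties broken by BIC then family name.

## Bayesian analysis

Independent Gamma(0.01, 0.01) priors per (positive) parameter by default
— diffuse, letting the data dominate; overridable. The sampler is
adaptive random-walk Metropolis on log-parameters: proposal covariance
from the inverse observed *posterior* information at the MLE (likelihood
curvature plus the analytic gamma-prior curvature `(a−1)/θ²`), scaled by
`2.38²/d`, with a global Robbins–Monro scale adaptation toward 35%
acceptance that runs during burn-in only, so the retained draws come from
a fixed valid kernel. Chains start at the MLE with overdispersed
log-scale jitter. Convergence is summarized by the Gelman–Rubin factor
`R = sqrt((W(n−1)/n + B/n)/W)`; `R < 1.2` is the working bar.

DIC is `D̄ + p_D` with `p_D = D̄ − D(θ̄)`. The plug-in `θ̄` is the
posterior mean **on the sampler's log scale** (the geometric mean of the
draws): the DIC plug-in is parameterization-dependent, and on this
model's curved `(γ, θ)` posterior ridge the arithmetic mean of the draws
falls off the ridge, yielding meaningless negative `p_D`; the
working-scale mean gives `p_D` near the free-parameter count, as theory
prescribes for diffuse priors and informative data. A difference of more
than 10 DIC units is read as strong preference, 5–10 as considerable.

## Synthetic data

The fixture generator draws by quantile inversion from any registered
family and optionally inflates the extreme tail: with contamination
fraction `c`, each observation is independently replaced, with
probability `c`, by a draw from above the 99th percentile. This emulates
the right-skewed, occasional-extreme-loss shape of real biomedical and
insurance data. What it does **not** emulate: censoring, covariate
structure, measurement rounding, serial dependence, or model
misspecification — so passing recovery tests demonstrate correctness of
the estimators under the model, not robustness on real data. (Real
datasets enter only as optional user-supplied CSVs; none ship with the
package.)

## Known limitations

- Complete samples only; no censoring or covariate regression.
- The `(α, γ, θ)` likelihood ridge makes `γ` and `θ` only weakly
  identified at n ≲ 300; report them with their (wide) intervals.
- The series moment/TVaR cross-checks require `θ ∈ (0, 2)`; outside it
  only the quadrature route exists. The TVaR series' alternating
  k-expansion loses precision as `θ → 2` with light tails.
- The KS p-value bias described above.
- Descriptive-measure magnitudes published elsewhere for this family are
  not all mutually consistent with the family's own cdf; this package's
  quadrature values are self-consistent (and verified against sampling),
  which is the authoritative convention here.
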