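# tiht — type-I heavy-tailed lifetime distributions

Positive-valued data from survival analysis, reliability engineering and
insurance-loss modelling routinely show right tails heavier than the
classical Weibull, gamma or exponential families can accommodate: remission
times with a handful of very long survivors, machine failure records with
occasional extreme lifetimes, loss portfolios where the largest claims
dominate risk. `tiht` implements a one-knob remedy: a transform that turns
any baseline lifetime law `F(x; ξ)` into a *type-I heavy-tailed* (TI-HT)
family with an extra tail parameter `θ > 0`,

```
G(x; θ, ξ) = 1 − [ (1 − F) / (1 − (1 − θ) F) ]^θ .
```

`θ = 1` recovers the baseline exactly; `θ < 1` thickens the right tail,
`θ > 1` thins it. With the rate-form Weibull baseline
`F(x) = 1 − exp(−γ x^α)` this yields the three-parameter TI-HT-Weibull
(TI-HTW) law, whose survival function behaves like
`θ^(−θ) exp(−θ γ x^α)` deep in the tail and whose quantile function is
available in closed form — so random variates come from plain inversion
and value-at-risk is a one-line formula.

The package is aimed at biostatisticians and actuaries who want to *fit,
simulate and stress-test* such models, and provides:

- `family_core` — the generic transform: cdf/pdf/sf/hazard/quantile/rng
  for any `BaselineDistribution`, with numerically stable deep-tail forms;
- `distributions` — closed-form TI-HTW evaluators, its named reductions
  (Weibull, exponential, Rayleigh, TI-HT-exponential, TI-HT-Rayleigh) and
  the competitor families used in model comparison (exponentiated
  Weibull, Lomax, Burr XII) behind a common registry;
- `moments` — quadrature moments and descriptive measures, with the
  family's series expansion as an independent cross-check;
- `estimation` — maximum likelihood with analytic score,
  observed-information standard errors and (untruncated) Wald intervals;
- `risk` — closed-form VaR and quadrature/series TVaR;
- `mc_study` — replicated bias/MSE/coverage studies and VaR/TVaR
  comparison experiments, deterministically substream-seeded;
- `gof` — AIC/BIC, Cramér–von Mises, Anderson–Darling,
  Kolmogorov–Smirnov with p-value, and ranked model comparison;
- `bayes` — gamma-prior MCMC (adaptive random-walk Metropolis),
  Gelman–Rubin diagnostics, DIC with effective parameter count;
- a `tiht` command-line tool (`fit`, `simulate`, `risk`, `gof`, `bayes`,
  `fixture`) over single-column CSV samples and YAML/JSON configs.

## Worked example

Generate a synthetic heavy-tailed sample, fit it, and compare models:

```python
import numpy as np
from tiht import TIHTWParams, tihtw_quantile, fit_mle, compare_models, var_q, tvar_q

truth = TIHTWParams(alpha=0.8, gamma=1.0, theta=0.5)      # heavy tail
x = np.asarray(tihtw_quantile(np.random.default_rng(1).random(5000), truth))

fit = fit_mle(x, "tihtw")
for name, est, se in zip(fit.param_names, fit.estimates, fit.std_errors):
    print(f"{name}: {est:.4f} (se {se:.4f})")
```

prints

```
alpha: 0.8242 (se 0.0316)
gamma: 0.8289 (se 0.2031)
theta: 0.5713 (se 0.0930)
```

— each estimate within one standard error of the generating values
(0.8, 1.0, 0.5); the large `gamma`/`theta` standard errors reflect the
strong ridge correlation between the scale and tail parameters that is
intrinsic to this family. Tail risk at the fitted parameters:

```python
p = TIHTWParams(*fit.estimates)
print(f"VaR 0.95: {var_q(p, 0.95):.3f}   TVaR 0.95: {tvar_q(p, 0.95):.3f}")
```

```
VaR 0.95: 10.599   TVaR 0.95: 14.692
```

i.e. the worst 5% of outcomes start at 10.6 and average 14.7 — the gap
between the two numbers is the hallmark of a heavy tail (for the nested
Weibull fit the same levels are markedly lower). The same workflow from
the shell:

```bash
tiht fixture --family tihtw --params 0.8,1.0,0.5 --n 5000 --seed 1 --out s.csv
tiht fit --data s.csv --family tihtw --out fit.json
tiht gof --data s.csv --families tihtw,weibull,lomax,burr12 --out gof.csv
```

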