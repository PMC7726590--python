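# locmix

Mixture-model decomposition of **spatial working-memory errors**.

When participants reproduce a remembered on-screen location, their errors
mix three distinct processes: *imprecision* (noisy memory of the right
item), *misbinding* (reporting the location of a different item from the
display — a swap error), and *guessing*. Raw accuracy or mean placement
error confounds them. `locmix` separates them by fitting two-dimensional
mixture models to trial-level continuous-report data, the 2D extension of
the mixture models routinely used for one-dimensional circular features
like color and orientation.

The response density for a trial with target **θ**, nontargets
**φ**₁..**φ**ₘ and screen area *A* is

> *P*(**θ̂**) = α ψ_σ(**θ̂** − **θ**) + β (1/m) Σᵢ ψ_σ(**θ̂** − **φ**ᵢ) + γ / A

where ψ_σ is an isotropic bivariate Gaussian with per-axis SD σ and
α + β + γ = 1 (α is derived, leaving three free parameters β, γ, σ). The
1D analogue swaps ψ_σ for a von Mises distribution with concentration κ
and γ/A for γ/2π.

For whom: researchers running spatial delayed-reproduction (or spatial
change-detection) experiments who want per-participant estimates of
imprecision, swap rate and guess rate rather than summary distances.

What's in the box:

- **Models** (statsmodels-style: model object → `fit()` → results):
  `SpatialMixtureModel` (misbinding / standard / two-nontarget-class
  variants, optional screen-truncation correction),
  `CircularMixtureModel` (1D von Mises analogue), and
  `ChangeDetectionModel` (2AFC likelihood obtained by integrating the
  continuous density over the probe's displacement disc).
- **Fitting**: fast multi-start MLE with simplex-safe transforms and
  analytic gradients; Hessian-based covariances and a Wald test for
  comparing conditions; ensemble MCMC (`fit_mcmc`) with split-R̂
  convergence control.
- **Response biases**: constant translation, proportional-to-edge and
  radial (toward the screen center, a fixed point, or each trial's
  nontarget) — usable generatively and as fitted corrections.
- **Response sampling**: a participant's own pooled responses, kernel-
  smoothed (Scott's rule), as an empirical guess distribution, with 90/10
  cross-validation to compare it against uniform guessing.
- **Behavioral metrics**: target distance, nearest-neighbor distance,
  chance-corrected swap errors (fixed or adaptive threshold), split-half
  reliability.
- **Simulation & recovery harness**: the 3-item task generator (with the
  88/29 px spacing-constraint variant), the 11×11×11 parameter sweep, and
  end-to-end parameter-recovery experiments with pooled true-vs-recovered
  correlations.
- A thin CLI: `locmix simulate | fit | recover | metrics | cd-fit | compare`.

## Worked example

```python
import numpy as np
import locmix as lm

rng = np.random.default_rng(7)
design = lm.TaskDesign()          # 3 items, 100 trials, 1366x768 px screen
data = lm.simulate_dataset(design, beta=0.3, gamma=0.2, sigma=30.0, rng=rng)

res = lm.SpatialMixtureModel(data).fit()
print(res.summary())
```

```
SpatialMixtureModel results
========================================
n trials:        100
free parameters: 3
log-likelihood:  -1151.9417
BIC:             2317.6988
converged:       True (25 starts, 5 polished)
----------------------------------------
param           estimate
alpha (derived)   0.5527
beta              0.2748
gamma             0.1725
sigma            31.0440
```

The fit recovers the generating parameters (β = .3, γ = .2, σ = 30 px)
within sampling error of a 100-trial experiment: β̂ = .27 ± .05,
γ̂ = .17 ± .04, σ̂ = 31.0 ± 1.8 (standard errors from `res.bse`, i.e. the
inverted Hessian). BIC (2317.7 here) compares model variants; smaller is
better. Posterior sampling exposes the parameter trade-offs:

```python
post = lm.SpatialMixtureModel(data).fit_mcmc(draws=10_000, seed=0)
print(post.corr("gamma", "beta"))   # -0.308
```

The negative γ–β correlation says the data cannot fully separate guesses
from swaps trial-by-trial — far-off responses are ambiguous — which is
exactly why model-based estimates beat threshold metrics. For comparison,
the model-free summaries on the same dataset:

```python
print(lm.target_distance(data).mean())   # 270.18 px
print(lm.swap_errors(data))              # 0.1901 (chance-corrected)
```

Reading real data instead of simulating: `lm.read_trials("trials.csv",
lm.ScreenGeometry(1366, 768))` with columns
`condition, resp_x, resp_y, targ_x, targ_y, nt1_x, nt1_y, nt1_class, ...`
(blank nontarget cells for absent items).

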