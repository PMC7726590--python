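# Methods

## The model

Continuous-report spatial working-memory tasks ask a participant to place a
remembered item back at its on-screen location. `locmix` decomposes the
resulting 2D errors with a three-component mixture. Writing `r` for the
response location, `t` for the target, `nt_1..nt_m` for the trial's
nontargets and `A` for the screen area, the response density is

    p(r) = alpha * psi_sigma(r - t)
         + (beta / m) * sum_i psi_sigma(r - nt_i)
         + gamma / A

with `psi_sigma` an isotropic bivariate Gaussian (zero covariance, SD
`sigma` per axis). `alpha` (target responding), `beta` (misbinding, i.e.
reporting a nontarget's location) and `gamma` (guessing, uniform over the
screen) sum to 1, so the free parameters are `(beta, gamma, sigma)`;
`alpha` is always derived. Dropping the `beta` term gives the standard
two-component model; splitting it by nontarget class (`beta1`, `beta2`)
gives the two-class variant for designs with distinct kinds of nonprobed
items. The circular 1D analogue replaces the Gaussian with a von Mises
distribution (concentration `kappa`) and the screen with the circle; the
helper `kappa_to_sd` maps `kappa` to a circular SD,
`sqrt(-2 ln(I1(kappa)/I0(kappa)))`, for comparison across the two model
families (`kappa = 0` maps to the finite uniform-circle SD `pi/sqrt(3)` so
comparisons stay plottable).

Assumptions worth stating explicitly: target and nontarget responses share
one `sigma`; guesses are uniform (unless the response-sampling density is
plugged in); trials are independent; the screen is a closed rectangle in
whatever length units the caller adopts (pixels by default — the screen
dimensions argument implicitly sets the units, and `deg_to_px`/`cm_to_px`
convert explicitly, defaulting to a 40 cm viewing distance and 42 px/cm).

### Screen truncation

The generative process resamples any component draw that lands off-screen,
which strictly implies a renormalised (truncated) density. The fitting
density is deliberately *untruncated* by default — plain Gaussians plus
`gamma/A` — matching common practice for these models; a `truncated=True`
mode renormalises every Gaussian component by its on-screen mass (computed
exactly as a product of axis-wise normal CDFs, possible because the
covariance is zero). The untruncated default is what all reference
statistics in the test suite were computed with; the truncated mode
quantifies the approximation (its density integrates to 1 over the screen
even for items near an edge).

## Fitting

`SpatialMixtureModel.fit()` is multi-start maximum likelihood. The
proportions are optimised through a softmax (additive log-ratio) transform
with the target proportion as the reference category, which enforces
`beta, gamma >= 0` and `beta + gamma <= 1` by construction; `sigma` is
optimised on the log scale within `[0.01, max(width, height)]`. Start
points are a 3x3x3 coarse grid (proportions in {.1, .3, .6} subject to the
simplex, spread in {3, 20, 80} px) plus one method-of-moments start
(robust `sigma` from the median target distance, crude guess/swap fractions
from distance thresholds); all starts are ranked by their objective value
and the best `n_polish` (default 5) are polished with L-BFGS-B. On the
plain misbinding/standard path the gradient is analytic (softmax Jacobian
plus the Gaussian scale derivative); models with bias terms, KDE guesses,
truncation or two classes fall back to finite differences. Convergence
tolerances default to 1e-9 (objective) and 1e-6 (gradient), configurable.
A fit on a 100-trial, 3-item dataset takes ~10 ms, which is what makes the
full recovery sweeps feasible on one CPU.

The 1D model fits `kappa` on the log scale. Its default range corresponds
to a circular SD between ~0.04 and 100 degrees — the conventional fitting
range for orientation tasks, and deliberately the range used by the
established 1D toolboxes so that 1D/2D comparisons are like-for-like.

Uncertainty comes from the observed information: `cov_params()` builds the
Hessian of the negative log-likelihood by central finite differences in the
natural parameter space and inverts it; a singular Hessian raises an error
that names the `ridge` fallback (a small diagonal inflation) rather than
silently regularising. `condition_compare` uses these covariances in a
Wald test, `(dp)' (Cov_A + Cov_B)^{-1} (dp) ~ chi2(k)`, to ask whether two
fitted conditions share parameters.

## MCMC

`fit_mcmc()` samples the posterior with the affine-invariant ensemble
sampler (emcee), flat priors over the bounds above, walkers initialised
overdispersed around the MLE. Convergence is monitored with split-chain
R-hat (threshold 1.1) computed over the trailing half of the accumulated
chain; sampling extends until the diagnostic passes, everything before the
retained window counting as burn-in. The retained window is sized to give
at least the requested number of draws (10,000 by default) and subsampled
to exactly that. Walkers in one ensemble are interacting, so this R-hat is
an approximation to the independent-chain diagnostic; it is used as a
stopping rule, not a publication-grade ESS claim.

## Response biases

Three parametric bias families can be simulated and fitted: a constant
translation (subtracted from responses; 2 parameters), a proportional shift
toward/away from a named screen edge (`x' = x + b (W - x)` for the right
edge; 1 parameter), and a radial contraction/expansion about a point
(`p' = p + b (c - p)`; 1 parameter), where the radial center may be fixed
(e.g. the screen center) or a per-trial coordinate such as the trial's
nontarget — the latter expresses a nontarget "pull" that is distinguishable
from misbinding because pulled responses sit *between* target and
nontarget. Conventions, fixed and tested: generative simulation applies
the bias to sampled responses and then clips to the screen edge; fitting
applies the same transform to the component means before density
evaluation, so the recovered bias estimates the simulated one with the same
sign. Component sampling resamples off-screen draws; bias application
clips. The two rules are never mixed silently. The nontarget-pull variant
is exposed for single-nontarget designs only, since the reference
demonstration used one nontarget and pull with several is not well defined.

## Response-sampling guess distribution

`ResponseKDE` smooths all of a participant's response locations with a
product-Gaussian kernel, per-axis bandwidths from Scott's rule for d = 2
(`h_j = sd_j * n^{-1/6}`, overridable), and renormalises over the screen
rectangle (each kernel's on-screen mass is again an exact product of normal
CDFs) so that `gamma` stays a probability. Plugged into a model it
replaces `gamma / A` by `gamma * kde(r)` without changing the
free-parameter count. `crossval_response_sampling` implements the 90/10
held-out comparison: per repetition, fit both guess models on the training
split (the KDE built from training responses only) and record the mean
per-trial likelihood of the held-out trials — the arithmetic mean of
per-trial likelihoods by default, with mean log-likelihood as an option.

## Change detection (2AFC)

For probe displacement `d > 0`, the probability of correctly rejecting the
probe is the integral of the continuous mixture density over the on-screen
part of the disc of radius `d` around the target — the probability the
model would have produced a response closer to the target than the probe
is. This encodes the assumption that accepting some displacement implies
accepting all smaller ones; no extra lapse parameter exists. The integral
uses polar quadrature (Gauss-Legendre in radius, uniform in angle,
24 x 48 nodes by default) with off-screen nodes dropped; for the uniform
component on an interior disc the rule is exact, so it reproduces
`pi d^2 / A` to rounding error, and the Gaussian components are checked in
tests against the noncentral-chi-square closed form. Near an edge the
clipped quadrature simply omits off-screen mass, consistent with the
untruncated density; tiny (<1%) non-monotonicities in `d` appear once the
disc extends far beyond the screen and are documented quadrature jitter.
The default 2AFC model is the standard mixture — binary responses carry
little information per trial and misbinding 2AFC fits are markedly slower
(available, flagged slow).

## Behavioral metrics

`target_distance` (all error sources), `nearest_neighbor_distance` (min
over target and nontargets; equals target distance on single-item trials
and never exceeds it), their difference (a misbinding proxy), and swap
errors: the proportion of responses within a threshold of a nontarget,
default 1.5 visual degrees (~44 px), or the participant's mean target
distance as an adaptive threshold. The chance correction subtracts, per
trial, the fraction of candidate locations at the response's own target
distance that would have counted as swaps; candidates are 360 evenly
spaced points on the circle of that radius centred on the target, with
off-screen points dropped before the fraction is taken (the discretisation
and the clipping are this package's choices; 360 points put the
discretisation error well below the Monte-Carlo oracle tolerance of 1e-2
used in tests). Trials without nontargets make swap errors undefined — the
functions return NaN with a warning rather than a silent zero.
`split_half_reliability` randomly halves each participant's trials, applies
a measure to each half, Spearman-correlates halves across participants and
averages over (default 100) iterations.

## Simulation and the recovery harness

The generator *is* the package's study conditions: a 3-item task (1 target,
2 nontargets), 100 trials, 1366x768 px screen, uniform stimulus placement;
the constrained variant enforces >= 88 px between items and from the screen
center and >= 29 px from the edges (3 and 1 visual degrees), via rejection
sampling capped at 10^4 attempts (an infeasible constraint set fails fast,
naming the constraints). Response types are drawn per trial with
probabilities `(alpha, beta, gamma)`; Gaussian components are resampled
until on-screen; misbinding picks uniformly among the trial's nontargets.
The parameter sweep takes 11 evenly spaced values per parameter —
`gamma, beta in [0.01, 0.98]`, `sigma in [0.1, 100]` (pixels in 2D,
circular-SD degrees in 1D) — keeping the 726 cells with
`gamma + beta <= 1`. A two-class fixture (one nonprobed same-class item
plus two distractors, `ignore_update_design`) exercises the two-class
model; it is synthetic and mirrors only the structure, not any dataset.

`run_recovery` simulates and refits every cell x iteration (failures are
recorded, not fatal; runs are checkpointable and seed-reproducible) and
reports signed and absolute recovery errors; `recovery_correlations` pools
all records and Spearman-correlates true against recovered values per
parameter (pooling, rather than averaging per-cell correlations, is the
implemented reading). 1D estimates are converted from `kappa` to
circular-SD degrees before any differencing so errors are on matching
scales. `compare_designs` sweeps one design factor (trials, nontargets,
placement constraints, generative bias) and summarises absolute errors per
level with a linear trend test. `metric_sweep` runs the same sweep without
fitting and records per-run metric means for the metric-validity
correlations.

Replication counts are scaled to a desk machine: the shipped experiments
use 10 iterations per sweep cell (7,260 runs per sweep; the pooled
correlations are then estimated from thousands of points and their
remaining variability is small), 10,000 posterior draws, and 8-25
repetitions for the paired directional contrasts. At these sizes the full
recovery sweep takes ~2 min and the whole reproduction script ~4 min on
one CPU.

## What the synthetic data do and do not show

The generator emulates exactly the mixture process the models assume, plus
the optional bias transforms and non-uniform guess samplers used to probe
robustness. Passing recovery tests therefore demonstrates that the
estimation machinery is correct and well-conditioned under the stated task
geometry — not that human data follow the model. Real responses include
heuristics, serial dependencies, landmark and edge-anchoring effects, and
reaction-time-linked lapses that none of the components capture; the
response-sampling KDE absorbs stable spatial response habits but nothing
trial-dependent. Conclusions about people require fitting people.

## Known limitations

- Isotropic, shared `sigma` only: no covariance term, no separate
  target/nontarget precision, no variable-precision or slot-style families.
- Hierarchical (multi-subject) MCMC is out of scope; fits are per dataset.
- The untruncated default density slightly misstates the likelihood of
  items very close to a screen edge (use `truncated=True` to quantify).
- The 2AFC integrator's accuracy near edges is limited by the clipped
  quadrature resolution; raise `n_radial`/`n_angular` for probe discs that
  overlap edges substantially.
- Single-dataset posterior summaries (e.g. the gamma-beta trade-off
  correlation) vary meaningfully from dataset to dataset at n = 100; the
  shipped values are seeded, representative draws from that distribution.
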