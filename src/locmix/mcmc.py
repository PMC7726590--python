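"""Posterior sampling for the mixture models.

Sampling uses the affine-invariant ensemble sampler (emcee) with flat
priors over the parameter bounds: proportions on the simplex
(``beta, gamma >= 0``, ``beta + gamma <= 1``), the spread parameter within
its box bounds, bias parameters within theirs.  Convergence is monitored
with the split-chain R-hat diagnostic (threshold 1.1 by default, treating
walkers as chains); sampling extends automatically until the diagnostic
passes or a round cap is hit.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

import emcee

__all__ = ["PosteriorResults", "sample_posterior"]


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter; chains shaped (n_chains, n_steps, k)."""
    c, t, k = chains.shape
    half = t // 2
    x = np.concatenate([chains[:, :half, :], chains[:, half : 2 * half, :]], axis=0)
    mean_c = x.mean(axis=1)            # (2c, k)
    var_c = x.var(axis=1, ddof=1)      # (2c, k)
    w = var_c.mean(axis=0)
    b = half * mean_c.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * w + b / half
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(var_hat / w)


class PosteriorResults:
    """Post-convergence posterior draws from one model fit."""

    def __init__(self, model, samples: pd.DataFrame, rhat: pd.Series, n_burn: int):
        if len(samples) < 2:
            raise ValueError("need more than one posterior draw")
        self.model = model
        self.samples = samples
        self.rhat = rhat
        self.n_burn = n_burn

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    def mean(self) -> pd.Series:
        return self.samples.mean()

    def sd(self) -> pd.Series:
        return self.samples.std(ddof=1)

    def corr(self, a: str, b: str) -> float:
        """Pearson correlation between two parameters' draws."""
        return float(np.corrcoef(self.samples[a], self.samples[b])[0, 1])

    def pairwise_correlations(self) -> pd.DataFrame:
        """Pairwise Pearson correlations among all sampled parameters."""
        return self.samples.corr(method="pearson")

    def summary(self) -> str:
        lines = [
            f"Posterior samples: {self.n_draws} draws "
            f"(burn-in {self.n_burn} steps), max R-hat {self.rhat.max():.3f}",
            str(pd.DataFrame({"mean": self.mean(), "sd": self.sd()})),
        ]
        return "\n".join(lines)


def _log_prior(theta: np.ndarray, model) -> float:
    nprop = model.n_prop
    props = theta[:nprop]
    if (props < 0).any() or props.sum() > 1.0:
        return -np.inf
    scale = theta[nprop]
    if not (model._scale_lo <= scale <= model._scale_hi):
        return -np.inf
    for val, (lo, hi) in zip(theta[nprop + 1 :], model._bias_bounds()):
        if not (lo <= val <= hi):
            return -np.inf
    return 0.0


def sample_posterior(
    model,
    draws: int = 10_000,
    walkers: int = 32,
    burn: int = 500,
    seed: int = 0,
    rhat_threshold: float = 1.1,
    max_rounds: int = 20,
    init: np.ndarray | None = None,
) -> PosteriorResults:
    """Draw posterior samples for a fitted-or-fittable mixture model.

    Walkers are initialised overdispersed around the MLE (or ``init``);
    after ``burn`` steps the split R-hat is checked on a trial window and
    burn-in extends until every parameter passes ``rhat_threshold`` (error
    after ``max_rounds`` extensions).  The retained window is sized to give
    at least ``draws`` post-convergence samples, subsampled to exactly
    ``draws``.
    """
    rng = np.random.default_rng(seed)
    k = model.k_params
    walkers = max(walkers, 2 * k + 2)
    if init is None:
        init = model.fit(n_polish=3).params.to_numpy(dtype=float)

    def log_prob(theta):
        lp = _log_prior(theta, model)
        if not np.isfinite(lp):
            return -np.inf
        return lp + model.loglike(theta)

    # overdispersed initial cloud, clipped into the prior support
    nprop = model.n_prop
    p0 = np.empty((walkers, k))
    for w in range(walkers):
        for _ in range(1000):
            cand = init.copy()
            cand[:nprop] = np.clip(init[:nprop] + rng.normal(0, 0.15, nprop), 1e-4, 0.98)
            if cand[:nprop].sum() > 0.99:
                cand[:nprop] *= 0.99 / cand[:nprop].sum()
            cand[nprop] = float(
                np.clip(init[nprop] * math.exp(rng.normal(0, 0.5)), model._scale_lo * 1.01, model._scale_hi * 0.99)
            )
            for j, (lo, hi) in enumerate(model._bias_bounds(), start=nprop + 1):
                cand[j] = float(np.clip(init[j] + rng.normal(0, 0.1 * (hi - lo)), lo, hi))
            if np.isfinite(log_prob(cand)):
                p0[w] = cand
                break
        else:
            raise RuntimeError("could not initialise walkers inside the prior support")

    sampler = emcee.EnsembleSampler(walkers, k, log_prob, args=())
    sampler.random_state = np.random.RandomState(seed).get_state()
    state = sampler.run_mcmc(p0, burn, progress=False)

    # extend in windows; the diagnostic runs on the trailing half of the
    # accumulated chain, so early steps turn into burn-in until R-hat passes
    window = max(int(np.ceil(draws / walkers)), 50)
    rhat = None
    for round_ in range(max_rounds):
        state = sampler.run_mcmc(state, window, progress=False)
        total = sampler.get_chain().shape[0]
        keep = max(window, total // 2)
        chain = sampler.get_chain()[-keep:]        # (keep, walkers, k)
        rhat = _split_rhat(np.moveaxis(chain, 0, 1))
        if np.nanmax(rhat) < rhat_threshold:
            break
    else:
        raise RuntimeError(
            f"MCMC did not converge: split R-hat {np.nanmax(rhat):.3f} "
            f">= {rhat_threshold} after {max_rounds} extensions"
        )

    flat = chain.reshape(-1, k)
    if flat.shape[0] > draws:
        idx = rng.choice(flat.shape[0], size=draws, replace=False)
        flat = flat[idx]
    samples = pd.DataFrame(flat, columns=model.param_names)
    return PosteriorResults(
        model,
        samples,
        pd.Series(rhat, index=model.param_names),
        n_burn=burn + round_ * window,
    )
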