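"""Mixture models and maximum-likelihood fitting.

The public surface follows the statsmodels idiom: a model object is built
from a dataset, ``fit()`` runs multi-start maximum likelihood and returns a
results object carrying point estimates, log-likelihood, BIC, a
Hessian-based covariance and a ``summary()`` table; ``fit_mcmc()`` returns
posterior samples (see :mod:`locmix.mcmc`).

Free parameters and constraints
-------------------------------
The proportions (all misbinding rates plus the guess rate) live on the
probability simplex with the target rate ``alpha`` as the derived remainder;
internally they are optimised through a softmax (additive log-ratio)
transform so that ``beta + gamma <= 1`` holds by construction.  The spread
parameter (sigma in 2D, kappa in 1D) is optimised on the log scale.  Bias
parameters, when present, are optimised directly within box bounds.

Multi-start: a coarse grid of start points plus one method-of-moments start
is screened by objective value and the best few are polished with L-BFGS-B
(analytic gradient on the plain-model path, finite differences otherwise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import i0e, i1e

from . import components
from .bias import BiasSpec, apply_bias
from .components import bic as _bic
from .data import CircularDataset, TrialDataset
from .geometry import ScreenGeometry
from .guess import ResponseKDE

__all__ = [
    "MixtureParams",
    "SpatialMixtureModel",
    "CircularMixtureModel",
    "MixtureResults",
    "condition_compare",
    "crossval_response_sampling",
]

_LOGIT_BOUND = 8.0
TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class MixtureParams:
    """Interpreted mixture parameters; ``alpha`` is always the remainder."""

    beta: float
    gamma: float
    sigma: float | None = None  # 2D spread (length units)
    kappa: float | None = None  # 1D concentration
    beta2: float | None = None  # second-class misbinding, if any
    bias: tuple[float, ...] = ()

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta - self.gamma - (self.beta2 or 0.0)


def _softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Map K logits to K proportions with the derived remainder alpha."""
    z = np.concatenate([[0.0], logits])
    z = z - z.max()
    e = np.exp(z)
    p = e / e.sum()
    return p[1:]  # alpha = p[0] is implied


def _inv_softmax(probs: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(probs, dtype=float), 1e-8, 1 - 1e-8)
    alpha = max(1.0 - p.sum(), 1e-8)
    return np.log(p / alpha)


class _BaseMixtureModel:
    """Shared fitting machinery; subclasses provide the likelihood."""

    param_names: list[str]
    n_prop: int  # number of simplex-constrained proportions

    # ---- transform between natural and optimizer space -------------------
    def _to_transformed(self, theta: np.ndarray) -> np.ndarray:
        x = np.empty_like(np.asarray(theta, dtype=float))
        x[: self.n_prop] = _inv_softmax(theta[: self.n_prop])
        x[self.n_prop] = math.log(theta[self.n_prop])
        x[self.n_prop + 1 :] = theta[self.n_prop + 1 :]
        return x

    def _to_natural(self, x: np.ndarray) -> np.ndarray:
        theta = np.empty_like(np.asarray(x, dtype=float))
        theta[: self.n_prop] = _softmax_probs(x[: self.n_prop])
        theta[self.n_prop] = math.exp(x[self.n_prop])
        theta[self.n_prop + 1 :] = x[self.n_prop + 1 :]
        return theta

    def _transformed_bounds(self) -> list[tuple[float, float]]:
        b = [(-_LOGIT_BOUND, _LOGIT_BOUND)] * self.n_prop
        b.append((math.log(self._scale_lo), math.log(self._scale_hi)))
        b.extend(self._bias_bounds())
        return b

    def _bias_bounds(self) -> list[tuple[float, float]]:
        return []

    # ---- likelihood ------------------------------------------------------
    def loglike(self, theta) -> float:
        """Log-likelihood at a natural-space parameter vector."""
        raise NotImplementedError

    def _nll_transformed(self, x: np.ndarray) -> float:
        return -self.loglike(self._to_natural(x))

    def _nll_grad_transformed(self, x: np.ndarray):
        return None  # numeric fallback

    # ---- starts ----------------------------------------------------------
    def _start_grid(self) -> list[np.ndarray]:
        raise NotImplementedError

    def _moments_start(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    def fit(
        self,
        n_polish: int = 5,
        maxiter: int = 200,
        ftol: float = 1e-9,
        gtol: float = 1e-6,
        extra_starts=None,
    ) -> "MixtureResults":
        """Multi-start maximum-likelihood estimation.

        All start points (coarse grid + method of moments + any
        ``extra_starts``, natural space) are screened by objective value and
        the best ``n_polish`` are optimised with L-BFGS-B.
        """
        if self.nobs < self.k_params + 1:
            raise ValueError("need at least k+1 trials to fit k parameters")
        starts = self._start_grid()
        starts.append(self._moments_start())
        if extra_starts is not None:
            starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
        xs = [self._to_transformed(np.asarray(s, dtype=float)) for s in starts]
        vals = np.array([self._nll_transformed(x) for x in xs])
        order = np.argsort(vals)
        order = order[np.isfinite(vals[order])]
        if order.size == 0:
            raise RuntimeError("all start points gave non-finite likelihood")
        bounds = self._transformed_bounds()
        grad = self._nll_grad_transformed(xs[int(order[0])])
        use_grad = grad is not None

        best = None
        diagnostics = []
        for idx in order[: max(1, n_polish)]:
            x0 = np.clip(xs[int(idx)], [b[0] for b in bounds], [b[1] for b in bounds])
            if use_grad:
                res = optimize.minimize(
                    lambda x: self._nll_grad_transformed(x),
                    x0,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
                )
            else:
                res = optimize.minimize(
                    self._nll_transformed,
                    x0,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
                )
            diagnostics.append((res.success, res.fun, res.message))
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(f"all optimizer starts failed: {diagnostics}")
        theta = self._to_natural(best.x)
        return MixtureResults(
            model=self,
            params=pd.Series(theta, index=self.param_names),
            llf=-float(best.fun),
            converged=bool(best.success),
            n_starts=len(starts),
            n_polished=int(min(max(1, n_polish), order.size)),
            optimizer_message=str(best.message),
        )


class SpatialMixtureModel(_BaseMixtureModel):
    """2D mixture model of spatial recall errors.

    Parameters
    ----------
    data : TrialDataset
    misbinding : bool
        Include the nontarget (swap) component; otherwise the standard
        two-component (target + guess) model.
    two_class : bool
        Separate misbinding rates beta1/beta2 for nontarget classes 1 and 2
        (requires class labels in the data).
    bias : BiasSpec | str
        Response-bias correction fitted alongside the mixture; the bias
        transform is applied to the component means (target and nontarget
        centers) before density evaluation, adding its parameters to the
        free-parameter list.
    guess : "uniform" | ResponseKDE
        Guess component: uniform over the screen, or a response-sampling
        kernel density (free-parameter count unchanged).
    truncated : bool
        Renormalise Gaussian components by their on-screen mass.
    """

    def __init__(
        self,
        data: TrialDataset,
        misbinding: bool = True,
        two_class: bool = False,
        bias: BiasSpec | str = "none",
        guess: object = "uniform",
        truncated: bool = False,
        screen: ScreenGeometry | None = None,
    ):
        self.data = data
        self.screen = screen or data.screen
        self.misbinding = bool(misbinding)
        self.two_class = bool(two_class)
        if two_class and not misbinding:
            raise ValueError("two_class requires the misbinding model")
        self.bias = BiasSpec(kind=bias) if isinstance(bias, str) else bias
        if isinstance(guess, str):
            if guess != "uniform":
                raise ValueError("guess must be 'uniform' or a ResponseKDE")
            self.kde = None
        else:
            self.kde = guess
        self.truncated = bool(truncated)
        self.nobs = data.n_trials

        names = []
        if two_class:
            names += ["beta1", "beta2"]
        elif misbinding:
            names += ["beta"]
        names += ["gamma", "sigma"]
        self.n_prop = len(names) - 1
        names += self.bias.param_names
        self.param_names = names
        self._scale_lo = 1e-2
        self._scale_hi = max(self.screen.width, self.screen.height)

        # cached geometry for the fast path
        d = self.data
        self._mask = d.nontarget_mask
        self._m = self._mask.sum(axis=1)
        self._d0sq = np.sum((d.responses - d.targets) ** 2, axis=1)
        if d.nontargets.shape[1]:
            dsq = np.sum((d.responses[:, None, :] - d.nontargets) ** 2, axis=2)
            self._dntsq = np.where(self._mask, dsq, np.inf)
        else:
            self._dntsq = np.empty((self.nobs, 0))
        if self.misbinding and not self.two_class and (self._m == 0).any():
            warnings.warn("some trials have no nontargets; their misbinding term is dropped")
        if self.kde is not None:
            self._kde_at_resp = self.kde.pdf(d.responses)
        self._fast = (
            self.bias.kind == "none"
            and self.kde is None
            and not self.truncated
            and not self.two_class
        )

    # ---- likelihood ------------------------------------------------------
    def _unpack(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        i = 0
        if self.two_class:
            b1, b2 = theta[0], theta[1]
            i = 2
        elif self.misbinding:
            b1, b2 = theta[0], None
            i = 1
        else:
            b1, b2 = 0.0, None
        gamma = theta[i]
        sigma = theta[i + 1]
        bias_vals = theta[i + 2 :]
        return b1, b2, gamma, sigma, bias_vals

    def _density(self, theta: np.ndarray) -> np.ndarray:
        b1, b2, gamma, sigma, bias_vals = self._unpack(theta)
        d = self.data
        targets, nontargets = d.targets, d.nontargets
        if self.bias.kind != "none":
            tc = nontargets[:, 0, :] if self.bias.center == "nontarget" else None
            targets = apply_bias(targets, self.bias, bias_vals, self.screen, trial_centers=tc)
            if nontargets.shape[1]:
                mask3 = self._mask[..., None]
                nt_filled = np.where(mask3, nontargets, 0.5)
                if self.bias.center == "nontarget":
                    tcn = np.repeat(tc[:, None, :], nontargets.shape[1], axis=1)
                    shifted = apply_bias(
                        nt_filled.reshape(-1, 2),
                        self.bias,
                        bias_vals,
                        self.screen,
                        trial_centers=tcn.reshape(-1, 2),
                    ).reshape(nontargets.shape)
                else:
                    shifted = apply_bias(
                        nt_filled.reshape(-1, 2), self.bias, bias_vals, self.screen
                    ).reshape(nontargets.shape)
                nontargets = np.where(mask3, shifted, np.nan)
        if self.two_class:
            dens = components.mixture_density_2d_two_class(
                d.responses, targets, nontargets, d.nt_class,
                b1, b2, gamma, sigma, self.screen, truncated=self.truncated,
            )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dens = components.mixture_density_2d(
                    d.responses, targets, nontargets,
                    b1 if self.misbinding else 0.0, gamma, sigma,
                    self.screen, truncated=self.truncated,
                )
        if self.kde is not None:
            # swap the uniform guess term for the response-sampling density
            dens = dens + gamma * (self._kde_at_resp - 1.0 / self.screen.area)
        return dens

    def loglike(self, theta) -> float:
        if isinstance(theta, MixtureParams):
            vec = [theta.beta] + ([theta.beta2] if self.two_class else [])
            theta = np.array(vec + [theta.gamma, theta.sigma, *theta.bias])
        dens = self._density(np.asarray(theta, dtype=float))
        if (dens <= 0).any() or not np.isfinite(dens).all():
            return -np.inf
        return float(np.log(dens).sum())

    # fast path: plain misbinding/standard model, uniform guess ------------
    def _nll_grad_transformed(self, x: np.ndarray):
        if not self._fast:
            return None
        nprop = self.n_prop
        probs = _softmax_probs(x[:nprop])
        sigma = math.exp(x[nprop])
        if self.misbinding:
            beta, gamma = probs
        else:
            beta, gamma = 0.0, probs[0]
        alpha = 1.0 - beta - gamma
        s2 = sigma * sigma
        invA = 1.0 / self.screen.area

        g0 = np.exp(-self._d0sq / (2 * s2)) / (TWO_PI * s2)
        if self._dntsq.shape[1]:
            gnt_all = np.exp(-self._dntsq / (2 * s2)) / (TWO_PI * s2)
            msafe = np.maximum(self._m, 1)
            gnt = gnt_all.sum(axis=1) / msafe
        else:
            gnt_all = None
            gnt = np.zeros(self.nobs)
        p = alpha * g0 + beta * gnt + gamma * invA
        if (p <= 0).any():
            return np.inf, np.zeros_like(x)
        nll = -np.log(p).sum()
        inv_p = 1.0 / p

        # partials in (beta, gamma, sigma)
        dp_dbeta = gnt - g0
        dp_dgamma = invA - g0
        t0 = g0 * (self._d0sq / s2 - 2.0) / sigma
        if gnt_all is not None:
            with np.errstate(invalid="ignore"):
                tnt = (gnt_all * (np.where(np.isfinite(self._dntsq), self._dntsq, 0.0) / s2 - 2.0)).sum(axis=1) / np.maximum(self._m, 1) / sigma
        else:
            tnt = 0.0
        dp_dsigma = alpha * t0 + beta * tnt

        g_beta = -(inv_p * dp_dbeta).sum()
        g_gamma = -(inv_p * dp_dgamma).sum()
        g_sigma = -(inv_p * dp_dsigma).sum() * sigma  # chain rule to log-sigma
        grad = np.empty_like(x)
        if self.misbinding:
            # softmax Jacobian for probs (beta, gamma) with alpha reference
            grad[0] = g_beta * beta * (1 - beta) + g_gamma * (-beta * gamma)
            grad[1] = g_beta * (-beta * gamma) + g_gamma * gamma * (1 - gamma)
        else:
            grad[0] = g_gamma * gamma * (1 - gamma)
        grad[nprop] = g_sigma
        return nll, grad

    # ---- starts ----------------------------------------------------------
    def _bias_bounds(self) -> list[tuple[float, float]]:
        span = 0.5 * max(self.screen.width, self.screen.height)
        return {
            "none": [],
            "constant": [(-span, span), (-span, span)],
            "edge_proportional": [(-0.95, 0.95)],
            "radial": [(-0.95, 0.95)],
        }[self.bias.kind]

    def _start_grid(self) -> list[np.ndarray]:
        sigmas = (3.0, 20.0, 80.0)
        props = (0.1, 0.3, 0.6)
        bias0 = [0.0] * self.bias.n_params
        starts = []
        if self.two_class:
            for b in props:
                for g in props:
                    if b + g < 0.95:
                        for s in sigmas:
                            starts.append(np.array([b / 2, b / 2, g, s, *bias0]))
        elif self.misbinding:
            for b in props:
                for g in props:
                    if b + g < 0.95:
                        for s in sigmas:
                            starts.append(np.array([b, g, s, *bias0]))
        else:
            for g in props:
                for s in sigmas:
                    starts.append(np.array([g, s, *bias0]))
        return starts

    def _moments_start(self) -> np.ndarray:
        d0 = np.sqrt(self._d0sq)
        sigma0 = np.clip(np.median(d0) / 1.1774, self._scale_lo * 2, self._scale_hi * 0.5)
        dnt_min = (
            np.sqrt(np.min(self._dntsq, axis=1))
            if self._dntsq.shape[1]
            else np.full(self.nobs, np.inf)
        )
        far = (d0 > 3 * sigma0) & (dnt_min > 3 * sigma0)
        gamma0 = float(np.clip(far.mean(), 0.02, 0.9))
        swapish = float(np.clip((dnt_min < d0).mean() - 0.2, 0.02, 0.8))
        bias0 = [0.0] * self.bias.n_params
        if self.two_class:
            theta = [swapish / 2, swapish / 2, gamma0, sigma0, *bias0]
        elif self.misbinding:
            theta = [swapish, gamma0, sigma0, *bias0]
        else:
            theta = [gamma0, sigma0, *bias0]
        theta = np.asarray(theta)
        k = self.n_prop
        if theta[:k].sum() > 0.95:
            theta[:k] *= 0.95 / theta[:k].sum()
        return theta

    def fit_mcmc(self, draws: int = 10_000, seed: int = 0, **kw):
        from .mcmc import sample_posterior

        return sample_posterior(self, draws=draws, seed=seed, **kw)


class CircularMixtureModel(_BaseMixtureModel):
    """1D (circular) misbinding mixture with a von Mises response kernel.

    Fits ``kappa`` (concentration); use :func:`locmix.components.kappa_to_sd`
    to express imprecision as a circular SD for comparison with 2D fits.
    """

    def __init__(self, data: CircularDataset, misbinding: bool = True, kappa_bounds: tuple[float, float] | None = None):
        self.data = data
        self.misbinding = bool(misbinding)
        self.nobs = data.n_trials
        self.param_names = (["beta"] if misbinding else []) + ["gamma", "kappa"]
        self.n_prop = len(self.param_names) - 1
        if kappa_bounds is None:
            # conventional fitting range for orientation tasks: circular SD
            # between ~0.04 and 100 degrees
            kappa_bounds = (components.sd_to_kappa(np.deg2rad(100.0)), 1e7)
        self._scale_lo, self._scale_hi = kappa_bounds
        self._mask = np.isfinite(data.nontargets)
        self._m = self._mask.sum(axis=1)
        self._cos0 = np.cos(data.responses - data.targets)
        if data.nontargets.shape[1]:
            delta = data.responses[:, None] - np.where(self._mask, data.nontargets, 0.0)
            self._cosnt = np.where(self._mask, np.cos(delta), np.nan)
        else:
            self._cosnt = np.empty((self.nobs, 0))

    def loglike(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        if self.misbinding:
            beta, gamma, kappa = theta
        else:
            beta, (gamma, kappa) = 0.0, theta
        p = self._density(beta, gamma, kappa)
        if (p <= 0).any() or not np.isfinite(p).all():
            return -np.inf
        return float(np.log(p).sum())

    def _density(self, beta, gamma, kappa) -> np.ndarray:
        alpha = 1.0 - beta - gamma
        c = 1.0 / (TWO_PI * i0e(kappa))
        p = alpha * np.exp(kappa * (self._cos0 - 1.0)) * c + gamma / TWO_PI
        if beta > 0 and self._cosnt.shape[1]:
            g = np.where(self._mask, np.exp(kappa * (np.where(self._mask, self._cosnt, 1.0) - 1.0)) * c, 0.0)
            p = p + beta * np.where(self._m > 0, g.sum(axis=1) / np.maximum(self._m, 1), 0.0)
        return p

    def _nll_grad_transformed(self, x: np.ndarray):
        nprop = self.n_prop
        probs = _softmax_probs(x[:nprop])
        kappa = math.exp(x[nprop])
        if self.misbinding:
            beta, gamma = probs
        else:
            beta, gamma = 0.0, probs[0]
        alpha = 1.0 - beta - gamma
        c = 1.0 / (TWO_PI * i0e(kappa))
        ratio = i1e(kappa) / i0e(kappa)

        v0 = np.exp(kappa * (self._cos0 - 1.0)) * c
        if self._cosnt.shape[1] and self.misbinding:
            cosnt = np.where(self._mask, self._cosnt, 1.0)
            vnt_all = np.where(self._mask, np.exp(kappa * (cosnt - 1.0)) * c, 0.0)
            msafe = np.maximum(self._m, 1)
            vnt = vnt_all.sum(axis=1) / msafe
            dvnt = (vnt_all * (cosnt - ratio)).sum(axis=1) / msafe
        else:
            vnt, dvnt = 0.0, 0.0
        p = alpha * v0 + beta * vnt + gamma / TWO_PI
        if (p <= 0).any():
            return np.inf, np.zeros_like(x)
        nll = -np.log(p).sum()
        inv_p = 1.0 / p

        dp_dbeta = vnt - v0
        dp_dgamma = 1.0 / TWO_PI - v0
        dp_dkappa = alpha * v0 * (self._cos0 - ratio) + beta * dvnt
        g_beta = -(inv_p * dp_dbeta).sum() if self.misbinding else 0.0
        g_gamma = -(inv_p * dp_dgamma).sum()
        g_kappa = -(inv_p * dp_dkappa).sum() * kappa
        grad = np.empty_like(x)
        if self.misbinding:
            grad[0] = g_beta * beta * (1 - beta) + g_gamma * (-beta * gamma)
            grad[1] = g_beta * (-beta * gamma) + g_gamma * gamma * (1 - gamma)
        else:
            grad[0] = g_gamma * gamma * (1 - gamma)
        grad[nprop] = g_kappa
        return nll, grad

    def _start_grid(self) -> list[np.ndarray]:
        kappas = [components.sd_to_kappa(np.deg2rad(s)) for s in (3.0, 20.0, 80.0)]
        props = (0.1, 0.3, 0.6)
        starts = []
        if self.misbinding:
            for b in props:
                for g in props:
                    if b + g < 0.95:
                        starts.extend(np.array([b, g, k]) for k in kappas)
        else:
            for g in props:
                starts.extend(np.array([g, k]) for k in kappas)
        return starts

    def _moments_start(self) -> np.ndarray:
        err = np.abs(components.wrap_angle(self.data.responses - self.data.targets))
        sd0 = float(np.clip(np.median(err) / 0.6745, 0.02, components.UNIFORM_CIRCULAR_SD * 0.98))
        kappa0 = components.sd_to_kappa(sd0)
        gamma0 = float(np.clip((err > 3 * sd0).mean(), 0.02, 0.9))
        if self.misbinding:
            return np.array([0.1, gamma0 if gamma0 + 0.1 <= 0.95 else 0.85, kappa0])
        return np.array([gamma0, kappa0])

    def fit_mcmc(self, draws: int = 10_000, seed: int = 0, **kw):
        from .mcmc import sample_posterior

        return sample_posterior(self, draws=draws, seed=seed, **kw)


class MixtureResults:
    """Container for a fitted mixture model (MLE)."""

    def __init__(self, model, params: pd.Series, llf: float, converged: bool,
                 n_starts: int, n_polished: int, optimizer_message: str = ""):
        self.model = model
        self.params = params
        self.llf = float(llf)
        self.converged = converged
        self.n_starts = n_starts
        self.n_polished = n_polished
        self.optimizer_message = optimizer_message

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def bic(self) -> float:
        return _bic(self.llf, self.k_params, self.nobs)

    @property
    def alpha(self) -> float:
        prop = [n for n in self.params.index if n.startswith("beta") or n == "gamma"]
        return 1.0 - float(self.params[prop].sum())

    @property
    def mixture_params(self) -> MixtureParams:
        p = self.params
        return MixtureParams(
            beta=float(p.get("beta", p.get("beta1", 0.0))),
            gamma=float(p["gamma"]),
            sigma=float(p["sigma"]) if "sigma" in p else None,
            kappa=float(p["kappa"]) if "kappa" in p else None,
            beta2=float(p["beta2"]) if "beta2" in p else None,
            bias=tuple(p[n] for n in p.index if n.startswith("bias")),
        )

    def cov_params(self, ridge: float = 0.0, rel_step: float = 1e-4) -> pd.DataFrame:
        """Covariance of the estimates from the inverse observed information.

        The Hessian of the negative log-likelihood is computed by central
        finite differences in the natural parameter space and inverted.  A
        singular Hessian raises; pass a small ``ridge`` (added to the
        diagonal) as the documented fallback.
        """
        theta = self.params.to_numpy(dtype=float)
        k = theta.size
        h = np.maximum(np.abs(theta), 1e-2) * rel_step
        H = np.empty((k, k))
        f = lambda t: -self.model.loglike(t)
        f0 = f(theta)
        for i in range(k):
            for j in range(i, k):
                ti = np.zeros(k); ti[i] = h[i]
                tj = np.zeros(k); tj[j] = h[j]
                if i == j:
                    H[i, i] = (f(theta + ti) - 2 * f0 + f(theta - ti)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(theta + ti + tj) - f(theta + ti - tj)
                        - f(theta - ti + tj) + f(theta - ti - tj)
                    ) / (4 * h[i] * h[j])
        if ridge:
            H = H + np.eye(k) * ridge
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular Hessian; refit or pass a small ridge (e.g. ridge=1e-6)"
            ) from e
        if not np.isfinite(cov).all():
            raise np.linalg.LinAlgError(
                "non-finite covariance; estimate may lie on a bound (try ridge>0)"
            )
        return pd.DataFrame(cov, index=self.params.index, columns=self.params.index)

    @property
    def bse(self) -> pd.Series:
        cov = self.cov_params()
        return pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=self.params.index)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} results",
            "=" * 40,
            f"n trials:        {self.nobs}",
            f"free parameters: {self.k_params}",
            f"log-likelihood:  {self.llf:.4f}",
            f"BIC:             {self.bic:.4f}",
            f"converged:       {self.converged} ({self.n_starts} starts, {self.n_polished} polished)",
            "-" * 40,
            f"{'param':<12}{'estimate':>12}",
            f"{'alpha (derived)':<12}{self.alpha:>9.4f}",
        ]
        for name, val in self.params.items():
            lines.append(f"{name:<12}{val:>12.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<MixtureResults llf={self.llf:.2f} params={self.params.to_dict()}>"


def condition_compare(fit_a: MixtureResults, fit_b: MixtureResults, ridge: float = 0.0):
    """Wald test of whether two fitted conditions share their parameters.

    Inverts each fit's Hessian to get parameter covariances and refers
    ``(dp)' (Cov_A + Cov_B)^-1 (dp)`` to a chi-square with k degrees of
    freedom.  Returns ``(statistic, p_value, df)``; p <= .05 counts the
    conditions as distinguished.
    """
    if list(fit_a.params.index) != list(fit_b.params.index):
        raise ValueError("fits must share a parameter vector")
    if not (fit_a.converged and fit_b.converged):
        warnings.warn("comparing fits that did not both converge")
    dp = fit_a.params.to_numpy() - fit_b.params.to_numpy()
    cov = fit_a.cov_params(ridge=ridge).to_numpy() + fit_b.cov_params(ridge=ridge).to_numpy()
    try:
        sol = np.linalg.solve(cov, dp)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular combined covariance; pass ridge>0 as a fallback"
        ) from e
    stat = float(dp @ sol)
    df = dp.size
    return stat, float(stats.chi2.sf(stat, df)), df


def crossval_response_sampling(
    data: TrialDataset,
    reps: int = 100,
    test_frac: float = 0.1,
    seed: int = 0,
    misbinding: bool = True,
    statistic: str = "likelihood",
    fit_kw: dict | None = None,
):
    """Held-out comparison of the uniform-guess vs response-sampling models.

    For each repetition the trials are split 90/10 at random; both models
    are fitted on the training split (the KDE built from *training*
    responses only) and the mean per-trial likelihood of the held-out trials
    under the fitted parameters is recorded.  Returns a DataFrame with one
    row per repetition and columns ``uniform`` / ``kde``; higher held-out
    likelihood for ``kde`` indicates real structure in the guesses rather
    than overfitting.

    ``statistic="log"`` averages log-likelihood per trial instead of the
    arithmetic mean of per-trial likelihoods.
    """
    if data.n_trials < 20:
        raise ValueError("need at least 20 trials for 90/10 cross-validation")
    rng = np.random.default_rng(seed)
    n = data.n_trials
    n_test = max(1, int(round(test_frac * n)))
    fit_kw = dict(fit_kw or {})
    rows = []
    for _ in range(reps):
        while True:
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if train_idx.size and test_idx.size:
                break
        train, test = data.subset(train_idx), data.subset(test_idx)
        out = {}
        for name in ("uniform", "kde"):
            if name == "kde":
                kde = ResponseKDE(train.responses, data.screen)
                m_train = SpatialMixtureModel(train, misbinding=misbinding, guess=kde)
            else:
                m_train = SpatialMixtureModel(train, misbinding=misbinding)
            res = m_train.fit(**fit_kw)
            if name == "kde":
                m_test = SpatialMixtureModel(test, misbinding=misbinding, guess=kde)
            else:
                m_test = SpatialMixtureModel(test, misbinding=misbinding)
            dens = m_test._density(res.params.to_numpy())
            out[name] = (
                float(np.mean(dens)) if statistic == "likelihood" else float(np.mean(np.log(dens)))
            )
        rows.append(out)
    return pd.DataFrame(rows)
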