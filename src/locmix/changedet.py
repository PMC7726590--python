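"""Change-detection (2AFC) likelihoods from the continuous mixture density.

A probe is shown displaced from the target by a distance ``d > 0`` and the
participant judges "same" or "different".  Under the mixture account, the
probability of correctly rejecting the probe is the probability that the
continuous model would have generated a response closer to the target than
the probe is — the integral of the mixture density over the on-screen part
of the disc of radius ``d`` around the target.  Imprecision spreads
acceptances near the target, guessing raises acceptance uniformly, and
misbinding raises acceptance near nontargets; accepting a given
displacement implies smaller ones would also have been accepted, which is
exactly what the integral encodes (no extra lapse parameter).

The integral uses polar quadrature around the target (Gauss-Legendre in
radius x uniform in angle) with off-screen nodes dropped.  For the uniform
component on a fully on-screen disc the rule is exact (the integrand is
polynomial in radius and constant in angle), so it matches the analytic
``pi d^2 / A`` to rounding error; near an edge the clipped quadrature
simply omits the off-screen mass, which is the documented behaviour of the
untruncated density there.

The default fitted model is the standard mixture (no misbinding): binary
judgments carry little per-trial information and misbinding-model 2AFC fits
are markedly slower (``misbinding=True`` is available but flagged slow).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .data import ChangeDataset
from .geometry import ScreenGeometry
from .model import _BaseMixtureModel

__all__ = ["ChangeDetectionModel", "p_reject"]

TWO_PI = 2.0 * math.pi
_EPS = 1e-9  # Bernoulli clipping for p in {0, 1}


class ChangeDetectionModel(_BaseMixtureModel):
    """2AFC change-detection model over a :class:`ChangeDataset`.

    Parameters
    ----------
    data : ChangeDataset
    misbinding : bool
        Include the swap component (slow; default False uses the standard
        two-component mixture).
    n_radial, n_angular : int
        Polar quadrature resolution for the disc integral.
    """

    def __init__(
        self,
        data: ChangeDataset,
        misbinding: bool = False,
        n_radial: int = 24,
        n_angular: int = 48,
        screen: ScreenGeometry | None = None,
    ):
        self.data = data
        self.screen = screen or data.screen
        self.misbinding = bool(misbinding)
        if misbinding:
            warnings.warn("misbinding 2AFC fits are slow; the standard mixture is the default")
        self.nobs = data.n_trials
        self.param_names = (["beta"] if misbinding else []) + ["gamma", "sigma"]
        self.n_prop = len(self.param_names) - 1
        self._scale_lo = 1e-2
        self._scale_hi = max(self.screen.width, self.screen.height)

        d = data.displacements
        n = self.nobs
        u, w = np.polynomial.legendre.leggauss(n_radial)
        r = d[:, None] * (u[None, :] + 1.0) / 2.0            # (n, nr)
        wr = w[None, :] * d[:, None] / 2.0
        ang = np.arange(n_angular) * TWO_PI / n_angular
        cs = np.column_stack([np.cos(ang), np.sin(ang)])      # (na, 2)
        pts = data.targets[:, None, None, :] + r[:, :, None, None] * cs[None, None, :, :]
        onscreen = self.screen.contains(pts)                  # (n, nr, na)
        wq = (wr * r)[:, :, None] * (TWO_PI / n_angular) * onscreen
        self._wq = wq.reshape(n, -1)                          # (n, nq)
        self._rsq = np.broadcast_to((r * r)[:, :, None], onscreen.shape).reshape(n, -1)
        m = data.nontargets.shape[1]
        if misbinding and m:
            diff = pts[:, :, :, None, :] - data.nontargets[:, None, None, :, :]
            self._ntsq = np.sum(diff * diff, axis=-1).reshape(n, -1, m)
        else:
            self._ntsq = None
        self._m = max(m, 1)
        self._unif = self._wq.sum(axis=1) / self.screen.area  # uniform-component integral

    # ---- probabilities ---------------------------------------------------
    def reject_probabilities(self, theta) -> np.ndarray:
        """Per-trial probability of rejecting the probe as changed."""
        theta = np.asarray(theta, dtype=float)
        if self.misbinding:
            beta, gamma, sigma = theta
        else:
            beta, (gamma, sigma) = 0.0, theta
        alpha = 1.0 - beta - gamma
        s2 = sigma * sigma
        gt = np.exp(-self._rsq / (2 * s2)) / (TWO_PI * s2)
        p = alpha * (self._wq * gt).sum(axis=1) + gamma * self._unif
        if self._ntsq is not None and beta > 0:
            gnt = np.exp(-self._ntsq / (2 * s2)) / (TWO_PI * s2)
            p = p + beta * (self._wq[:, :, None] * gnt).sum(axis=(1, 2)) / self._m
        return np.clip(p, 0.0, 1.0)

    def loglike(self, theta) -> float:
        """Bernoulli log-likelihood of the observed accept/reject responses."""
        p_rej = self.reject_probabilities(theta)
        if ((p_rej <= 0.0) | (p_rej >= 1.0)).any():
            warnings.warn("reject probability hit 0/1 exactly; clipped at eps")
        p_rej = np.clip(p_rej, _EPS, 1.0 - _EPS)
        y = self.data.responses
        return float(np.sum(y * np.log(p_rej) + (1 - y) * np.log1p(-p_rej)))

    # ---- starts ----------------------------------------------------------
    def _start_grid(self):
        sigmas = (10.0, 40.0, 120.0)
        props = (0.1, 0.4, 0.7)
        starts = []
        if self.misbinding:
            for b in (0.1, 0.3):
                for g in props:
                    if b + g < 0.95:
                        starts.extend(np.array([b, g, s]) for s in sigmas)
        else:
            starts.extend(np.array([g, s]) for g in props for s in sigmas)
        return starts

    def _moments_start(self) -> np.ndarray:
        d = self.data.displacements
        acc = 1 - self.data.responses
        gamma0 = float(np.clip(acc[d > np.median(d)].mean(), 0.05, 0.9))
        sigma0 = float(np.clip(np.median(d) / 1.5, self._scale_lo * 2, self._scale_hi / 2))
        if self.misbinding:
            return np.array([0.1, min(gamma0, 0.8), sigma0])
        return np.array([gamma0, sigma0])

    def fit_mcmc(self, draws: int = 10_000, seed: int = 0, **kw):
        from .mcmc import sample_posterior

        return sample_posterior(self, draws=draws, seed=seed, **kw)


def p_reject(
    target,
    displacement: float,
    nontargets,
    beta: float,
    gamma: float,
    sigma: float,
    screen: ScreenGeometry,
    n_radial: int = 24,
    n_angular: int = 48,
) -> float:
    """Probability of rejecting a probe displaced ``d`` from one target.

    Convenience wrapper around :class:`ChangeDetectionModel` for a single
    trial; ``p_accept = 1 - p_reject``, and the result is non-decreasing in
    ``d`` for fixed parameters.
    """
    if not displacement > 0:
        raise ValueError("probe displacement must be > 0")
    target = np.asarray(target, dtype=float)
    probe = target + np.array([displacement, 0.0])
    nt = np.asarray(nontargets, dtype=float).reshape(1, -1, 2) if np.size(nontargets) else np.empty((1, 0, 2))
    ds = ChangeDataset(target[None, :], probe[None, :], nt, np.array([0]), screen)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ChangeDetectionModel(
            ds, misbinding=beta > 0 and nt.shape[1] > 0, n_radial=n_radial, n_angular=n_angular
        )
    theta = [beta, gamma, sigma] if model.misbinding else [gamma, sigma]
    return float(model.reject_probabilities(np.asarray(theta))[0])
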