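"""Component densities for the spatial (2D) and circular (1D) mixture models.

The three-component misbinding model describes each response as coming from
one of three sources: a distribution centred on the target (proportion
``alpha``), a distribution centred on one of the ``m`` nontargets shown on
that trial (misbinding, proportion ``beta``, averaged over nontargets), or a
guess (proportion ``gamma``).  In 2D the component distribution is an
isotropic bivariate Gaussian with standard deviation ``sigma`` per axis and
zero covariance, and guesses are uniform over the screen area ``A``:

    p(r) = alpha * psi_sigma(r - t) + (beta / m) * sum_i psi_sigma(r - nt_i)
           + gamma / A

In 1D the Gaussian is replaced by the von Mises distribution with
concentration ``kappa`` and guesses are uniform over the circle (1 / 2*pi).
``alpha = 1 - beta - gamma`` is always derived, never free.

Array convention used throughout the package: responses and targets are
``(n, 2)`` float arrays, nontargets are ``(n, m_max, 2)`` with ``NaN``
padding where a trial has fewer nontargets; the padding rows are masked out
and the per-trial nontarget count honours the actual items shown.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import i0e, i1e, ndtr

from .geometry import ScreenGeometry

__all__ = [
    "mixture_density_2d",
    "mixture_density_2d_two_class",
    "mixture_density_1d",
    "log_likelihood",
    "bic",
    "kappa_to_sd",
    "sd_to_kappa",
    "wrap_angle",
    "UNIFORM_CIRCULAR_SD",
]

#: SD of the circular uniform distribution, pi / sqrt(3): the documented
#: finite value returned by :func:`kappa_to_sd` at kappa = 0.
UNIFORM_CIRCULAR_SD = math.pi / math.sqrt(3.0)

TWO_PI = 2.0 * math.pi


def _as2d(name: str, arr) -> np.ndarray:
    a = np.atleast_2d(np.asarray(arr, dtype=float))
    if a.shape[-1] != 2:
        raise ValueError(f"{name} must have trailing dimension 2")
    if not np.isfinite(a).all():
        raise ValueError(f"non-finite values in {name}")
    return a


def _nontarget_array(nontargets, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (n, m_max, 2) array and finite-mask (n, m_max)."""
    nt = np.asarray(nontargets, dtype=float)
    if nt.size == 0:
        nt = np.empty((n, 0, 2))
    if nt.ndim == 2:
        nt = nt[None, :, :] if n == 1 else nt[:, None, :]
    mask = np.isfinite(nt).all(axis=-1)
    return nt, mask


def _gauss2d(sq_dist: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic bivariate normal density at squared distance from its mean."""
    return np.exp(-sq_dist / (2.0 * sigma * sigma)) / (TWO_PI * sigma * sigma)


def _onscreen_mass(centers: np.ndarray, sigma: float, screen: ScreenGeometry) -> np.ndarray:
    """Probability mass of an isotropic Gaussian lying inside the screen.

    Zero covariance makes this a product of two 1D normal CDF differences.
    """
    cx, cy = centers[..., 0], centers[..., 1]
    px = ndtr((screen.width - cx) / sigma) - ndtr(-cx / sigma)
    py = ndtr((screen.height - cy) / sigma) - ndtr(-cy / sigma)
    return px * py


def _check_props(beta: float, gamma: float, sigma: float, extra: float = 0.0) -> None:
    if beta < 0 or gamma < 0 or extra < 0 or beta + gamma + extra > 1.0 + 1e-9:
        raise ValueError("mixture proportions must be >= 0 and sum to <= 1")
    if not sigma > 0:
        raise ValueError("spread parameter must be positive")


def mixture_density_2d(
    responses,
    targets,
    nontargets,
    beta: float,
    gamma: float,
    sigma: float,
    screen: ScreenGeometry,
    truncated: bool = False,
) -> np.ndarray:
    """Per-trial response density of the 2D misbinding mixture model.

    Parameters
    ----------
    responses, targets : array_like, shape (n, 2)
    nontargets : array_like, shape (n, m_max, 2)
        NaN-padded; a trial's misbinding term averages over its finite rows.
        With ``m = 0`` on a trial the beta component contributes nothing and
        the remaining weights are used as given (a warning is issued when
        ``beta > 0``).
    beta, gamma, sigma : float
        Misbinding and guessing proportions and per-axis Gaussian SD.
        ``alpha = 1 - beta - gamma``.
    truncated : bool
        If True, each Gaussian component is renormalised by its on-screen
        mass, turning the density into a proper truncated density over the
        screen.  The default (False) evaluates plain Gaussians.

    Returns
    -------
    ndarray, shape (n,) — density per unit area.
    """
    _check_props(beta, gamma, sigma)
    r = _as2d("responses", responses)
    t = _as2d("targets", targets)
    n = r.shape[0]
    nt, mask = _nontarget_array(nontargets, n)
    alpha = 1.0 - beta - gamma

    d0sq = np.sum((r - t) ** 2, axis=-1)
    g0 = _gauss2d(d0sq, sigma)
    if truncated:
        g0 = g0 / _onscreen_mass(t, sigma, screen)
    dens = alpha * g0 + gamma / screen.area

    m = mask.sum(axis=1)
    if beta > 0 and (m == 0).any():
        warnings.warn(
            "beta > 0 but some trials have no nontargets; their misbinding "
            "component contributes 0 without renormalisation",
            stacklevel=2,
        )
    if nt.shape[1] and beta > 0:
        dsq = np.sum((r[:, None, :] - nt) ** 2, axis=-1)
        gnt = np.where(mask, _gauss2d(np.where(mask, dsq, 0.0), sigma), 0.0)
        if truncated:
            w = np.where(mask, _onscreen_mass(np.where(mask[..., None], nt, 0.5), sigma, screen), 1.0)
            gnt = gnt / w
        with np.errstate(invalid="ignore"):
            mean_nt = np.where(m > 0, gnt.sum(axis=1) / np.maximum(m, 1), 0.0)
        dens = dens + beta * mean_nt
    return dens


def mixture_density_2d_two_class(
    responses,
    targets,
    nontargets,
    nt_class,
    beta1: float,
    beta2: float,
    gamma: float,
    sigma: float,
    screen: ScreenGeometry,
    truncated: bool = False,
) -> np.ndarray:
    """Misbinding mixture with separate swap rates for two nontarget classes.

    ``nt_class`` is an integer array (n, m_max) with labels 1 and 2 (any
    other value marks padding).  On trials where a class is absent that beta
    term contributes 0 (a warning flags the first occurrence).
    """
    _check_props(beta1, gamma, sigma, extra=beta2)
    r = _as2d("responses", responses)
    t = _as2d("targets", targets)
    n = r.shape[0]
    nt, mask = _nontarget_array(nontargets, n)
    cls = np.asarray(nt_class)
    if cls.shape != mask.shape:
        raise ValueError("nt_class must match the nontarget array layout")
    alpha = 1.0 - beta1 - beta2 - gamma

    d0sq = np.sum((r - t) ** 2, axis=-1)
    g0 = _gauss2d(d0sq, sigma)
    if truncated:
        g0 = g0 / _onscreen_mass(t, sigma, screen)
    dens = alpha * g0 + gamma / screen.area

    if nt.shape[1]:
        dsq = np.sum((r[:, None, :] - nt) ** 2, axis=-1)
        g = np.where(mask, _gauss2d(np.where(mask, dsq, 0.0), sigma), 0.0)
        if truncated:
            w = np.where(mask, _onscreen_mass(np.where(mask[..., None], nt, 0.5), sigma, screen), 1.0)
            g = g / w
        for b, label in ((beta1, 1), (beta2, 2)):
            if b == 0:
                continue
            sel = mask & (cls == label)
            mc = sel.sum(axis=1)
            if (mc == 0).any():
                warnings.warn(
                    f"nontarget class {label} absent on some trials; its "
                    "misbinding term contributes 0 there",
                    stacklevel=2,
                )
            term = np.where(mc > 0, np.where(sel, g, 0.0).sum(axis=1) / np.maximum(mc, 1), 0.0)
            dens = dens + b * term
    return dens


def wrap_angle(theta) -> np.ndarray:
    """Reduce angles to the interval [-pi, pi)."""
    return np.mod(np.asarray(theta, dtype=float) + math.pi, TWO_PI) - math.pi


def _vonmises(delta: np.ndarray, kappa: float) -> np.ndarray:
    # exponentially scaled Bessel keeps this finite for very large kappa
    return np.exp(kappa * (np.cos(delta) - 1.0)) / (TWO_PI * i0e(kappa))


def mixture_density_1d(responses, targets, nontargets, beta, gamma, kappa) -> np.ndarray:
    """Circular misbinding mixture density (per radian).

    The von Mises distribution (circular analogue of the Gaussian) with
    concentration ``kappa`` plays the role of the Gaussian; guesses are
    uniform over the circle.  Angles are radians; ``nontargets`` is
    ``(n, m_max)`` NaN-padded.
    """
    if not kappa > 0:
        raise ValueError("kappa must be positive")
    _check_props(beta, gamma, 1.0)
    r = np.atleast_1d(np.asarray(responses, dtype=float))
    t = np.atleast_1d(np.asarray(targets, dtype=float))
    if not (np.isfinite(r).all() and np.isfinite(t).all()):
        raise ValueError("non-finite angles")
    nt = np.asarray(nontargets, dtype=float)
    if nt.size == 0:
        nt = np.empty((r.shape[0], 0))
    if nt.ndim == 1:
        nt = nt[:, None] if r.shape[0] > 1 else nt[None, :]
    mask = np.isfinite(nt)
    alpha = 1.0 - beta - gamma

    dens = alpha * _vonmises(r - t, kappa) + gamma / TWO_PI
    m = mask.sum(axis=1)
    if beta > 0 and (m == 0).any():
        warnings.warn("beta > 0 on trials without nontargets", stacklevel=2)
    if nt.shape[1] and beta > 0:
        g = np.where(mask, _vonmises(np.where(mask, r[:, None] - nt, 0.0), kappa), 0.0)
        dens = dens + beta * np.where(m > 0, g.sum(axis=1) / np.maximum(m, 1), 0.0)
    return dens


def log_likelihood(densities) -> float:
    """Sum of log densities; -inf (with a warning) if any density is <= 0."""
    d = np.asarray(densities, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one trial")
    if (d <= 0).any() or not np.isfinite(d).all():
        warnings.warn("non-positive trial density; log-likelihood is -inf", stacklevel=2)
        return -np.inf
    return float(np.log(d).sum())


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, ``k * ln(n) - 2 * lnL`` (smaller = better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * math.log(n) - 2.0 * loglik


def kappa_to_sd(kappa: float) -> float:
    """Circular standard deviation (radians) of a von Mises distribution.

    ``sqrt(-2 ln(I1(kappa) / I0(kappa)))``, monotonically decreasing in
    kappa.  ``kappa = 0`` maps to the SD of the circular uniform,
    ``pi / sqrt(3)``, as a documented finite cap.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return UNIFORM_CIRCULAR_SD
    r = i1e(kappa) / i0e(kappa)  # the exp scaling cancels
    if r >= 1.0:
        return 0.0
    return math.sqrt(-2.0 * math.log(r))


def sd_to_kappa(sd: float, tol: float = 1e-12) -> float:
    """Inverse of :func:`kappa_to_sd` by bisection on log-kappa."""
    if not sd > 0:
        raise ValueError("sd must be positive")
    if sd >= UNIFORM_CIRCULAR_SD:
        return 0.0
    target = math.exp(-sd * sd / 2.0)  # mean resultant length

    def resultant(kappa: float) -> float:
        return i1e(kappa) / i0e(kappa)

    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if resultant(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0 + tol:
            break
    return math.sqrt(lo * hi)
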