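"""Guess-distribution components: uniform over the screen, or a response-
sampling KDE built from a participant's own response locations.

The response-sampling idea: pooled over an experiment, a participant's
responses form an empirical distribution that already contains whatever
spatial biases they have.  Smoothing those locations with a product-Gaussian
kernel yields a guess density that replaces the uniform ``gamma / A`` term,
keeping the free-parameter count unchanged.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr

from .geometry import ScreenGeometry

__all__ = ["ResponseKDE", "build_response_kde"]

TWO_PI = 2.0 * math.pi


class ResponseKDE:
    """Product-Gaussian kernel density over 2D response locations.

    Per-axis bandwidths default to Scott's rule for d = 2,
    ``h_j = sd_j * n**(-1/6)``.  Kernel mass falling off-screen is
    renormalised over the screen rectangle (analytically, since the kernel
    factorises into axis-wise normal CDFs), keeping the guess proportion
    interpretable as a probability.
    """

    def __init__(self, responses, screen: ScreenGeometry, bandwidth=None, normalize: bool = True):
        pts = np.atleast_2d(np.asarray(responses, dtype=float))
        if pts.shape[0] < 2 or np.unique(pts, axis=0).shape[0] < 2:
            raise ValueError("need at least 2 distinct responses to build a KDE")
        if not np.isfinite(pts).all():
            raise ValueError("non-finite response coordinates")
        self.points = pts
        self.screen = screen
        n = pts.shape[0]
        if bandwidth is None:
            sd = pts.std(axis=0, ddof=1)
            h = sd * n ** (-1.0 / 6.0)
        else:
            h = np.broadcast_to(np.asarray(bandwidth, dtype=float), (2,)).copy()
        if not (h > 0).all():
            raise ValueError("bandwidth must be positive on both axes (are all responses identical?)")
        self.bandwidth = h
        self.normalize = normalize
        # analytic on-screen mass of each kernel (product of CDF differences)
        mx = ndtr((screen.width - pts[:, 0]) / h[0]) - ndtr(-pts[:, 0] / h[0])
        my = ndtr((screen.height - pts[:, 1]) / h[1]) - ndtr(-pts[:, 1] / h[1])
        self._screen_mass = float(np.mean(mx * my))

    def pdf(self, xy) -> np.ndarray:
        """Density at (n, 2) evaluation points (per unit area)."""
        q = np.atleast_2d(np.asarray(xy, dtype=float))
        hx, hy = self.bandwidth
        zx = (q[:, None, 0] - self.points[None, :, 0]) / hx
        zy = (q[:, None, 1] - self.points[None, :, 1]) / hy
        k = np.exp(-0.5 * (zx * zx + zy * zy))
        dens = k.mean(axis=1) / (TWO_PI * hx * hy)
        if self.normalize:
            dens = dens / self._screen_mass
        return dens

    def sample(self, n: int, rng: np.random.Generator, max_resample: int = 10_000) -> np.ndarray:
        """Draw n points from the KDE, resampling any that land off-screen."""
        out = np.empty((n, 2))
        todo = np.arange(n)
        for _ in range(max_resample):
            idx = rng.integers(0, self.points.shape[0], size=todo.size)
            cand = self.points[idx] + rng.standard_normal((todo.size, 2)) * self.bandwidth
            ok = self.screen.contains(cand)
            out[todo[ok]] = cand[ok]
            todo = todo[~ok]
            if todo.size == 0:
                return out
        raise RuntimeError("KDE sampling failed to land on screen")


def build_response_kde(responses, screen: ScreenGeometry, bandwidth=None, normalize: bool = True) -> ResponseKDE:
    """Build the response-sampling guess density for one participant."""
    return ResponseKDE(responses, screen, bandwidth=bandwidth, normalize=normalize)
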