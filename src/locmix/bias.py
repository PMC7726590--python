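"""Parametric response-bias models.

Three bias families are supported, each usable generatively (applied to
simulated responses, then edge-constrained to the screen) and as extra free
parameters of a fitted model (applied to the component means before density
evaluation):

* ``constant`` — a fixed translation subtracted from every response
  (2 extra parameters, the x/y translation);
* ``edge_proportional`` — responses shifted toward (positive) or away from
  (negative) a named screen edge by a proportion of their distance to it
  (1 extra parameter);
* ``radial`` — responses contracted toward (positive) or expanded away from
  (negative) a reference point, either a fixed point such as the screen
  center or a per-trial coordinate such as the nontarget location
  (1 extra parameter).

Convention (documented and tested): simulation SUBTRACTS the constant bias
from responses; the fitted correction shifts component means with the same
transform, so a recovered bias estimates the simulated bias with the same
sign.  Bias application always clips to the screen boundary; mixture
component sampling instead resamples off-screen draws — the two rules are
never mixed silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScreenGeometry

__all__ = [
    "BiasSpec",
    "apply_constant_bias",
    "apply_edge_proportional_bias",
    "apply_radial_bias",
    "apply_bias",
]

_EDGES = ("left", "right", "top", "bottom")


@dataclass(frozen=True)
class BiasSpec:
    """Which bias family is active and where its center/edge lies.

    ``center`` may be ``"screen_center"``, ``"nontarget"`` (per-trial: the
    trial's first nontarget), or a fixed ``(x, y)`` tuple.  Numeric bias
    values are not stored here: generative values are passed to
    :func:`apply_bias`, fitted values live in the model's parameter vector.
    """

    kind: str = "none"  # none | constant | edge_proportional | radial
    edge: str = "right"
    center: object = "screen_center"

    def __post_init__(self) -> None:
        if self.kind not in ("none", "constant", "edge_proportional", "radial"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kind == "edge_proportional" and self.edge not in _EDGES:
            raise ValueError(f"edge must be one of {_EDGES}")

    @property
    def n_params(self) -> int:
        return {"none": 0, "constant": 2, "edge_proportional": 1, "radial": 1}[self.kind]

    @property
    def param_names(self) -> list[str]:
        return {
            "none": [],
            "constant": ["bias_x", "bias_y"],
            "edge_proportional": ["bias_prop"],
            "radial": ["bias_radial"],
        }[self.kind]

    def resolve_centers(self, screen: ScreenGeometry, trial_centers=None) -> np.ndarray:
        """Reference point(s) for a radial bias; (2,) or (n, 2)."""
        if self.center == "screen_center":
            return screen.center
        if self.center == "nontarget":
            if trial_centers is None:
                raise ValueError("radial bias with per-trial center requires nontarget coordinates on every trial")
            tc = np.asarray(trial_centers, dtype=float)
            if not np.isfinite(tc).all():
                raise ValueError("per-trial bias center missing on some trials")
            return tc
        return np.asarray(self.center, dtype=float)


def apply_constant_bias(points, bias, screen: ScreenGeometry, clip: bool = True) -> np.ndarray:
    """Subtract a fixed translation, then edge-constrain to the screen."""
    out = np.asarray(points, dtype=float) - np.asarray(bias, dtype=float)
    return screen.clip(out) if clip else out


def apply_edge_proportional_bias(points, proportion: float, edge: str, screen: ScreenGeometry, clip: bool = True) -> np.ndarray:
    """Shift points by a proportion of their distance to a screen edge.

    Positive values move toward the edge, negative away; the orthogonal
    coordinate is untouched (for the right edge, ``x' = x + b (W - x)``).
    """
    if edge not in _EDGES:
        raise ValueError(f"edge must be one of {_EDGES}")
    p = np.asarray(points, dtype=float).copy()
    b = float(proportion)
    x, y = p[..., 0], p[..., 1]
    if edge == "right":
        p[..., 0] = x + b * (screen.width - x)
    elif edge == "left":
        p[..., 0] = x - b * x
    elif edge == "bottom":
        p[..., 1] = y + b * (screen.height - y)
    else:  # top
        p[..., 1] = y - b * y
    return screen.clip(p) if clip else p


def apply_radial_bias(points, proportion: float, center, screen: ScreenGeometry, clip: bool = True) -> np.ndarray:
    """Contract (b > 0) or expand (b < 0) points about a center.

    ``point' = point + b (center - point)``; for b in (0, 1) this is a pure
    contraction: |point' - center| = (1 - b) |point - center|.
    """
    p = np.asarray(points, dtype=float)
    c = np.asarray(center, dtype=float)
    out = p + float(proportion) * (c - p)
    return screen.clip(out) if clip else out


def apply_bias(points, spec: BiasSpec, values, screen: ScreenGeometry, trial_centers=None, clip: bool = True) -> np.ndarray:
    """Dispatch a bias transform given its spec and numeric parameter values."""
    if spec.kind == "none":
        return np.asarray(points, dtype=float)
    if spec.kind == "constant":
        return apply_constant_bias(points, values, screen, clip=clip)
    if spec.kind == "edge_proportional":
        return apply_edge_proportional_bias(points, float(np.ravel(values)[0]), spec.edge, screen, clip=clip)
    centers = spec.resolve_centers(screen, trial_centers)
    return apply_radial_bias(points, float(np.ravel(values)[0]), centers, screen, clip=clip)
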