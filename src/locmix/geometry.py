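"""Screen geometry and unit conversions.

The response space is a closed rectangle ``[0, width] x [0, height]`` with the
origin at the top-left corner, x increasing rightward and y downward (the
convention of most display toolkits).  All model code takes the screen as an
explicit argument; units are whatever the screen dimensions are expressed in
(pixels by default), and no conversion is ever implicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "DEFAULT_SCREEN",
    "deg_to_px",
    "px_to_deg",
    "cm_to_px",
    "px_to_cm",
]

#: Default viewing distance (cm) and screen resolution (px per cm) used for
#: visual-angle conversions; these match a 40 cm viewing distance on a
#: 42 px/cm laptop display.
DEFAULT_VIEWING_CM = 40.0
DEFAULT_PX_PER_CM = 42.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Bounded rectangular response space.

    Parameters
    ----------
    width, height : float
        Extent of the screen in length units (e.g. pixels).  Must be > 0.

    Notes
    -----
    The area ``A = width * height`` normalises the uniform guess component of
    the spatial mixture model.
    """

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("screen width and height must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> np.ndarray:
        return np.array([self.width / 2.0, self.height / 2.0])

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed rectangle."""
        p = np.asarray(points, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)

    def clip(self, points: np.ndarray) -> np.ndarray:
        """Edge-constrain points to the screen rectangle."""
        p = np.asarray(points, dtype=float).copy()
        p[..., 0] = np.clip(p[..., 0], 0.0, self.width)
        p[..., 1] = np.clip(p[..., 1], 0.0, self.height)
        return p

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly over the screen."""
        u = rng.random((n, 2))
        return u * np.array([self.width, self.height])


#: The 1366x768 px screen used throughout the simulation defaults.
DEFAULT_SCREEN = ScreenGeometry(1366.0, 768.0)


def deg_to_px(
    degrees: float,
    viewing_cm: float = DEFAULT_VIEWING_CM,
    px_per_cm: float = DEFAULT_PX_PER_CM,
) -> float:
    """Convert a visual angle to an on-screen extent in pixels.

    Uses the exact chord formula ``2 * D * tan(deg / 2)``; at 40 cm and
    42 px/cm, 3 degrees is ~88 px and 1 degree ~29 px.
    """
    return 2.0 * viewing_cm * math.tan(math.radians(degrees) / 2.0) * px_per_cm


def px_to_deg(
    pixels: float,
    viewing_cm: float = DEFAULT_VIEWING_CM,
    px_per_cm: float = DEFAULT_PX_PER_CM,
) -> float:
    """Inverse of :func:`deg_to_px`."""
    return math.degrees(2.0 * math.atan(pixels / px_per_cm / (2.0 * viewing_cm)))


def cm_to_px(cm: float, px_per_cm: float = DEFAULT_PX_PER_CM) -> float:
    return cm * px_per_cm


def px_to_cm(pixels: float, px_per_cm: float = DEFAULT_PX_PER_CM) -> float:
    return pixels / px_per_cm
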