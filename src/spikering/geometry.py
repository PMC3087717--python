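"""Circular geometry shared by both network layers.

Both the place-cell (input) and action-cell (output) layers live on a ring:
cell ``k`` of a layer with ``count`` cells has preferred angle
``2*pi*k/count``.  All angular comparisons go through the wrapped distance
:func:`circular_distance`, which measures the shorter arc between two angles
and therefore lies in ``[0, pi]``.  The trial reward is an unnormalised
Gaussian of that distance (peak value 1), and the alternative performance
measure is the wrapped error scaled to ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TWO_PI",
    "RingLayout",
    "RewardParams",
    "circular_distance",
    "gaussian_reward",
    "normalized_error",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class RingLayout:
    """Equally spaced preferred angles on the circle.

    Parameters
    ----------
    count
        Number of cells on the ring (>= 1).
    """

    count: int

    def __post_init__(self) -> None:
        if int(self.count) != self.count or self.count < 1:
            raise ValueError(f"count must be a positive integer, got {self.count!r}")

    @property
    def spacing(self) -> float:
        """Angular distance between neighbouring cells, ``2*pi/count``."""
        return TWO_PI / self.count

    @property
    def angles(self) -> np.ndarray:
        """Preferred angles ``2*pi*k/count`` for ``k = 0..count-1``."""
        return TWO_PI * np.arange(self.count) / self.count

    def preferred_angle(self, k: int) -> float:
        return TWO_PI * (k % self.count) / self.count


@dataclass(frozen=True)
class RewardParams:
    """Width of the Gaussian reward function.

    ``sigma_r`` is the standard deviation, in radians, of the reward as a
    function of the wrapped target/decision distance.  The reward is not
    normalised: its peak value is 1 at zero distance.
    """

    sigma_r: float = 0.5

    def __post_init__(self) -> None:
        if not (self.sigma_r > 0):
            raise ValueError(f"sigma_r must be > 0, got {self.sigma_r!r}")


def circular_distance(a, b):
    """Shorter-arc distance between two angles (radians), in ``[0, pi]``.

    Accepts scalars or arrays (broadcasting); inputs are reduced modulo
    ``2*pi`` so any finite real angle is valid.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("circular_distance requires finite angles")
    d = np.abs(a - b) % TWO_PI
    d = np.minimum(d, TWO_PI - d)
    if d.ndim == 0:
        return float(d)
    return d


def gaussian_reward(target, decision, params: RewardParams = RewardParams()):
    """Unnormalised Gaussian reward ``exp(-d^2 / (2 sigma_r^2))`` in ``(0, 1]``.

    ``d`` is the wrapped distance between target and decision, so the reward
    is maximal (1) exactly when the decision hits the target and decreases
    monotonically towards ``exp(-pi^2/(2 sigma_r^2))`` at the antipode.
    """
    d = circular_distance(target, decision)
    out = np.exp(-np.square(d) / (2.0 * params.sigma_r**2))
    if np.ndim(out) == 0:
        return float(out)
    return out


def normalized_error(target, decision):
    """Wrapped absolute error scaled by ``pi`` so it lies in ``[0, 1]``.

    Used as a reward-shape-independent performance measure: 0 for a perfect
    decision, 1 for the antipodal one, linear in the wrapped distance.
    """
    out = np.asarray(circular_distance(target, decision)) / np.pi
    if out.ndim == 0:
        return float(out)
    return out
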