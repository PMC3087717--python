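"""Population-vector readout of the action layer's decision.

The decision angle is the argument of the activity-weighted sum of unit
vectors at the cells' preferred angles ("every neuron votes with its firing
rate").  The readout is linear in the rates, invariant to rescaling them,
and exactly equivariant under ring rotation.  A trial in which no action
cell fires has no defined decision; the caller decides how to score it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TWO_PI, RingLayout

__all__ = ["DecisionResult", "DegenerateDecisionError", "mean_activity", "population_vector_decision"]


class DegenerateDecisionError(ValueError):
    """Raised when the population vector has zero length (no usable vote)."""


@dataclass(frozen=True)
class DecisionResult:
    angle: float  # radians in [0, 2*pi)
    resultant_length: float  # |sum_i r_i e^{i phi_i}|, >= 0
    total_spikes: int


def mean_activity(action_raster: np.ndarray, t_window: float) -> np.ndarray:
    """Per-cell mean firing rate (Hz): spike count divided by the window."""
    if not (t_window > 0):
        raise ValueError("t_window must be > 0")
    return np.asarray(action_raster).sum(axis=1) / float(t_window)


def population_vector_decision(
    mean_rates: np.ndarray, layout: RingLayout, total_spikes: int | None = None
) -> DecisionResult:
    """Decode the decision angle from mean rates via the population vector.

    ``total_spikes`` is carried through for bookkeeping; when omitted it is
    taken as ``round(sum(mean_rates))``, which is exact when counts rather
    than rates are passed (the angle is scale invariant either way).

    Raises
    ------
    DegenerateDecisionError
        If the resultant vector has (numerically) zero length — no spikes,
        or perfectly balanced activity.
    """
    r = np.asarray(mean_rates, dtype=float)
    if r.shape != (layout.count,):
        raise ValueError(f"mean_rates must have shape ({layout.count},), got {r.shape}")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    phi = layout.angles
    x = float(np.dot(r, np.cos(phi)))
    y = float(np.dot(r, np.sin(phi)))
    length = float(np.hypot(x, y))
    if total_spikes is None:
        total_spikes = int(round(float(r.sum())))
    if length <= 1e-12 * max(1.0, float(r.sum())):
        raise DegenerateDecisionError("population vector has zero resultant length")
    angle = float(np.arctan2(y, x)) % TWO_PI
    return DecisionResult(angle=angle, resultant_length=length, total_spikes=total_spikes)
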