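"""Place-cell input layer: sigmoidal ring tuning and Poisson spike generation.

Each place cell ``j`` fires as a Poisson process whose rate depends on the
wrapped distance ``d`` between its preferred angle and the animat's location::

    rate_j = nu_max * logistic(beta * (1/2 - c * d(theta_j, location)))

With the default scale factor ``c = M / (2*pi)`` the argument of the logistic
vanishes exactly midway between two neighbouring cells, so the rate there is
``nu_max / 2`` ("drops to half of the maximum") independently of the
steepness ``beta``.  ``beta`` controls how much neighbouring receptive
fields overlap: a shallower sigmoid (smaller ``beta``) makes a cell respond
far from its preferred angle.

Rates are constant within a trial; spikes are generated per time bin as
independent Bernoulli draws with probability ``rate * dt`` (clipped at 1),
the first-order discretisation of the Poisson process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import TWO_PI, RingLayout, circular_distance

__all__ = ["PlaceCellParams", "place_rates", "sample_poisson_raster", "calibrate_nu_max"]


@dataclass(frozen=True)
class PlaceCellParams:
    """Tuning-curve parameters of the place-cell population.

    Parameters
    ----------
    m
        Number of place cells on the input ring.
    beta
        Steepness of the sigmoidal tuning curve (dimensionless, > 0).
        Smaller values widen the receptive fields and increase the overlap
        between neighbouring cells.
    nu_max
        Peak-rate scale in Hz.  With narrow tuning this is close to the rate
        of the most active cell; see :func:`calibrate_nu_max` to set it from
        a summed-population-rate budget instead.
    c
        Scale factor of the distance term.  ``None`` (default) uses
        ``m / (2*pi)``, which pins the half-maximum to the midpoint between
        neighbouring cells for every population size.
    """

    m: int = 256
    beta: float = 2.0
    nu_max: float = 180.0
    c: float | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not (self.beta > 0):
            raise ValueError("beta must be > 0")
        if not (self.nu_max > 0):
            raise ValueError("nu_max must be > 0")

    @property
    def scale_c(self) -> float:
        return self.m / TWO_PI if self.c is None else self.c

    @property
    def layout(self) -> RingLayout:
        return RingLayout(self.m)


def place_rates(location: float, params: PlaceCellParams, layout: RingLayout | None = None) -> np.ndarray:
    """Firing rate (Hz) of each place cell for an animat at ``location``.

    Returns an ``(m,)`` vector.  The rate is a strictly decreasing function
    of the wrapped distance to the cell's preferred angle and equals
    ``nu_max/2`` at half the inter-cell spacing when ``c`` is left at its
    default.
    """
    layout = layout or params.layout
    if layout.count != params.m:
        raise ValueError(f"layout.count ({layout.count}) != params.m ({params.m})")
    d = circular_distance(layout.angles, float(location))
    x = params.beta * (0.5 - params.scale_c * d)
    # logistic in a numerically safe form
    rates = params.nu_max * 0.5 * (1.0 + np.tanh(0.5 * x))
    return rates


def calibrate_nu_max(params: PlaceCellParams, total_rate: float = 180.0) -> PlaceCellParams:
    """Rescale ``nu_max`` so the summed population rate equals ``total_rate`` Hz.

    The summed rate depends (weakly) on where the animat sits relative to
    the cell grid; the calibration uses the average over a fine grid of
    locations spanning one inter-cell spacing, which is the period of the
    summed rate.
    """
    probe = replace(params, nu_max=1.0)
    layout = probe.layout
    locs = np.linspace(0.0, layout.spacing, 32, endpoint=False)
    mean_sum = float(np.mean([place_rates(x, probe, layout).sum() for x in locs]))
    return replace(params, nu_max=total_rate / mean_sum)


def sample_poisson_raster(
    rates: np.ndarray,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    uniforms: np.ndarray | None = None,
) -> np.ndarray:
    """Binary ``(m, n_steps)`` spike raster from per-cell Poisson rates.

    Each bin is an independent Bernoulli draw with probability
    ``rate * dt`` (clipped at 1).  ``uniforms`` may supply the pre-drawn
    uniform variates (shape ``(m, n_steps)``) instead of ``rng``; this is
    what makes exact rotation-equivariance checks possible.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = np.minimum(rates * dt, 1.0)
    if uniforms is None:
        uniforms = rng.random((rates.size, n_steps))
    return (uniforms < p[:, None]).astype(np.uint8)
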