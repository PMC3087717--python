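"""Action-cell output layer: leaky integrate-and-fire ring with escape noise.

Each action cell integrates feedforward place-cell spikes (weight matrix
``w_ff``, N x M) and, optionally, lateral spikes through a fixed Mexican-hat
matrix (short-range excitation, uniform long-range inhibition).  Membrane
potentials relax towards ``u_rest`` with time constant ``tau_m``; every
presynaptic spike deflects the potential by its synaptic weight
instantaneously.  Spiking is stochastic ("escape noise"): at potential ``u``
a cell fires in a bin of width ``dt`` with probability
``min(rho0 * exp((u - u_theta)/delta_u) * dt, 1)``, after which its
potential is reset to ``u_reset`` below rest (hyperpolarising spike
afterpotential).

Lateral spikes act with a one-time-step delay (a cell sees the other cells'
spikes from the previous bin), feedforward spikes within the same bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RingLayout, circular_distance

__all__ = [
    "ActionCellParams",
    "LateralParams",
    "mexican_hat_weights",
    "escape_rate",
    "step_membrane",
    "simulate_action_layer",
]


@dataclass(frozen=True)
class ActionCellParams:
    """Membrane and escape-noise parameters of the action cells.

    Defaults are standard leaky integrate-and-fire values: 20 ms membrane
    time constant, resting potential -70 mV, soft threshold 10 mV above
    rest with 4 mV sharpness, 60 Hz rate at threshold and a 5 mV
    hyperpolarising reset below rest.
    """

    n: int = 256
    tau_m: float = 0.020  # s
    u_rest: float = -70.0  # mV
    u_theta: float = -60.0  # mV, soft threshold
    delta_u: float = 4.0  # mV, threshold sharpness
    rho0: float = 60.0  # Hz, escape rate at threshold
    u_reset: float = -75.0  # mV, post-spike potential

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.tau_m > 0 and self.delta_u > 0 and self.rho0 > 0):
            raise ValueError("tau_m, delta_u and rho0 must be > 0")
        if not (self.u_reset < self.u_rest):
            raise ValueError("u_reset must lie below u_rest")

    @property
    def layout(self) -> RingLayout:
        return RingLayout(self.n)


@dataclass(frozen=True)
class LateralParams:
    """Mexican-hat lateral connectivity of the action ring.

    ``w_scale = 0`` disables lateral connections entirely (the "democratic"
    architecture).  For ``w_scale > 0`` the weight between cells at wrapped
    angular distance ``d`` is::

        (w_scale / n) * (w_e * exp(-d^2 / (2 sigma_lat^2)) - w_i)

    i.e. Gaussian short-range excitation on top of uniform inhibition,
    scaled by ``1/n`` so the total recurrent drive is independent of the
    ring size.
    """

    w_scale: float = 0.0
    w_e: float = 5.0
    w_i: float = 1.5
    sigma_lat: float = 0.5  # rad

    def __post_init__(self) -> None:
        if self.w_scale < 0:
            raise ValueError("w_scale must be >= 0")
        if not (self.sigma_lat > 0):
            raise ValueError("sigma_lat must be > 0")


def mexican_hat_weights(params: LateralParams, layout: RingLayout) -> np.ndarray:
    """Circulant ``(n, n)`` lateral weight matrix.

    Row ``k`` is row 0 rolled by ``k``; the matrix is symmetric, maximal on
    the diagonal and (for sufficient ``w_i``) negative at large distance.
    """
    angles = layout.angles
    d = circular_distance(angles[:, None], angles[None, :])
    w = (params.w_scale / layout.count) * (
        params.w_e * np.exp(-np.square(d) / (2.0 * params.sigma_lat**2)) - params.w_i
    )
    return w


def escape_rate(u, params: ActionCellParams):
    """Instantaneous firing rate ``rho0 * exp((u - u_theta)/delta_u)`` in Hz."""
    return params.rho0 * np.exp((np.asarray(u, dtype=float) - params.u_theta) / params.delta_u)


def step_membrane(
    u: np.ndarray,
    ff_spikes: np.ndarray,
    w_ff: np.ndarray,
    lat_spikes_prev: np.ndarray,
    w_lat: np.ndarray | None,
    params: ActionCellParams,
    dt: float,
) -> np.ndarray:
    """One integration step of the membrane potentials.

    The leak is integrated exactly over the bin
    (``u <- u_rest + (u - u_rest) * exp(-dt/tau_m)``, the closed-form
    solution of the linear leak equation) and the spikes of the bin then add
    their synaptic weights as instantaneous deflections.  Lateral input uses
    the previous bin's action spikes.
    """
    u = np.asarray(u, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if w_ff.shape[0] != u.shape[0] or w_ff.shape[1] != np.shape(ff_spikes)[0]:
        raise ValueError("inconsistent feedforward dimensions")
    decay = np.exp(-dt / params.tau_m)
    out = params.u_rest + (u - params.u_rest) * decay
    out = out + w_ff @ np.asarray(ff_spikes, dtype=float)
    if w_lat is not None:
        if w_lat.shape != (u.shape[0], np.shape(lat_spikes_prev)[0]):
            raise ValueError("inconsistent lateral dimensions")
        out = out + w_lat @ np.asarray(lat_spikes_prev, dtype=float)
    return out


def simulate_action_layer(
    place_raster: np.ndarray,
    w_ff: np.ndarray,
    lateral: LateralParams,
    params: ActionCellParams,
    dt: float,
    rng: np.random.Generator,
    w_lat: np.ndarray | None = None,
    uniforms: np.ndarray | None = None,
):
    """Simulate one trial of the action layer.

    Parameters
    ----------
    place_raster
        Binary ``(m, t_steps)`` input raster.
    w_ff
        Feedforward weights, ``(n, m)``.
    lateral
        Lateral connectivity parameters; ``w_lat`` may pre-supply the
        matrix to avoid rebuilding it every trial.
    uniforms
        Optional pre-drawn ``(n, t_steps)`` uniforms for the escape-noise
        draws (drawn from ``rng`` otherwise).  Supplying rolled uniforms
        gives bit-exact rotation-equivariance.

    Returns
    -------
    action_raster : uint8 ``(n, t_steps)``
    rho_trace : float ``(n, t_steps)``
        Escape rate (Hz) of every cell at every step, i.e. the instantaneous
        firing probability per unit time used by the plasticity rule.
    u_final : float ``(n,)``
        Membrane potentials after the last step (trials normally restart
        from ``u_rest`` regardless).
    """
    place_raster = np.asarray(place_raster)
    n = params.n
    m, t_steps = place_raster.shape
    if w_ff.shape != (n, m):
        raise ValueError(f"w_ff must be (n, m) = {(n, m)}, got {w_ff.shape}")

    use_lateral = lateral.w_scale > 0 or w_lat is not None
    if use_lateral and w_lat is None:
        w_lat = mexican_hat_weights(lateral, params.layout)

    # feedforward drive for the whole trial in one BLAS call
    drive = w_ff @ place_raster.astype(float)

    if uniforms is None:
        uniforms = rng.random((n, t_steps))
    elif uniforms.shape != (n, t_steps):
        raise ValueError("uniforms must have shape (n, t_steps)")

    decay = np.exp(-dt / params.tau_m)
    inv_du = 1.0 / params.delta_u
    u = np.full(n, params.u_rest, dtype=float)
    raster = np.zeros((n, t_steps), dtype=np.uint8)
    rho_trace = np.empty((n, t_steps), dtype=float)
    prev_spikes = np.zeros(n, dtype=np.uint8)

    for t in range(t_steps):
        u = params.u_rest + (u - params.u_rest) * decay
        u += drive[:, t]
        if use_lateral:
            idx = np.flatnonzero(prev_spikes)
            if idx.size:
                u += w_lat[:, idx].sum(axis=1)
        rho = params.rho0 * np.exp((u - params.u_theta) * inv_du)
        rho_trace[:, t] = rho
        p = np.minimum(rho * dt, 1.0)
        spikes = uniforms[:, t] < p
        raster[spikes, t] = 1
        u[spikes] = params.u_reset
        prev_spikes = spikes

    return raster, rho_trace, u
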