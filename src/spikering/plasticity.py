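"""Reward-modulated policy-gradient plasticity with per-trial eligibility traces.

The feedforward weights are updated once per trial::

    w_ij <- w_ij + eta * (R - b) * e_ij + xi_ij

where ``R`` is the trial reward, ``b`` a constant reward baseline, ``xi`` an
optional positively biased uniform noise sample on ``[0, noise_eps]``
(modelling synaptic crosstalk), and ``e_ij`` the eligibility trace: the
score-function (likelihood-ratio) gradient of the action cells' spike
emission with respect to the weights, accumulated over the trial::

    e_ij = (1/delta_u) * sum_t (Y_i(t) - rho_i(t) * dt) * eps_ij(t)

``Y_i`` is the postsynaptic spike train, ``rho_i * dt`` its expectation per
bin, and ``eps_ij`` the postsynaptic-potential trace of presynaptic cell
``j`` — a superposition of causal ``exp(-t/tau_m)`` kernels over its spikes,
truncated at postsynaptic cell ``i``'s most recent spike.  The truncation
mirrors the simulator's hard post-spike reset (which erases the integrated
PSPs), making ``e`` the exact derivative of the trial's Bernoulli spiking
log-likelihood up to terms of order ``dt``.  Synapses that were recently
active when the cell fired more (less) than expected gain positive
(negative) eligibility; reward above baseline then consolidates it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .action import ActionCellParams

__all__ = [
    "LearningParams",
    "psp_kernel",
    "psp_traces",
    "compute_eligibility",
    "update_weights",
]


@dataclass(frozen=True)
class LearningParams:
    """Learning rate, reward baseline and additive synaptic noise bound."""

    eta: float = 4.0
    baseline_b: float = 0.4
    noise_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.noise_eps < 0:
            raise ValueError("noise_eps must be >= 0")


def psp_kernel(t_since_spike, tau_m: float):
    """Causal exponential PSP time course: ``exp(-t/tau_m)`` for t >= 0, else 0."""
    if not (tau_m > 0):
        raise ValueError("tau_m must be > 0")
    t = np.asarray(t_since_spike, dtype=float)
    out = np.where(t >= 0, np.exp(-np.clip(t, 0.0, None) / tau_m), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def psp_traces(place_raster: np.ndarray, tau_m: float, dt: float) -> np.ndarray:
    """Superposed PSP traces, one row per presynaptic cell, ``(m, t_steps)``.

    Entry ``(j, t)`` is ``sum_f exp(-(t - t_f) * dt / tau_m)`` over spikes
    of cell ``j`` at bins ``t_f <= t`` — computed by the equivalent
    recursion ``trace <- trace * exp(-dt/tau_m) + spike``.  The decay factor
    matches the simulator's exact leak integration, so the trace at bin
    ``t`` is precisely the derivative of the membrane potential with respect
    to the synaptic weight (absent postsynaptic resets).
    """
    if dt <= 0 or tau_m <= 0:
        raise ValueError("dt and tau_m must be > 0")
    x = np.asarray(place_raster, dtype=float)
    m, t_steps = x.shape
    decay = np.exp(-dt / tau_m)
    traces = np.empty_like(x)
    acc = np.zeros(m)
    for t in range(t_steps):
        acc = acc * decay + x[:, t]
        traces[:, t] = acc
    return traces


def compute_eligibility(
    action_raster: np.ndarray,
    rho_trace: np.ndarray,
    place_raster: np.ndarray,
    params: ActionCellParams,
    dt: float,
) -> np.ndarray:
    """Per-synapse eligibility matrix ``(n, m)`` for one trial.

    Implements the score-function accumulation with reset-aware PSP traces:
    a presynaptic spike's contribution to synapse ``(i, j)`` is erased once
    cell ``i`` fires (the hard reset wipes the integrated PSP), exactly as
    in the simulated membrane.  Organised as two O(n*t) recursions plus one
    (n, t) x (t, m) matrix product:

    - ``a_i(t) = Y_i(t) - min(rho_i(t) dt, 1)`` is the spike innovation;
    - the full traces ``eps_j(t)`` come from :func:`psp_traces`;
    - the truncation correction subtracts, for each postsynaptic spike at
      bin ``s``, the trace carried across it, accumulated backwards as
      ``p_i(t) = a_i(t) + decay * p_i(t+1) * (1 - Y_i(t))``.
    """
    y = np.asarray(action_raster, dtype=float)
    rho = np.asarray(rho_trace, dtype=float)
    x = np.asarray(place_raster)
    if y.shape != rho.shape or y.shape[1] != x.shape[1]:
        raise ValueError("inconsistent raster shapes")
    n, t_steps = y.shape
    decay = np.exp(-dt / params.tau_m)

    a = y - np.minimum(rho * dt, 1.0)
    eps = psp_traces(x, params.tau_m, dt)

    # Backward pass: p[:, t] = a[:, t] + decay * p[:, t+1] * (1 - Y[:, t]);
    # the carried-over trace erased by a spike at bin s is eps(s) * decay**(t-s)
    # for t in (s, next spike], so its total weight is decay * p[:, s+1].
    p = np.zeros((n, t_steps))
    nxt = np.zeros(n)
    for t in range(t_steps - 1, -1, -1):
        cur = a[:, t] + decay * nxt * (1.0 - y[:, t])
        p[:, t] = cur
        nxt = cur
    corr = np.zeros_like(a)
    if t_steps > 1:
        corr[:, :-1] = y[:, :-1] * decay * p[:, 1:]

    return ((a - corr) @ eps.T) / params.delta_u


def update_weights(
    w_ff: np.ndarray,
    reward: float,
    elig: np.ndarray,
    params: LearningParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply the end-of-trial policy-gradient update; returns a new matrix.

    ``xi`` is i.i.d. uniform on ``[0, noise_eps]`` per synapse (identically
    zero when ``noise_eps == 0``) — an additive, positively biased
    perturbation of every weight.
    """
    if elig.shape != w_ff.shape:
        raise ValueError("eligibility and weight shapes differ")
    w = w_ff + params.eta * (reward - params.baseline_b) * elig
    if params.noise_eps > 0:
        if rng is None:
            raise ValueError("rng required when noise_eps > 0")
        w = w + rng.uniform(0.0, params.noise_eps, size=w_ff.shape)
    return w
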