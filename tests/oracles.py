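"""Independent numerical oracles used by the test suite.

These deliberately re-derive quantities through routes different from the
package implementation (direct recursions, finite differences, closed-form
integrals) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from spikering.action import ActionCellParams


def trial_loglikelihood(w, place, action, params: ActionCellParams, dt: float) -> float:
    """Bernoulli log-likelihood of a frozen action spike train.

    Replays the membrane recursion (exact leak integration, same-bin
    feedforward spikes, hard reset at the frozen postsynaptic spike bins)
    for weight matrix ``w`` and scores each bin as Bernoulli(min(rho*dt,1)).
    Plain scalar re-implementation, independent of the package's vectorised
    eligibility code path.
    """
    n, t_steps = action.shape
    u = np.full(n, params.u_rest)
    decay = np.exp(-dt / params.tau_m)
    ll = 0.0
    for t in range(t_steps):
        u = params.u_rest + (u - params.u_rest) * decay + w @ place[:, t]
        rho = params.rho0 * np.exp((u - params.u_theta) / params.delta_u)
        p = np.clip(rho * dt, 1e-300, 1.0 - 1e-12)
        y = action[:, t]
        ll += float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        u[y == 1] = params.u_reset
    return ll


def fd_loglik_gradient(w, place, action, params: ActionCellParams, dt: float, h: float = 1e-5):
    """Central finite difference of the frozen-train log-likelihood w.r.t.
    every feedforward weight, ``(n, m)``.

    Perturbing ``w[i, j]`` only changes cell ``i``'s membrane path, so all
    ``m x 2`` perturbed paths of a cell are integrated simultaneously:
    the recursion runs on an ``(n, m, 2)`` tensor of potentials.
    """
    place = np.asarray(place, dtype=float)
    action = np.asarray(action, dtype=float)
    n, t_steps = action.shape
    m = place.shape[0]
    decay = np.exp(-dt / params.tau_m)
    signs = np.array([h, -h])

    base_drive = w @ place  # (n, t)
    u = np.full((n, m, 2), params.u_rest)
    ll = np.zeros((n, m, 2))
    for t in range(t_steps):
        # perturbed drive: base + (+-h) * x_j(t) on the (j, +-) slot
        u = params.u_rest + (u - params.u_rest) * decay
        u += base_drive[:, t][:, None, None]
        u += place[:, t][None, :, None] * signs[None, None, :]
        rho = params.rho0 * np.exp((u - params.u_theta) / params.delta_u)
        p = np.clip(rho * dt, 1e-300, 1.0 - 1e-12)
        y = action[:, t][:, None, None]
        ll += y * np.log(p) + (1 - y) * np.log1p(-p)
        fired = action[:, t] == 1
        u[fired] = params.u_reset
    return (ll[..., 0] - ll[..., 1]) / (2 * h)


def chance_reward_closed_form(sigma_r: float) -> float:
    """Expected Gaussian reward when the decision is uniform on the circle
    and independent of the target: E[exp(-d^2/(2 s^2))] with d the wrapped
    distance of two independent uniform angles (density 1/pi on [0, pi])."""
    val, _ = integrate.quad(lambda d: np.exp(-d * d / (2 * sigma_r**2)) / np.pi, 0.0, np.pi)
    return float(val)
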