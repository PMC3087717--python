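"""The full simulated-animat protocol: trials, blocks, ensembles, scenarios.

A *trial*: the animat is placed at a uniformly random angle (which is also
the maximally rewarded "correct" direction), the place layer encodes the
location as Poisson spike trains for ``t_steps`` bins, the action layer is
simulated from rest, the population vector of the action spikes gives the
decision angle, and the Gaussian reward of the target/decision distance is
delivered.  During *learning* trials the feedforward weights receive the
policy-gradient update at the trial end; *analysis* trials leave them
untouched and only measure performance.

An *experiment*: every animat of an independent ensemble starts from zero
feedforward weights, is evaluated over ``analysis_trials`` trials (block 0,
before any learning), and then alternates blocks of ``trials_per_block``
learning trials with analysis evaluations.  Curves report the ensemble
mean and standard deviation per block.

Diagnostic *profiles* average the potential weight change of single trials
at zero weights, summed over the place index and cyclically shifted so the
trial's target sits at the centre bin — the numerically estimated gradient
(or raw eligibility) as a function of action-cell offset from the target.

Randomness: every animat owns independent child streams (targets, spikes,
synaptic noise) spawned deterministically from the master seed, so results
are bit-reproducible and animats are independent of ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .action import ActionCellParams, LateralParams, mexican_hat_weights, simulate_action_layer
from .geometry import TWO_PI, RewardParams, RingLayout, gaussian_reward, normalized_error
from .place import PlaceCellParams, calibrate_nu_max, place_rates, sample_poisson_raster
from .plasticity import LearningParams, compute_eligibility, update_weights
from .readout import DegenerateDecisionError, mean_activity, population_vector_decision

__all__ = [
    "ExperimentConfig",
    "NetworkState",
    "TrialResult",
    "LearningCurve",
    "Profile",
    "AnimatStreams",
    "run_trial",
    "run_learning_experiment",
    "gradient_profile",
    "eligibility_profile",
    "run_scenario",
    "trials_to_reward",
    "SCENARIOS",
    "WEAK_LATERAL_SCALE",
    "STRONG_LATERAL_SCALE",
    "LATERAL_ETA",
    "LATERAL_BASELINE",
    "SYNAPTIC_NOISE_EPS",
]

# Lateral-strength working points (dimensionless w_scale of the Mexican hat).
# The weak value is the smallest (in round numbers) at which the undriven
# action layer reliably forms a pronounced activity bump; the strong value is
# far beyond it, where the bump dynamics dominate everything else.
WEAK_LATERAL_SCALE = 120.0
STRONG_LATERAL_SCALE = 320.0

# Reward widths (rad) for the reward-shape scenario.
WIDE_REWARD_SIGMA = 0.5
NARROW_REWARD_SIGMA = 0.15

# Receptive-field steepness for the overlap scenario (lowering beta below
# its default widens the place fields and increases their overlap).
HIGH_OVERLAP_BETA = 1.0

# Jointly optimised learning parameters of the bump-forming (lateral)
# systems; the non-lateral defaults are the ExperimentConfig values.  Each
# architecture gets its own optimum, as the learning parameters were tuned
# per system.
LATERAL_ETA = 16.0
LATERAL_BASELINE = 0.3

# Uniform synaptic-noise bound for the additive-noise scenario.
SYNAPTIC_NOISE_EPS = 3e-3


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one experiment (flat, file-friendly fields)."""

    n_place: int = 256
    n_action: int = 256
    # place tuning
    beta: float = 2.0
    nu_max: float = 180.0
    input_rate_hz: float | None = 180.0  # if set, calibrates nu_max to this summed rate
    # integration
    dt: float = 1e-3  # s
    t_steps: int = 128
    # action-cell membrane / escape noise
    tau_m: float = 0.020
    u_rest: float = -70.0
    u_theta: float = -60.0
    delta_u: float = 4.0
    rho0: float = 60.0
    u_reset: float = -75.0
    # lateral connectivity
    w_scale: float = 0.0
    w_e: float = 5.0
    w_i: float = 1.5
    sigma_lat: float = 0.5
    # reward
    sigma_r: float = WIDE_REWARD_SIGMA
    # learning
    eta: float = 4.0
    baseline_b: float = 0.4
    noise_eps: float = 0.0
    # protocol
    n_animats: int = 16
    trials_per_block: int = 512
    analysis_trials: int = 128
    n_blocks: int = 5
    master_seed: int = 0
    scenario: str = "default"

    def __post_init__(self) -> None:
        for name in ("n_place", "n_action", "t_steps", "n_animats", "trials_per_block", "analysis_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        # eagerly build the parameter bundles so invalid values fail here,
        # with the configuration, rather than mid-run
        self.action_params, self.lateral_params, self.reward_params, self.learning_params
        PlaceCellParams(m=self.n_place, beta=self.beta, nu_max=self.nu_max)

    # ---- derived parameter bundles -------------------------------------
    @property
    def place_params(self) -> PlaceCellParams:
        p = PlaceCellParams(m=self.n_place, beta=self.beta, nu_max=self.nu_max)
        if self.input_rate_hz is not None:
            p = calibrate_nu_max(p, self.input_rate_hz)
        return p

    @property
    def action_params(self) -> ActionCellParams:
        return ActionCellParams(
            n=self.n_action, tau_m=self.tau_m, u_rest=self.u_rest, u_theta=self.u_theta,
            delta_u=self.delta_u, rho0=self.rho0, u_reset=self.u_reset,
        )

    @property
    def lateral_params(self) -> LateralParams:
        return LateralParams(w_scale=self.w_scale, w_e=self.w_e, w_i=self.w_i, sigma_lat=self.sigma_lat)

    @property
    def reward_params(self) -> RewardParams:
        return RewardParams(sigma_r=self.sigma_r)

    @property
    def learning_params(self) -> LearningParams:
        return LearningParams(eta=self.eta, baseline_b=self.baseline_b, noise_eps=self.noise_eps)

    @property
    def t_window(self) -> float:
        return self.t_steps * self.dt


@dataclass
class NetworkState:
    """Mutable per-animat state: weights and cached structures."""

    w_ff: np.ndarray
    w_lat: np.ndarray | None
    place_params: PlaceCellParams
    action_params: ActionCellParams
    lateral_params: LateralParams
    degenerate_trials: int = 0

    @classmethod
    def initial(cls, config: ExperimentConfig) -> "NetworkState":
        """Zero feedforward weights; fixed lateral matrix built once."""
        ap = config.action_params
        lp = config.lateral_params
        w_lat = mexican_hat_weights(lp, ap.layout) if lp.w_scale > 0 else None
        return cls(
            w_ff=np.zeros((config.n_action, config.n_place)),
            w_lat=w_lat,
            place_params=config.place_params,
            action_params=ap,
            lateral_params=lp,
        )


@dataclass(frozen=True)
class TrialResult:
    target: float
    decision: float | None  # None when no action cell fired
    reward: float
    error: float
    total_spikes: int

    @property
    def degenerate(self) -> bool:
        return self.decision is None


@dataclass
class AnimatStreams:
    """Independent per-purpose RNG streams of one animat."""

    targets: np.random.Generator
    spikes: np.random.Generator
    noise: np.random.Generator

    @classmethod
    def from_seed_sequence(cls, ss: np.random.SeedSequence) -> "AnimatStreams":
        t, s, n = ss.spawn(3)
        return cls(
            targets=np.random.default_rng(t),
            spikes=np.random.default_rng(s),
            noise=np.random.default_rng(n),
        )


def animat_streams(master_seed: int, n_animats: int) -> list[AnimatStreams]:
    """Spawn one independent stream bundle per animat from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n_animats)
    return [AnimatStreams.from_seed_sequence(c) for c in children]


# --------------------------------------------------------------------------
# trial and experiment loops
# --------------------------------------------------------------------------

def _simulate_trial(
    state: NetworkState, config: ExperimentConfig, target: float, streams: AnimatStreams
):
    """Encode, simulate, decode and reward one trial; no weight change."""
    rates = place_rates(target, state.place_params)
    place_raster = sample_poisson_raster(rates, config.t_steps, config.dt, streams.spikes)
    action_raster, rho_trace, _ = simulate_action_layer(
        place_raster, state.w_ff, state.lateral_params, state.action_params,
        config.dt, streams.spikes, w_lat=state.w_lat,
    )
    counts = action_raster.sum(axis=1)
    total = int(counts.sum())
    if total == 0:
        return place_raster, action_raster, rho_trace, None, 0
    rates_out = mean_activity(action_raster, config.t_window)
    try:
        decision = population_vector_decision(rates_out, state.action_params.layout, total)
    except DegenerateDecisionError:
        # perfectly balanced votes: no usable decision either
        return place_raster, action_raster, rho_trace, None, total
    return place_raster, action_raster, rho_trace, decision.angle, total


def run_trial(
    state: NetworkState,
    config: ExperimentConfig,
    learning: bool,
    streams: AnimatStreams,
) -> TrialResult:
    """One complete trial; mutates ``state.w_ff`` only when ``learning``.

    The target angle (drawn uniformly on the circle) doubles as the
    animat's location: the correct, maximally rewarded direction is the one
    the place layer encodes.  Degenerate trials (no action spike) score
    reward 0 and error 1 and trigger no weight update.
    """
    target = float(streams.targets.uniform(0.0, TWO_PI))
    place_raster, action_raster, rho_trace, decision, total = _simulate_trial(
        state, config, target, streams
    )
    if decision is None:
        state.degenerate_trials += 1
        if learning and config.learning_params.noise_eps > 0:
            # crosstalk noise perturbs the weights regardless of the vote
            state.w_ff = update_weights(
                state.w_ff, 0.0, np.zeros_like(state.w_ff),
                replace(config.learning_params, eta=0.0), streams.noise,
            )
        return TrialResult(target=target, decision=None, reward=0.0, error=1.0, total_spikes=0)

    reward = gaussian_reward(target, decision, config.reward_params)
    error = normalized_error(target, decision)
    if learning:
        elig = compute_eligibility(
            action_raster, rho_trace, place_raster, state.action_params, config.dt
        )
        state.w_ff = update_weights(
            state.w_ff, reward, elig, config.learning_params, streams.noise
        )
    return TrialResult(target=target, decision=decision, reward=reward, error=error, total_spikes=total)


@dataclass
class LearningCurve:
    """Per-block ensemble statistics of the analysis-phase performance.

    Index 0 is the pre-learning evaluation; there are ``n_blocks + 1``
    entries in total.  ``reward_per_animat`` / ``error_per_animat`` hold the
    underlying ``(n_animats, n_blocks + 1)`` matrices.
    """

    blocks: np.ndarray
    reward_mean: np.ndarray
    reward_std: np.ndarray
    error_mean: np.ndarray
    error_std: np.ndarray
    reward_per_animat: np.ndarray
    error_per_animat: np.ndarray
    trials_per_block: int
    degenerate_trials: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per animat per block, plus aggregates."""
        n_animats, n_points = self.reward_per_animat.shape
        rows = []
        for a in range(n_animats):
            for b in range(n_points):
                rows.append(
                    dict(block=b, animat=a, kind="animat",
                         reward=self.reward_per_animat[a, b],
                         error=self.error_per_animat[a, b])
                )
        for b in range(n_points):
            rows.append(
                dict(block=b, animat=-1, kind="ensemble_mean",
                     reward=self.reward_mean[b], error=self.error_mean[b])
            )
            rows.append(
                dict(block=b, animat=-1, kind="ensemble_std",
                     reward=self.reward_std[b], error=self.error_std[b])
            )
        return pd.DataFrame(rows)


def _analysis_phase(state, config, streams) -> tuple[float, float]:
    """Mean reward and error over the frozen-weight analysis trials."""
    rewards = np.empty(config.analysis_trials)
    errors = np.empty(config.analysis_trials)
    for k in range(config.analysis_trials):
        res = run_trial(state, config, learning=False, streams=streams)
        rewards[k] = res.reward
        errors[k] = res.error
    return float(rewards.mean()), float(errors.mean())


def run_learning_experiment(
    config: ExperimentConfig,
    progress: Callable[[int, int, float], None] | None = None,
) -> LearningCurve:
    """Run the block protocol for the whole animat ensemble.

    ``progress(animat, block, mean_reward)`` is invoked after every
    analysis evaluation when given (used by the CLI for logging).
    """
    n_points = config.n_blocks + 1
    reward = np.empty((config.n_animats, n_points))
    error = np.empty((config.n_animats, n_points))
    degenerate = 0
    for a, streams in enumerate(animat_streams(config.master_seed, config.n_animats)):
        state = NetworkState.initial(config)
        reward[a, 0], error[a, 0] = _analysis_phase(state, config, streams)
        if progress:
            progress(a, 0, reward[a, 0])
        for b in range(1, n_points):
            for _ in range(config.trials_per_block):
                run_trial(state, config, learning=True, streams=streams)
            reward[a, b], error[a, b] = _analysis_phase(state, config, streams)
            if progress:
                progress(a, b, reward[a, b])
        degenerate += state.degenerate_trials
    return LearningCurve(
        blocks=np.arange(n_points),
        reward_mean=reward.mean(axis=0),
        reward_std=reward.std(axis=0, ddof=1) if config.n_animats > 1 else np.zeros(n_points),
        error_mean=error.mean(axis=0),
        error_std=error.std(axis=0, ddof=1) if config.n_animats > 1 else np.zeros(n_points),
        reward_per_animat=reward,
        error_per_animat=error,
        trials_per_block=config.trials_per_block,
        degenerate_trials=degenerate,
    )


def trials_to_reward(curve: LearningCurve, threshold: float = 0.7) -> float:
    """Cumulative learning trials until the ensemble mean reward first
    reaches ``threshold``, linearly interpolated between block evaluations.

    Returns ``inf`` if the threshold is never reached.
    """
    r = curve.reward_mean
    t = curve.blocks * curve.trials_per_block
    for b in range(len(r)):
        if r[b] >= threshold:
            if b == 0:
                return 0.0
            frac = (threshold - r[b - 1]) / (r[b] - r[b - 1])
            return float(t[b - 1] + frac * curve.trials_per_block)
    return float("inf")


# --------------------------------------------------------------------------
# diagnostic profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Profile:
    """Shift-aligned trial-averaged curve over action-cell index offset.

    ``values[k]`` is the average at offset ``k - n//2`` cells from the
    target direction; the centre bin (index ``n//2``) is the target itself.
    """

    values: np.ndarray
    n_samples: int

    @property
    def centre_index(self) -> int:
        return len(self.values) // 2

    @property
    def peak(self) -> float:
        return float(self.values[self.centre_index])

    def to_frame(self) -> pd.DataFrame:
        n = len(self.values)
        return pd.DataFrame(
            {"offset": np.arange(n) - n // 2, "value": self.values, "n_samples": self.n_samples}
        )


def _aligned_average(
    config: ExperimentConfig,
    n_samples: int,
    streams: AnimatStreams,
    per_trial_weight: bool,
    noise_into_weights: bool,
) -> Profile:
    """Common shift-and-average machinery behind both profile estimators.

    ``per_trial_weight`` multiplies each trial's eligibility by
    ``eta * (R - b)`` (the potential weight change of the learning rule) and
    aligns on the target angle, at which the averaged gradient peaks.  With
    ``per_trial_weight`` False the raw eligibility is averaged; since its
    target-aligned expectation vanishes (score-function identity), each
    trial is instead aligned on the maximum of its summed eligibility, which
    exposes the *shape and magnitude* of the per-trial gradient information.
    ``noise_into_weights`` accumulates the uniform synaptic noise into the
    feedforward weights trial by trial, exactly as the learning-phase
    updates would, so the noise perturbs the spiking dynamics of later
    sample trials.
    """
    state = NetworkState.initial(config)
    n = config.n_action
    layout: RingLayout = state.action_params.layout
    acc = np.zeros(n)
    lp = config.learning_params
    for _ in range(n_samples):
        target = float(streams.targets.uniform(0.0, TWO_PI))
        place_raster, action_raster, rho_trace, decision, total = _simulate_trial(
            state, config, target, streams
        )
        if decision is None:
            elig_sum = np.zeros(n)
            reward = 0.0
        else:
            elig = compute_eligibility(
                action_raster, rho_trace, place_raster, state.action_params, config.dt
            )
            elig_sum = elig.sum(axis=1)
            reward = gaussian_reward(target, decision, config.reward_params)
        if per_trial_weight:
            contrib = lp.eta * (reward - lp.baseline_b) * elig_sum
            k = int(np.round(target / layout.spacing)) % n
        else:
            contrib = elig_sum
            k = int(np.argmax(elig_sum))
        acc += np.roll(contrib, n // 2 - k)
        if noise_into_weights and lp.noise_eps > 0:
            state.w_ff = state.w_ff + streams.noise.uniform(0.0, lp.noise_eps, size=state.w_ff.shape)
    return Profile(values=acc / n_samples, n_samples=n_samples)


def gradient_profile(
    config: ExperimentConfig, n_samples: int = 2048, streams: AnimatStreams | None = None
) -> Profile:
    """Numerical weight-gradient profile at zero weights (before learning).

    Averages the potential update ``eta * (R - b) * e`` (no noise), summed
    over the place index and shifted so the target maps to the centre bin.
    """
    streams = streams or animat_streams(config.master_seed, 1)[0]
    clean = replace(config, noise_eps=0.0)
    return _aligned_average(clean, n_samples, streams, per_trial_weight=True, noise_into_weights=False)


def eligibility_profile(
    config: ExperimentConfig,
    with_noise: bool,
    n_samples: int = 2048,
    shared_seed: int | None = None,
) -> Profile:
    """Aligned average eligibility at zero weights, with or without noise.

    With noise, the uniform positively-biased synaptic noise is drawn into
    the weights after every sample trial (as the learning rule would apply
    it), so its accumulated effect perturbs the spiking dynamics; spike and
    target streams depend only on ``shared_seed``, so a with/without pair at
    the same seed sees identical inputs and isolates the noise effect.
    """
    seed = config.master_seed if shared_seed is None else shared_seed
    streams = animat_streams(seed, 1)[0]
    return _aligned_average(
        config, n_samples, streams, per_trial_weight=False,
        noise_into_weights=with_noise and config.noise_eps > 0,
    )


# --------------------------------------------------------------------------
# the four parametric scenarios
# --------------------------------------------------------------------------


def _with_scale(config: ExperimentConfig, scale: float, **kw) -> ExperimentConfig:
    """Apply a lateral working point, switching to the bump systems' jointly
    optimised learning rate when lateral connections are present."""
    if scale > 0:
        kw.setdefault("eta", LATERAL_ETA)
        kw.setdefault("baseline_b", LATERAL_BASELINE)
    return replace(config, w_scale=scale, **kw)


def _scenario_lateral_strength(config: ExperimentConfig, n_profile_samples: int):
    out = {}
    for name, scale in [("no_lateral", 0.0), ("weak_lateral", WEAK_LATERAL_SCALE),
                        ("strong_lateral", STRONG_LATERAL_SCALE)]:
        c = _with_scale(config, scale, scenario="lateral_strength")
        curve = run_learning_experiment(c)
        prof = gradient_profile(c, n_profile_samples)
        out[f"curve_{name}"] = curve.to_frame()
        out[f"profile_{name}"] = prof.to_frame()
    return out


def _scenario_reward_width(config: ExperimentConfig, n_profile_samples: int):
    out = {}
    for rname, sigma in [("wide", WIDE_REWARD_SIGMA), ("narrow", NARROW_REWARD_SIGMA)]:
        for lname, scale in [("no_lateral", 0.0), ("lateral", WEAK_LATERAL_SCALE)]:
            c = _with_scale(config, scale, sigma_r=sigma, scenario="reward_width")
            curve = run_learning_experiment(c)
            prof = gradient_profile(c, n_profile_samples)
            out[f"curve_{rname}_{lname}"] = curve.to_frame()
            out[f"profile_{rname}_{lname}"] = prof.to_frame()
    return out


def _scenario_overlap(config: ExperimentConfig, n_profile_samples: int):
    out = {}
    n_blocks = max(config.n_blocks, 9)
    for lname, scale in [("no_lateral", 0.0), ("lateral", WEAK_LATERAL_SCALE)]:
        c = _with_scale(config, scale, beta=HIGH_OVERLAP_BETA, n_blocks=n_blocks,
                        scenario="overlap")
        curve = run_learning_experiment(c)
        prof = gradient_profile(c, n_profile_samples)
        out[f"curve_overlap_{lname}"] = curve.to_frame()
        out[f"profile_overlap_{lname}"] = prof.to_frame()
        ref = _with_scale(config, scale, n_blocks=n_blocks, scenario="overlap")
        out[f"curve_reference_{lname}"] = run_learning_experiment(ref).to_frame()
    return out


def _scenario_synaptic_noise(config: ExperimentConfig, n_profile_samples: int):
    out = {}
    n_blocks = max(config.n_blocks, 9)
    eps = config.noise_eps if config.noise_eps > 0 else SYNAPTIC_NOISE_EPS
    for lname, scale in [("no_lateral", 0.0), ("lateral", WEAK_LATERAL_SCALE)]:
        noisy = _with_scale(config, scale, noise_eps=eps, n_blocks=n_blocks,
                            scenario="synaptic_noise")
        clean = replace(noisy, noise_eps=0.0)
        out[f"curve_noisy_{lname}"] = run_learning_experiment(noisy).to_frame()
        out[f"curve_clean_{lname}"] = run_learning_experiment(clean).to_frame()
        out[f"elig_profile_clean_{lname}"] = eligibility_profile(
            clean, with_noise=False, n_samples=n_profile_samples
        ).to_frame()
        out[f"elig_profile_noisy_{lname}"] = eligibility_profile(
            noisy, with_noise=True, n_samples=n_profile_samples
        ).to_frame()
    return out


SCENARIOS: dict[str, Callable] = {
    "lateral_strength": _scenario_lateral_strength,
    "reward_width": _scenario_reward_width,
    "overlap": _scenario_overlap,
    "synaptic_noise": _scenario_synaptic_noise,
}


def run_scenario(
    name: str, config: ExperimentConfig, n_profile_samples: int = 2048
) -> dict[str, pd.DataFrame]:
    """Run one of the four parametric scenarios; returns named result tables."""
    try:
        fn = SCENARIOS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}") from None
    return fn(config, n_profile_samples)
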