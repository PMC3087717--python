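# Methods

`spikering` simulates a two-layer spiking network that learns a circular
association task — a minimal, self-contained stand-in for navigation — with a
reward-modulated policy-gradient rule, and reproduces the experimental
protocol built around it (learning/analysis blocks, animat ensembles, the
four parametric scenarios, and the gradient/eligibility diagnostic
profiles).  This note records the model, the parameter choices and their
rationale, the numerical decisions, and what the simulations do and do not
establish.

## Task

An *animat* lives on a circle.  Each trial it is placed at a uniformly
random angle, which is simultaneously the "correct" (maximally rewarded)
direction Y\*.  The network observes the location through the input layer,
emits a decision angle Ŷ through the output layer, and receives the reward

    R = exp(−d(Y*, Ŷ)² / (2 σ_R²)),

where d is the wrapped (shorter-arc) angular distance and σ_R the reward
width.  The reward is deliberately unnormalised: its peak is 1, so "70 % of
the maximum reward" means R = 0.7.  Because changing σ_R changes the total
reward mass, scenario comparisons across reward widths use instead the
normalised error d(Y\*, Ŷ)/π ∈ [0, 1].

## Network

**Place cells (input).**  M = 256 Poisson units with preferred angles θ_j
equally spaced on the circle.  The rate of cell j for location x is

    ν_j = ν_max · σ( β (1/2 − c · d(θ_j, x)) ),   c = M / 2π,

with σ the logistic function.  The scale factor c pins the half-maximum to
the midpoint between neighbouring cells for any M; β sets how steeply the
rate falls beyond that, i.e. the receptive-field overlap.  Rates are
constant within a trial; spikes are independent Bernoulli draws per 1 ms bin
with probability ν·dt (clipped at 1).  ν_max is calibrated so that the
summed population rate is 180 Hz (the calibration averages over one grid
spacing of locations; the "input = 180 Hz" budget is interpreted as the
summed drive — the peak-single-cell interpretation is available by setting
`input_rate_hz: null` and `nu_max` directly).

**Action cells (output).**  N = 256 leaky integrate-and-fire units with
exponential escape noise (a special case of the spike response model).
Membrane potentials decay toward u_rest with time constant τ_m; each
presynaptic spike adds its synaptic weight instantaneously.  The leak is
integrated exactly over each bin (u ← u_rest + (u − u_rest)·e^(−dt/τ_m) —
the closed-form solution of the linear leak, preferred over forward Euler
because it removes the O(dt) discretisation bias and makes the plasticity
rule exactly consistent with the simulated likelihood).  A cell fires in a
bin with probability min(ρ·dt, 1), ρ = ρ₀·exp((u − u_θ)/Δu), and its
potential is then reset to u_reset below rest (hyperpolarising spike
afterpotential).  Feedforward spikes act within their bin; lateral spikes
act with a one-bin delay.

**Lateral connectivity (optional).**  A fixed circulant Mexican-hat matrix
over the output ring: w_ik = (w_scale/N)(w_E·exp(−d(φ_i,φ_k)²/(2σ_lat²)) −
w_I) — short-range excitation over uniform inhibition.  With w_scale large
enough, the undriven layer spontaneously forms a localised activity bump; the
bump position then *is* the network's decision ("non-democratic" readout).
With w_scale = 0 every spike votes independently ("democratic").

**Readout.**  Both architectures are decoded the same way, by the
population vector: Ŷ = arg Σ_i r̄_i·e^{iφ_i} with r̄_i the trial-average
rate of cell i.  The decode is scale invariant, rotation equivariant, and —
in the bump regime — lands within one cell spacing of the activity peak.
Trials with no output spike (or a perfectly balanced vote) have no decision;
they score reward 0 and error 1 and trigger no weight update.  At the
default working point they essentially never occur (the undriven network
emits ≈160 spikes per trial).

## Plasticity

Feedforward weights start at zero and are updated once per trial:

    w_ij ← w_ij + η (R − b) e_ij + ξ_ij,

with learning rate η, constant reward baseline b, optional crosstalk noise
ξ_ij ~ U[0, ε] (ε = 0 by default), and the eligibility trace

    e_ij = (1/Δu) Σ_t (Y_i(t) − ρ_i(t)·dt) · ε̃_ij(t),

the score-function (likelihood-ratio) gradient of the output layer's spike
train probability with respect to w_ij.  ε̃_ij is the superposed exponential
PSP trace of place cell j, truncated at action cell i's most recent spike:
because the hard reset erases the integrated PSPs, the exact derivative of
the trial's Bernoulli log-likelihood truncates there too (the renewal
convention of spike-response-model likelihoods).  The implementation is
validated against central finite differences of that log-likelihood with
frozen spike trains; the residual is O(dt) (the (1 − p) factors dropped from
the per-bin weighting) and shrinks when dt is halved.

The computation is organised as two O(N·T) scans plus one (N×T)·(T×M)
matrix product per trial, which keeps a full 256×256×128 learning trial
around 10 ms on one CPU core.

## Parameters

| parameter | value | why |
|---|---|---|
| τ_m | 20 ms | standard cortical LIF value |
| u_rest / u_θ / Δu | −70 / −60 / 4 mV | literature-style working point; gives ρ(u_rest) ≈ 4.9 Hz, i.e. sparse spontaneous activity (≈160 spikes per 128 ms trial across the ring) and visible pre-learning rasters |
| ρ₀ | 60 Hz | escape rate at threshold |
| u_reset | −75 mV | 5 mV hyperpolarisation below rest |
| dt, T | 1 ms, 128 steps | trial window 128 ms |
| M = N | 256 | ring sizes |
| β | 2.0 | receptive-field overlap; part of the joint optimisation below |
| input rate | 180 Hz summed | calibration target for ν_max |
| σ_R | 0.5 rad (wide), 0.15 rad (narrow scenario) | wide: chance reward ≈ 0.2, well below the 0.7 learning criterion; narrow: sharpened credit assignment for the reward-shape scenario |
| w_E / w_I / σ_lat | 5 / 1.5 / 0.5 rad | Mexican hat with excitation radius ≈ 20 cells over uniform inhibition |
| w_scale | 0 / 120 (weak) / 320 (strong) | weak: smallest round value at which the undriven layer reliably forms a pronounced bump (circular resultant of spike angles ≈ 0.88); strong: far past ignition, bump dynamics dominate |
| η | 4 (no lateral), 16 (lateral) | per-architecture joint optimisation, below |
| b | 0.4 | reward baseline from the same optimisation |
| ε | 3×10⁻³ | additive-noise scenario; see below |
| ensemble | 16 animats × 512-trial blocks, 128 analysis trials | protocol defaults |

The learning parameters (η, b) and the overlap β were found by grid search,
separately for the lateral and non-lateral architectures, maximising the
analysis reward reached within five blocks — the same joint-optimisation
procedure the protocol prescribes.  The search is reproducible with the
`spikering sweep` command.  Two properties of the working point matter more
than the specific numbers: (i) spontaneous output activity must be sparse
enough that individual spikes carry reward correlation (the policy-gradient
signal), yet dense enough that the pre-learning population vector is defined
on every trial; (ii) the learning rate trades early speed against the
asymptotic noise floor of the weights — the per-architecture optima differ
by the ~4× difference in per-trial eligibility mass between bump and
background activity.

## Protocol and statistics

Each animat of an ensemble owns three independent RNG streams (targets,
spikes, synaptic noise) spawned from the master seed, so results are
bit-reproducible, animats are independent of ensemble size, and the
matched-seed noise comparison below is exact.  Performance is always
evaluated on separate analysis blocks (128 trials, learning disabled,
weights verified bit-identical), including a block-0 evaluation before any
learning.  Curves report mean ± s.d. across animats.  "Trials to 70 %" is
the cumulative learning-trial count at which the ensemble-mean analysis
reward first reaches 0.7, linearly interpolated between block evaluations.

**Diagnostic profiles.**  With weights still at zero, the potential update
η(R − b)e (the "numerical weight gradient") is summed over the place index,
cyclically shifted so the trial's target maps to the nearest action index at
the centre bin (ties toward the lower index), and averaged over 2,048
trials.  The eligibility variant averages e itself, leaving the reward
factor out; because the target-aligned expectation of e alone vanishes (the
score-function identity), each trial is instead aligned on the maximum of
its summed eligibility, which exposes the magnitude and shape of the
per-trial gradient information.  For the with-noise eligibility profile, the uniform noise is
drawn into the feedforward weights after every sample trial — exactly what
the learning-rule noise term does to the weights — so its accumulated effect
perturbs the spiking dynamics of subsequent trials; spike and target streams
are shared between the with/without pair, isolating the noise effect.
(Adding ξ only to the plotted quantity would merely offset the profile and
could not change its peak, so it could not expose the bump system's noise
sensitivity.)

**Additive-noise scenario.**  ε = 3×10⁻³ was chosen by the prescribed
search over ε: large enough that the accumulated positive bias (≈7 mV per
synapse over nine 512-trial learning blocks) measurably perturbs the bump
system's decisions, small enough that the democratic system — whose linear
readout cancels the common-mode drive — keeps learning.

## What the simulations show, and what they do not

The generator *is* the study: all inputs are synthetic by construction
(uniform targets, Poisson encoding), so the tests characterise the model
itself rather than any recorded data.  The reproduced phenomena are
qualitative and robust at this working point: the democratic system learns
fastest and its aligned gradient profile is largest; the pronounced-bump
system learns at roughly half the speed with a smaller profile; the
very-strong-bump system stays at chance with a near-flat profile; and the
bump system is disproportionately hurt by receptive-field overlap and by
positively biased synaptic noise.  The *quantitative* curves depend on the
jointly optimised parameters (as any policy-gradient result does) and on
the unread constants of the original study; they are not figure-exact.

Numerical/design notes:

- Exact exponential leak integration (not forward Euler); spike probability
  min(ρ·dt, 1); membranes reset to u_rest at every trial start.
- The eligibility uses the simulator's own decay factor and reset
  truncation, making it the exact discrete-likelihood gradient up to
  O(dt); the 1/Δu prefactor is absorbable into η.
- Degenerate (zero-spike) trials are scored conservatively (R = 0,
  error = 1, no update) and counted; they do not occur at the default
  working point.
- No weight bounds or decay are applied; runs at the default η are stable,
  and the CLI logs per-block rewards so divergence would be visible.
- Scaled-down problem sizes (fewer animats or smaller rings) are used in
  parts of the test suite; the headline experiment runs at full
  256×256×128 scale with ensembles of at least four animats.

## Known limitations

- One-dimensional ring geometry only; no 2-D navigation.
- Lateral weights are fixed (no lateral plasticity), with exactly one-bin
  delay; feedforward synapses are instantaneous-delta current injections.
- The Bernoulli-per-bin Poisson approximation slightly undercounts
  coincident spikes at rates approaching 1/dt.
- The baseline b is a constant, not an adaptive reward predictor.
- Parameter optima were located by a coarse grid, not the exhaustive
  GPU-scale search of the original study; other working points of
  comparable quality likely exist.
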