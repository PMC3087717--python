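# spikering

Spiking ring-network simulator for studying how a population's *decision
mechanism* shapes reward-driven learning.

## The problem

A simulated animal (an *animat*) lives on a circle.  On each trial it is
placed at a random angle and must "choose" a direction; choices close to the
correct direction — which equals its position — earn a Gaussian reward
R = exp(−d²/2σ_R²) of the wrapped angular error d.  The animat is a
two-layer spiking network:

- **Place cells** (input ring, Poisson): cell j fires at
  ν_j = ν_max σ(β(½ − c·d(θ_j, x))) for location x, peaking at its preferred
  angle θ_j and dropping to half-maximum midway to its neighbours.
- **Action cells** (output ring, leaky integrate-and-fire with exponential
  escape noise): spike with instantaneous rate ρ = ρ₀ e^{(u−u_θ)/Δu}, reset
  below rest after firing.  Optionally coupled by a fixed Mexican-hat
  lateral matrix (short-range excitation, long-range inhibition) that makes
  the layer form an activity **bump**.
- **Readout**: the population vector Ŷ = arg Σ_i r̄_i e^{iφ_i} of the
  output activity — a "democratic" vote when there are no lateral
  connections, a bump-position readout when there are.

Learning modifies only the feedforward weights, once per trial, by a
spike-based policy-gradient (REINFORCE-family) rule with eligibility traces:

    Δw_ij = η (R − b) · (1/Δu) Σ_t (Y_i(t) − ρ_i(t)dt) ε̃_ij(t)  [+ ξ_ij]

where ε̃ is the (reset-truncated) exponential PSP trace of place cell j,
b a constant reward baseline and ξ optional positively-biased uniform
synaptic noise.  The package reproduces the full experimental protocol:
blocks of 512 learning trials interleaved with frozen-weight analysis
blocks, ensembles of independent animats, the four parametric scenarios
(lateral strength, reward width, receptive-field overlap, synaptic noise)
and the shift-aligned gradient/eligibility diagnostic profiles.

The scientific punchline this toolkit lets you reproduce: *democratic*
population decisions learn the task faster and more robustly than bump
(*non-democratic*) decisions, which are disproportionately hurt by
receptive-field overlap and synaptic crosstalk noise.

## Worked example

```python
import spikering as sr

cfg = sr.ExperimentConfig(n_animats=4, n_blocks=5, master_seed=1)  # no lateral
curve = sr.run_learning_experiment(cfg)
print([float(round(r, 3)) for r in curve.reward_mean])
print("trials to 70%:", round(sr.trials_to_reward(curve, 0.7)))
```

prints

```
[0.201, 0.374, 0.576, 0.663, 0.721, 0.757]
trials to 70%: 1863
```

block 0 is the pre-learning evaluation (chance level ≈ 0.2 for the default
reward width σ_R = 0.5 rad); the ensemble-mean analysis reward passes 70 %
of the maximum within four 512-trial blocks.  The same experiment with the
bump-forming lateral coupling (`w_scale=120, eta=16, baseline_b=0.3`) needs
roughly twice as many trials, and with very strong coupling
(`w_scale=320`) it never leaves chance.

The same runs from the shell, with CSV tables and a reproducibility
manifest:

```bash
spikering run --seed 1 --animats 4 --blocks 5 --out-dir results/run
spikering scenario lateral_strength --seed 1 --out-dir results/lat
spikering profile --kind gradient --seed 1 --out-dir results/prof
spikering plot results/run/learning_curve.csv
```

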