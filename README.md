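# gridforage

Active-inference simulation of spatial foraging in a grid world: a discrete
(POMDP) agent that navigates toward preferred locations, epistemically
forages a novel patch by learning its contingencies, and exposes the
simulated neurophysiology of its belief updates — firing-rate rasters, local
field potentials, dopamine (precision) responses and theta-band dynamics.

It is written for computational-neuroscience and cognitive-modelling work
where one wants the full belief-updating machinery of discrete active
inference — not just the behaviour — in plain, inspectable scientific
Python.

## The model

The agent holds a generative model over a single hidden-state factor
(*location* on a 10×10 grid) with two outcome modalities: *where* (the
location, observed unambiguously through an identity likelihood) and *what*
(`reward` vs `null`, rewarded only at one location). The model comprises the
usual arrays — likelihood **A**, action-conditioned transitions **B** (up,
down, left, right, stay), log-preferences **C**, initial-state prior **D**
and policy habit prior **E** — with optional Dirichlet concentration
parameters *a*, *b* over **A** and **B**.

- **Perception** is a gradient descent on variational free energy: beliefs
  `s_π,τ = σ(v_π,τ)` are driven by a state prediction error combining
  forward, backward and likelihood messages (16 iterations per time step,
  each one recorded).
- **Planning** scores every depth-4 policy by expected free energy
  `G(π) = Σ_τ Σ_m [risk + ambiguity − novelty]`, where novelty is the
  Dirichlet information-gain bound `o·W·s`, `W = ½(1/a − 1/ā)`. The policy
  posterior is `Q(π) = σ(ln E − F_π − γ G_π)`; only the first action of the
  receding horizon is executed.
- **Precision** `γ = 1/β` over policies is revised at every new observation
  by iterating `β ← β_prior + (Q − Q₀)·G`; its piecewise trace is the
  simulated dopamine signal (tonic level, phasic bursts at step boundaries).
- **Learning** accumulates concentration parameters, `a ← a + η Σ_τ o_τ ⊗
  s_τ` (and analogously for executed transitions), so visited locations lose
  their novelty — the associative-plasticity account of map learning.

Under the 250 ms-per-movement convention, one belief-update cycle per step
is a 4 Hz rhythm, and the population activity shows the theta periodicity
reported in rodent foraging.

## Worked example

Navigate from the bottom-left corner (location 90) to a target at Manhattan
distance 8 (location 54) with a known map:

```python
import numpy as np
from gridforage import (GridGeometry, GridWorld, build_geocache_model,
                        run_navigation_trial, compute_ephys, spectral_peak_hz,
                        preference_ratio)

geom = GridGeometry(10, 10)
model = build_geocache_model(geom, target_location=54, start_location=90)
world = GridWorld(geom, true_location=90, reward_location=54)
record = run_navigation_trial(model, world, n_moves=10, seed=1)

print("preference ratio :", round(preference_ratio(model), 2))
print("trajectory       :", record.true_states)
print("first reward step:", record.first_reward_step())
ephys = compute_ephys(record)
print("units            :", ephys.n_units)
print("gamma per step   :", [round(g, 2) for g in record.gamma_per_step])
print("theta peak       :", spectral_peak_hz(ephys.lfp_mua, ephys.dt), "Hz")
```

prints

```
preference ratio : 20.09
trajectory       : [90, 91, 92, 93, 83, 73, 63, 53, 54, 54, 54]
first reward step: 8
units            : 1100
gamma per step   : [1.0, 1.42, 1.37, 1.3, 1.6, 6.88, 1.13, 1.08, 1.1, 1.23, 1.24]
theta peak       : 4.0 Hz
```

Reading the numbers: the utilities [3, 0] make the rewarding outcome about
20 (= e³) times more expected than null; the agent walks a shortest
(8-move) path and spends the final two steps sitting on the target, where it
first observes reward at step 8. The electrophysiology carries one unit per
(location, represented time point) pair — 100 × 11 = 1,100 units over 176
recorded iterations — and the precision γ jumps whenever an observation
eliminates competing plans (the large burst at step 5 is such an event); the
population activity peaks at 4 Hz, the theta rhythm implied by one update
cycle per 250 ms movement.

The same loop with `dirichlet_prior_scale=1/100` and a hidden reward
(`run_foraging_trial`) produces novelty-driven exploration: the agent sweeps
~30 distinct cells in 30 moves, while a novelty-ablated twin averages fewer
and a uniform random walk discovers the hidden object roughly half as often.

A command line wraps the same machinery:

```bash
gridforage simulate --scenario navigation --seed 1 --out runs/nav
gridforage simulate --scenario foraging --seed 1 --out runs/patch
gridforage ephys runs/record.json --out ephys.csv
gridforage fixtures --kind tiny_hmm --seed 1
```

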