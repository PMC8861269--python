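# Methods

## Model

`gridforage` implements a discrete-state active-inference agent for a
geocaching-style task. The generative model is a POMDP with one hidden-state
factor, *location*, on an `n_rows × n_cols` grid (default 10×10; 0-based,
row-major indices; (0,0) top-left; `up` decreases the row; an action that
would leave the grid maps onto `stay`, in the model and in the true process
alike). Two outcome modalities are generated from location:

- **where** — one level per cell, identity likelihood (the agent is told
  unambiguously where it is);
- **what** — `reward` vs `null`; the true process emits `reward` only at the
  rewarding cell.

Preferences are log relative probabilities: `C[what] = [3, 0]` (reward about
e³ ≈ 20 times more expected than null) and, during navigation,
`C[where](j) = −w·d(j, target)` with Manhattan distance `d` and weight
`w = 0.25`. The graded proximity preference is our minimal monotone reading
of "prefers being in proximity of the target"; it is what steers the agent
when the target lies beyond the 4-step planning horizon. In the foraging
patch the rewarding location is unknown to the agent, so no proximity
gradient is computable and `w = 0` there.

Uncertain mappings carry Dirichlet concentration parameters. In the foraging
condition the `what` likelihood starts at the uniform concentration 1/100
per cell, and the transition tables optionally carry concentrations
`2·B_true + 10⁻⁴` (the jitter floor keeps all entries positive). The `where`
likelihood is always known — the task's novelty concerns state→what
mappings, not self-location.

## Inference

Beliefs are policy-conditioned categorical distributions per time point,
`s_π,τ = σ(v_π,τ)`, updated by a gradient descent on variational free energy
with the state prediction error

```
ε_π,τ = ln B̄[u_τ−1]·s_π,τ−1  +  (ln B̄[u_τ])ᵀ·s_π,τ+1  +  Σ_m ln Ā[m]ᵀ·o_τ  −  ln s_π,τ
```

(`ln D` replaces the forward message at τ = 0; the backward message is
absent at τ = T; likelihood messages exist only for already-observed time
points and are omitted — not zero-filled — for the future). This is exactly
the mean-field reading of the update: ε is the negative gradient of the
mean-field free energy, so two key guarantees hold by construction rather
than by tuning:

- **Monotone descent.** The update `v ← v + η(ε − mean ε)`, `η = 1/4`,
  applied coordinate-wise (Gauss–Seidel over τ), moves `v_τ` linearly toward
  the exact coordinate-ascent optimum `σ(messages)`; along that path the
  free energy is provably non-increasing (it is a KL divergence to the
  coordinate optimum, decreasing along the natural-parameter segment).
  Sixteen iterations per time step are run and recorded.
- **Evidence bound.** `F_π = Σ_{τ≤t} s·(ln s − forward − likelihood)` is the
  mean-field ELBO with its sign flipped, hence an upper bound on the
  negative log evidence of the observations under the policy.

A note on the backward message: transposing the *log*-table, as here, and
transposing-then-renormalising the table before taking logs differ only by a
term that is constant across states (the row-sum normalisers contract with
`s_τ+1` into one scalar), which the mean-centred softmax gauge removes; the
two conventions are therefore equivalent in every belief and every posterior.

**Messages use the posterior-predictive tables.** When Dirichlet counts are
present, log-messages use `ln(mean)` — the categorical the Dirichlet
actually predicts — not the geometric expectation `ψ(a) − ψ(ā)`. At the
foraging prior of 1/100 the geometric form assigns ≈ −50 nats to *every*
outcome of an unvisited cell, which out-weighs the (floored) log-zeros of
the identity where-likelihood and would collapse location beliefs onto
previously visited cells. The geometric expectation remains available as
`expected_log_likelihood` (it is the quantity behind the novelty bound) and
is validated against a Monte-Carlo oracle in the tests. Logs of probability
tables are floored at e⁻³², far below anything the softmax dynamics can
resolve.

## Planning and precision

All `5^depth` policies (depth 4 by default) are re-enumerated and re-scored
after every executed action; only the first action of the winning posterior
is executed. Expected free energy decomposes per future time point and
modality into

- risk `o·(ln o − C̃)` (KL of predicted outcomes from the softmax of C),
- ambiguity `s·H` with `H_j = −Σ_i Ā_ij ln Ā_ij`,
- minus novelty `o·W·s`, `W = ½(1/a − 1/ā)` — the standard Dirichlet
  information-gain bound: nonnegative, strictly decreasing in every count,
  vanishing as counts saturate.

With no future observations, the variational fixed point for future time
points is plain forward propagation, so predicted beliefs are computed on
the shared prefix tree of the policy set (5 + 25 + 125 + 625 nodes rather
than 625 × 4 independent chains). Within-horizon revisits are scored with
the *current* counts, so a policy that loops over a novel cell double-counts
its novelty; this is a known property of horizon-static counts and is
corrected in behaviour by the online count updates after every executed
move.

The policy posterior is `Q(π) = σ(ln E − F_π − γ G_π)` with habit prior E
(uniform here) and precision γ = 1/β. Because a strictly receding horizon
shares its executed past across all candidates, `F_π` would be constant and
the precision update inert; instead, when a new observation arrives the
*previous* step's full policy window — including the counterfactual first
actions that were not executed — is re-scored. A counterfactual policy's own
forward message points away from the observed location, so its `F_π` is
large and the observation eliminates it. The precision is then iterated to a
fixed point (16 iterations, each recorded):

```
Q  = σ(ln E − F − γG),   Q₀ = σ(ln E − γG),   β ← β_prior + (Q − Q₀)·G
```

with β floored at 10⁻⁶ and β_prior = 1. When the observation concentrates Q
on low-G policies, β falls and γ rises — the phasic dopamine signature of
eliminating competing plans. The converged γ is held constant across the
step's 16 iterations (precision is only revised at observations), so phasic
events sit exactly at step boundaries; the raw fixed-point relaxation is
kept in `PrecisionState` for analysis. These update equations follow the
companion process-theory scheme; the sign convention is fixed by requiring
that growing confidence increases γ.

During a trial the policy-conditioned beliefs at the current time point
group into at most five distinct vectors (one per candidate first action:
forward and likelihood messages are shared within a group), which is what
makes a 625-policy, 31-time-point trial run in well under a second. The
generic `infer_states` path — full sweeps over all time points for arbitrary
policy sets — is the library surface and is the path checked against the
enumeration oracle.

## Learning

Concentration parameters accumulate as `a ← a + η·o_τ ⊗ s̄_τ` (Bayesian-
model-average beliefs) and `b[u] ← b[u] + η·s̄_τ+1 ⊗ s̄_τ` for the executed
action, with η = 1 and no forgetting. Updates are applied **online**, after
every observed step, so that visited locations lose their novelty within the
30-move trial — the mechanism that makes the agent sweep unexplored ground;
a batch (trial-end) mode is available behind `LearningConfig(online=False)`.
The initial (pre-move) observation is not accumulated, so a 30-move trial
adds exactly 30 counts per learned modality.

## Simulated electrophysiology

One movement lasts 250 ms; with 16 belief iterations per step, dt = 15.625 ms
(64 Hz sampling), making one update cycle per movement a 4 Hz (theta)
rhythm. The readouts per trial record:

- **Firing rates** — one unit per (represented time point, location) pair,
  holding the Bayesian-model-average belief at every recorded iteration:
  `n_states · (n_moves + 1)` units (1,100 for 10 moves on the 10×10 grid).
  Within a step, the units of the current time point follow the gradient
  relaxation and the predicted-future units follow the precision-weighted
  re-planning.
- **LFPs** — per-unit first differences of firing rate over dt. The *signed*
  unit-mean of these traces cancels identically (each time point's units
  always hold a normalised belief), so the population channel used for
  spectral analysis is the mean **rectified** LFP (`lfp_mua`, a multi-unit
  activity envelope); the signed mean is still exported for completeness.
- **Dopamine** — tonic trace = γ per iteration (piecewise constant within
  steps); phasic trace = positive part of its first difference over dt,
  nonzero only at step boundaries.
- **Theta band** — a 2nd-order Butterworth band-pass (2–6 Hz) applied
  forward–backward (zero phase); time-frequency maps use a short-time
  spectrogram (1 s window, 75 % overlap, constant detrend).

## Oracle fixtures

`make_fixture` emits miniature random POMDPs (2–3 states, ≤ 4 moves) whose
posterior marginals and evidence are computed by brute-force enumeration of
all state sequences — the independent oracle for the variational scheme.
The fixtures emulate the task's operating regime: columns are
near-deterministic (dominant mass 0.95–0.995) with the dominant entries
forming a permutation (each state has a distinct modal outcome and modal
successor), and trajectories/outcomes follow the modal dynamics from a
randomly sampled start. This matters for what passing oracle tests do and
do not show: a mean-field posterior provably cannot reproduce the
correlated, multimodal posteriors that arise when ambiguous likelihoods meet
strongly conflicting evidence, and the fixtures deliberately stay out of
that regime — as does the task itself, whose location observations are
exact and whose dynamics are deterministic. The weak stochastic tails keep
the comparison a genuine numerical check rather than a delta-matching
exercise.

## What the synthetic environment does and does not emulate

The generative process is a deterministic grid with edge-stay, a single
rewarding cell per phase, and exact location readout; it never consults the
agent's beliefs. It emulates the structure of the task — goal-directed
approach, local epistemic search, session chaining — but none of the
messiness of real spatial data: no observation noise on position, no
obstacles, no multiple or depleting rewards, no continuous space or time.
Passing tests therefore certify the belief-updating machinery and its
qualitative neurophysiological signatures, not quantitative fits to animal
recordings.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| grid | 10×10 | hidden-state space (100 locations) |
| utilities | [3, 0] | log-preference for reward vs null |
| proximity weight | 0.25 (navigation), 0 (foraging) | nats per Manhattan step |
| policy depth | 4 | planning horizon (actions) |
| iterations per step | 16 | gradient iterations per time point |
| step size | 0.25 | damping toward the coordinate optimum |
| navigation / foraging moves | 10 / 30 | trial lengths |
| a-prior | 0.01 | foraging what-likelihood concentration |
| transition prior scale | 2.0 | b concentration on the true transition |
| β prior | 1.0 | prior inverse precision over policies |
| η | 1.0 | learning rate (counts per observation) |
| step duration | 0.25 s | temporal calibration (⇒ 64 Hz sampling) |

## Known limitations

- Single hidden-state factor; no hierarchical (two-level) model — the
  navigation→foraging alternation is session orchestration, not a deep
  temporal level.
- `F_π` distinguishes policies only through their first action (the
  one-step-back evaluation window); longer counterfactual histories are not
  scored.
- Novelty covers the likelihood mapping only; transition (b) uncertainty
  informs predictions but contributes no information-gain term to G.
- The exploitation/exploration balance is whatever expected free energy
  dictates: with a 100-cell patch and 30 moves, novelty still dominates
  after the hidden object is found, so the agent keeps exploring rather
  than camping on the reward.
- Habits (E), preferences (C) and initial-state priors (D) are not learned.
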