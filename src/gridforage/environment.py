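"""Generative process (true grid world) and trial/session orchestration.

The *process* is strictly separated from the agent's *model*: the world moves
deterministically on the grid (off-grid actions map to stay), emits a one-hot
``where`` outcome at the true location and a ``reward``/``null`` ``what``
outcome depending on whether the true location is the rewarding one.  It never
consults the agent's beliefs.

The agent runs a plan–act–observe loop with a receding four-step horizon:

1. **Observe & infer** — the new outcome updates beliefs about the current
   location by gradient descent on free energy (``iterations_per_step``
   iterations, every one recorded for the neurophysiology readouts).  The
   policy window of the *previous* step — which still contains counterfactual
   first actions — is re-scored: policies whose own first action is
   inconsistent with the observed location acquire a large free energy
   ``F_π``, eliminating them.
2. **Update precision** — the eliminated alternatives drive the fixed-point
   update of the precision γ over policies (the simulated dopamine signal);
   confidence rises exactly when the observation prunes competing plans.
3. **Learn** (optional) — Dirichlet counts of the likelihood/transition
   mappings accumulate, so visited locations lose their novelty.
4. **Replan & act** — a fresh depth-``policy_depth`` policy set is scored by
   expected free energy from the current belief; the first action of the
   precision-weighted policy posterior is executed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._num import entropy_of, log_stable, softmax
from .generative_model import (
    ACTIONS,
    GenerativeModel,
    GridGeometry,
    build_geocache_model,
)
from .inference import DEFAULT_STEP_SIZE, likelihood_message
from .learning import LearningConfig, update_likelihood_counts, update_transition_counts
from .planning import (
    PrecisionState,
    enumerate_policies,
    policy_posterior,
    score_policy_set,
    select_action,
    update_precision,
)


@dataclass(frozen=True)
class GridWorld:
    """True state of the environment (the generative process)."""

    geometry: GridGeometry
    true_location: int
    reward_location: int
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.geometry.n_locations
        if not (0 <= self.true_location < n and 0 <= self.reward_location < n):
            raise ValueError("locations must lie on the grid")


def observe(world: GridWorld) -> dict[str, np.ndarray]:
    """Outcomes emitted at the current true location."""
    n = world.geometry.n_locations
    o_where = np.zeros(n)
    o_where[world.true_location] = 1.0
    o_what = np.zeros(2)
    o_what[0 if world.true_location == world.reward_location else 1] = 1.0
    return {"what": o_what, "where": o_where}


def env_step(world: GridWorld, action: str) -> tuple[GridWorld, dict[str, np.ndarray]]:
    """Move deterministically (edge-stay) and emit the new outcomes."""
    if action not in ACTIONS:
        raise KeyError(f"unknown action {action!r}")
    new = dataclasses.replace(
        world, true_location=world.geometry.move(world.true_location, action)
    )
    return new, observe(new)


@dataclass
class SimulationRecord:
    """Complete log of one trial."""

    n_moves: int
    n_states: int
    iterations_per_step: int
    step_duration_s: float
    seed: int
    true_states: list[int] = field(default_factory=list)
    actions: list[str] = field(default_factory=list)
    outcomes: list[dict] = field(default_factory=list)  # {"what": level, "where": loc}
    bma: Optional[np.ndarray] = None  # (T+1, n_states) final beliefs
    raster: Optional[np.ndarray] = None  # (16·(T+1), T+1, n_states)
    policy_posteriors: list[np.ndarray] = field(default_factory=list)
    F_vectors: list[np.ndarray] = field(default_factory=list)
    G_vectors: list[np.ndarray] = field(default_factory=list)
    risk_vectors: list[np.ndarray] = field(default_factory=list)
    novelty_vectors: list[np.ndarray] = field(default_factory=list)
    gamma_per_step: list[float] = field(default_factory=list)
    gamma_fixed_point: list[float] = field(default_factory=list)
    entropy_prior: list[float] = field(default_factory=list)
    entropy_post: list[float] = field(default_factory=list)
    free_energy_iterations: list[list[float]] = field(default_factory=list)
    novelty_selected: list[float] = field(default_factory=list)
    a_delta: dict = field(default_factory=dict)
    b_delta: dict = field(default_factory=dict)

    @property
    def visited(self) -> list[int]:
        return self.true_states

    @property
    def distinct_visited(self) -> int:
        return len(set(self.true_states))

    def first_reward_step(self) -> Optional[int]:
        for tau, o in enumerate(self.outcomes):
            if o["what"] == 0:
                return tau
        return None

    # -- serialization ----------------------------------------------------

    def to_dict(self, include_raster: bool = True) -> dict:
        arr = lambda x: None if x is None else np.asarray(x).tolist()  # noqa: E731
        d = {
            "n_moves": self.n_moves,
            "n_states": self.n_states,
            "iterations_per_step": self.iterations_per_step,
            "step_duration_s": self.step_duration_s,
            "seed": self.seed,
            "true_states": list(self.true_states),
            "actions": list(self.actions),
            "outcomes": self.outcomes,
            "bma": arr(self.bma),
            "raster": arr(self.raster) if include_raster else None,
            "policy_posteriors": [arr(q) for q in self.policy_posteriors],
            "F_vectors": [arr(f) for f in self.F_vectors],
            "G_vectors": [arr(g) for g in self.G_vectors],
            "risk_vectors": [arr(g) for g in self.risk_vectors],
            "novelty_vectors": [arr(g) for g in self.novelty_vectors],
            "gamma_per_step": list(self.gamma_per_step),
            "gamma_fixed_point": list(self.gamma_fixed_point),
            "entropy_prior": list(self.entropy_prior),
            "entropy_post": list(self.entropy_post),
            "free_energy_iterations": self.free_energy_iterations,
            "novelty_selected": list(self.novelty_selected),
            "a_delta": {m: arr(v) for m, v in self.a_delta.items()},
            "b_delta": {u: arr(v) for u, v in self.b_delta.items()},
        }
        return d

    def save(self, path, include_raster: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_raster), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationRecord":
        arr = lambda x: None if x is None else np.asarray(x, dtype=float)  # noqa: E731
        return cls(
            n_moves=d["n_moves"],
            n_states=d["n_states"],
            iterations_per_step=d["iterations_per_step"],
            step_duration_s=d["step_duration_s"],
            seed=d["seed"],
            true_states=list(d["true_states"]),
            actions=list(d["actions"]),
            outcomes=d["outcomes"],
            bma=arr(d["bma"]),
            raster=arr(d["raster"]),
            policy_posteriors=[arr(q) for q in d["policy_posteriors"]],
            F_vectors=[arr(f) for f in d["F_vectors"]],
            G_vectors=[arr(g) for g in d["G_vectors"]],
            risk_vectors=[arr(g) for g in d["risk_vectors"]],
            novelty_vectors=[arr(g) for g in d["novelty_vectors"]],
            gamma_per_step=list(d["gamma_per_step"]),
            gamma_fixed_point=list(d["gamma_fixed_point"]),
            entropy_prior=list(d["entropy_prior"]),
            entropy_post=list(d["entropy_post"]),
            free_energy_iterations=d["free_energy_iterations"],
            novelty_selected=list(d["novelty_selected"]),
            a_delta={m: arr(v) for m, v in d["a_delta"].items()},
            b_delta={u: arr(v) for u, v in d["b_delta"].items()},
        )

    @classmethod
    def load(cls, path) -> "SimulationRecord":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def run_trial(
    model: GenerativeModel,
    world: GridWorld,
    n_moves: int,
    learning: Optional[LearningConfig] = None,
    beta_prior: float = 1.0,
    step_size: float = DEFAULT_STEP_SIZE,
    step_duration_s: float = 0.25,
    ablate_novelty: bool = False,
    sample_actions: bool = False,
    seed: int = 0,
) -> SimulationRecord:
    """Run one plan–act–observe trial of ``n_moves`` moves.

    The model's Dirichlet counts are updated in place when ``learning`` is
    given (online by default, batch at trial end otherwise).
    """
    T = n_moves
    n = model.n_states
    K = model.iterations_per_step
    rng = np.random.default_rng(seed)

    policies = enumerate_policies(ACTIONS, model.policy_depth)
    nP = len(policies)
    E = np.full(nP, 1.0 / nP)
    lnE = log_stable(E)
    depth = model.policy_depth

    a_prior = {m: v.copy() for m, v in model.likelihood.a.items()}
    b_prior = {u: v.copy() for u, v in model.transitions.b.items()}

    rec = SimulationRecord(
        n_moves=T,
        n_states=n,
        iterations_per_step=K,
        step_duration_s=step_duration_s,
        seed=seed,
    )
    raster = np.full((K * (T + 1), T + 1, n), 1.0 / n)
    bma = np.full((T + 1, n), 1.0 / n)

    precision = PrecisionState(beta_prior=beta_prior, beta=beta_prior)
    gamma = precision.gamma

    prev_G = None  # EFE of the previous step's policy window
    prev_Q = None
    F_shared = 0.0

    def record_outcome(o):
        rec.outcomes.append(
            {"what": int(np.argmax(o["what"])), "where": int(np.argmax(o["where"]))}
        )

    first_idx = np.array([ACTIONS.index(p[0]) for p in policies])

    o_t = observe(world)
    rec.true_states.append(world.true_location)
    record_outcome(o_t)

    for t in range(T + 1):
        base = K * t
        lnD = log_stable(np.asarray(model.priors.D, dtype=float))
        like = likelihood_message(model, o_t)

        if t == 0:
            # single shared belief about the initial location
            v = lnD.copy()
            F_iter = []
            for k in range(K):
                eps = lnD + like - log_stable(softmax(v))
                v = v + step_size * (eps - eps.mean())
                s0 = softmax(v)
                raster[base + k, 0] = s0
                F_iter.append(float(s0 @ (log_stable(s0) - lnD - like)))
                rec.gamma_fixed_point.append(gamma)
            rec.free_energy_iterations.append(F_iter)
            rec.gamma_per_step.append(gamma)
            bma[0] = s0
            s_curr = s0
        else:
            # phase A: re-score the previous window against the new outcome.
            # Policies group by their first action: forward and likelihood
            # messages are shared within a group.
            lnB = {u: model.transitions.mean_log(u) for u in ACTIONS}
            fwd = {u: lnB[u] @ bma[t - 1] for u in ACTIONS}
            v_g = {u: log_stable(model.transitions.mean(u) @ bma[t - 1]) for u in ACTIONS}
            s_g = {u: softmax(v_g[u]) for u in ACTIONS}
            group_F_iter = {u: [] for u in ACTIONS}
            s_g_iter = []  # per-iteration dict of group beliefs
            for k in range(K):
                for u in ACTIONS:
                    eps = fwd[u] + like - log_stable(s_g[u])
                    v_g[u] = v_g[u] + step_size * (eps - eps.mean())
                    s_g[u] = softmax(v_g[u])
                    group_F_iter[u].append(
                        float(s_g[u] @ (log_stable(s_g[u]) - fwd[u] - like))
                    )
                s_g_iter.append({u: s_g[u].copy() for u in ACTIONS})

            group_F_final = np.array([group_F_iter[u][-1] for u in ACTIONS])
            F_vec = F_shared + group_F_final[first_idx]
            rec.F_vectors.append(F_vec)

            # phase B of the *previous* step produced prev_G for this window
            precision = update_precision(precision, E, F_vec, prev_G, n_iter=K)
            gamma = precision.gamma
            rec.gamma_per_step.append(gamma)

            Q_post = policy_posterior(E, F_vec, prev_G, gamma)
            rec.entropy_prior.append(entropy_of(prev_Q))
            rec.entropy_post.append(entropy_of(Q_post))

            # per-iteration Bayesian model average at the current time point,
            # weighted by the evolving precision trace
            F_iter = []
            for k in range(K):
                g_k = precision.gamma_trace[-K + k]
                rec.gamma_fixed_point.append(g_k)
                Q_k = policy_posterior(E, F_vec, prev_G, g_k)
                w = np.bincount(first_idx, weights=Q_k, minlength=len(ACTIONS))
                s_bar = sum(w[i] * s_g_iter[k][u] for i, u in enumerate(ACTIONS))
                raster[base + k, t] = s_bar
                F_iter.append(
                    float(sum(w[i] * group_F_iter[u][k] for i, u in enumerate(ACTIONS)))
                )
            rec.free_energy_iterations.append(F_iter)

            w_final = np.bincount(first_idx, weights=Q_post, minlength=len(ACTIONS))
            s_curr = sum(w_final[i] * s_g[u] for i, u in enumerate(ACTIONS))
            s_curr = s_curr / s_curr.sum()
            bma[t] = s_curr
            F_shared += float(group_F_iter[rec.actions[-1]][-1])

            # learning: accumulate Dirichlet counts for this observed step
            if learning is not None and learning.online:
                _accumulate(model, learning, [bma[t - 1], bma[t]], [o_t], [rec.actions[-1]])

        if t < T:
            # phase B: replan over a freshly anchored policy window
            comps, levels = score_policy_set(model, s_curr, policies)
            G_vec = comps.risk + comps.ambiguity - (0.0 if ablate_novelty else 1.0) * comps.novelty
            rec.G_vectors.append(G_vec)
            rec.risk_vectors.append(comps.risk)
            rec.novelty_vectors.append(comps.novelty)
            Q_t = policy_posterior(E, np.zeros(nP), G_vec, gamma)
            rec.policy_posteriors.append(Q_t)

            # predicted-future units of the raster, weighted per iteration by
            # the precision relaxation
            for k in range(K):
                g_k = rec.gamma_fixed_point[base + k]
                Q_k = policy_posterior(E, np.zeros(nP), G_vec, g_k)
                q = Q_k
                for lvl in range(1, depth + 1):
                    if t + lvl > T:
                        break
                    n_prefix = len(ACTIONS) ** lvl
                    wq = q.reshape(n_prefix, -1).sum(axis=1)
                    raster[base + k, t + lvl] = wq @ levels[lvl]
            for lvl in range(1, depth + 1):
                if t + lvl > T:
                    break
                n_prefix = len(ACTIONS) ** lvl
                wq = Q_t.reshape(n_prefix, -1).sum(axis=1)
                bma[t + lvl] = wq @ levels[lvl]

            action = select_action(Q_t, policies, 0, rng=rng, sample=sample_actions)
            rec.actions.append(action)
            rec.novelty_selected.append(float(comps.novelty[int(np.argmax(Q_t))]))
            prev_G = G_vec
            prev_Q = Q_t

            world, o_t = env_step(world, action)
            rec.true_states.append(world.true_location)
            record_outcome(o_t)

    if learning is not None and not learning.online:
        _accumulate(
            model,
            learning,
            [bma[tau] for tau in range(T + 1)],
            [ _onehot_outcomes(rec.outcomes[tau], n) for tau in range(1, T + 1)],
            rec.actions,
            batch=True,
        )

    rec.bma = bma
    rec.raster = raster
    for m, prior in a_prior.items():
        rec.a_delta[m] = model.likelihood.a[m] - prior
    for u, prior in b_prior.items():
        rec.b_delta[u] = model.transitions.b[u] - prior
    return rec


def _onehot_outcomes(outcome: dict, n_states: int) -> dict[str, np.ndarray]:
    o_what = np.zeros(2)
    o_what[outcome["what"]] = 1.0
    o_where = np.zeros(n_states)
    o_where[outcome["where"]] = 1.0
    return {"what": o_what, "where": o_where}


def _accumulate(model, learning, beliefs, outcomes, actions, batch=False):
    """Apply Dirichlet updates; online calls pass one step at a time.

    ``beliefs`` has one more entry than ``outcomes``: the leading belief is
    the pre-move state (used only for the transition update), so the initial
    observation of a trial is never accumulated.
    """
    if learning.learn_what:
        for m in list(model.likelihood.a):
            model.likelihood.a[m] = update_likelihood_counts(
                model.likelihood.a[m],
                beliefs[1:],
                [np.asarray(o[m], dtype=float) for o in outcomes],
                learning.eta,
            )
    if learning.learn_transitions and model.transitions.b:
        model.transitions.b = update_transition_counts(
            model.transitions.b, beliefs, actions, learning.eta
        )


def run_navigation_trial(
    model: GenerativeModel,
    world: GridWorld,
    n_moves: int = 10,
    **kwargs,
) -> SimulationRecord:
    """Goal-directed navigation with a known map (no learning)."""
    return run_trial(model, world, n_moves, learning=None, **kwargs)


def run_foraging_trial(
    model: GenerativeModel,
    world: GridWorld,
    n_moves: int = 30,
    learning_config: Optional[LearningConfig] = None,
    **kwargs,
) -> SimulationRecord:
    """Novelty-driven local foraging with Dirichlet learning."""
    if learning_config is None:
        learning_config = LearningConfig()
    return run_trial(model, world, n_moves, learning=learning_config, **kwargs)


def uniform_random_walk(
    world: GridWorld, n_moves: int, rng: np.random.Generator
) -> list[int]:
    """Baseline: uniformly random actions; returns the visited trajectory."""
    path = [world.true_location]
    for _ in range(n_moves):
        world, _ = env_step(world, ACTIONS[int(rng.integers(len(ACTIONS)))])
        path.append(world.true_location)
    return path


def run_geocaching_session(
    base_model: GenerativeModel,
    session_script: Sequence[dict],
    n_nav_moves: int = 10,
    n_forage_moves: int = 30,
    forage_prior_scale: float = 0.01,
    forage_transition_scale: Optional[float] = 2.0,
    patch_entrance: Optional[int] = None,
    start_location: int = 0,
    learning_config: Optional[LearningConfig] = None,
    seed: int = 0,
    **kwargs,
) -> list[SimulationRecord]:
    """Alternate navigation and local-foraging trials.

    ``session_script`` is a sequence of ``{"target": int, "hidden_object": int}``
    entries.  Each navigation trial starts where the previous foraging trial
    discovered the hidden object (mapped onto the global grid); each foraging
    patch is a fresh 10×10 grid with fresh novelty priors.  The script's
    exhaustion ends the session cleanly.
    """
    geom = base_model.geometry
    records: list[SimulationRecord] = []
    loc = start_location
    for i, entry in enumerate(session_script):
        target = int(entry["target"])
        nav_model = build_geocache_model(
            geom,
            target,
            utilities=np.asarray(base_model.preferences.C["what"]),
            proximity_weight=0.25,
            start_location=loc,
            policy_depth=base_model.policy_depth,
            iterations_per_step=base_model.iterations_per_step,
        )
        nav_world = GridWorld(geom, true_location=loc, reward_location=target, seed=seed + 2 * i)
        if n_nav_moves > 0:
            records.append(
                run_navigation_trial(nav_model, nav_world, n_nav_moves, seed=seed + 2 * i, **kwargs)
            )
            loc = records[-1].true_states[-1]
        if n_forage_moves > 0 and "hidden_object" in entry:
            entrance = (
                geom.to_index(geom.n_rows // 2, geom.n_cols // 2)
                if patch_entrance is None
                else patch_entrance
            )
            patch_model = build_geocache_model(
                geom,
                int(entry["hidden_object"]),
                utilities=np.asarray(base_model.preferences.C["what"]),
                dirichlet_prior_scale=forage_prior_scale,
                transition_prior_scale=forage_transition_scale,
                proximity_weight=0.0,
                start_location=entrance,
                policy_depth=base_model.policy_depth,
                iterations_per_step=base_model.iterations_per_step,
            )
            patch_world = GridWorld(
                geom,
                true_location=entrance,
                reward_location=int(entry["hidden_object"]),
                seed=seed + 2 * i + 1,
            )
            records.append(
                run_foraging_trial(
                    patch_model,
                    patch_world,
                    n_forage_moves,
                    learning_config=learning_config,
                    seed=seed + 2 * i + 1,
                    **kwargs,
                )
            )
            found = records[-1].first_reward_step()
            loc = (
                records[-1].true_states[found]
                if found is not None
                else records[-1].true_states[-1]
            )
    return records
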