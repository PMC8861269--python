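"""Small random POMDP fixtures with exact (enumeration) oracles.

These fixtures emulate the task's operating regime at a miniature scale:
likelihood and transition columns are *near-deterministic* (a dominant mass
of 0.95–0.995, mirroring the deterministic grid moves and the unambiguous
``where`` mapping, with weak stochasticity probing robustness), the dominant
entries form a permutation (each state has a distinct modal outcome and modal
successor), and the emitted trajectory follows the modal dynamics and modal
outcomes from a randomly sampled start.  This is the self-consistent regime
the grid task occupies; grossly conflicting evidence would induce posterior
correlations that no factorised (mean-field) posterior can represent and is
exercised nowhere in the task.

For ≤ 3 states and ≤ 4 moves the posterior marginals and model evidence are
computed by brute-force enumeration of all state sequences, providing an
independent oracle for the variational scheme.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np

from .generative_model import (
    GenerativeModel,
    GridGeometry,
    InitialAndHabitPriors,
    LikelihoodModel,
    PreferenceModel,
    TransitionModel,
    build_geocache_model,
)

FIXTURE_KINDS = ("tiny_hmm", "two_state_bandit", "mini_grid")

#: Dominant column mass of near-deterministic fixture tables.
DOMINANT_MASS = (0.95, 0.995)


def _peaked_permutation_table(n: int, rng: np.random.Generator) -> np.ndarray:
    """Near-deterministic square table whose dominant entries form a
    permutation (distinct modal image per column)."""
    perm = rng.permutation(n)
    cols = []
    for j in range(n):
        p = rng.uniform(*DOMINANT_MASS)
        col = rng.dirichlet(np.ones(n)) * (1 - p)
        col[perm[j]] += p
        cols.append(col / col.sum())
    return np.column_stack(cols)


def exhaustive_smoother(
    model: GenerativeModel,
    policy: Sequence[str],
    observations: Sequence[dict],
    t_now: Optional[int] = None,
) -> tuple[np.ndarray, float]:
    """Exact smoothing marginals and evidence by enumerating state sequences.

    Returns ``(marginals, evidence)`` with marginals of shape
    ``(T+1, n_states)``; intended for ≤ 3 states and T ≤ 4 only.
    """
    T = len(policy)
    t_now = T if t_now is None else t_now
    n = model.n_states
    A = {m: np.asarray(t, float) for m, t in model.likelihood.A.items()}
    B = {u: np.asarray(t, float) for u, t in model.transitions.B.items()}
    D = np.asarray(model.priors.D, float)

    marginals = np.zeros((T + 1, n))
    evidence = 0.0
    for seq in np.ndindex(*([n] * (T + 1))):
        p = D[seq[0]]
        for tau in range(T):
            p *= B[policy[tau]][seq[tau + 1], seq[tau]]
        for tau in range(min(t_now, T) + 1):
            for m, o in observations[tau].items():
                p *= float(np.asarray(o, float) @ A[m][:, seq[tau]])
        evidence += p
        for tau, s in enumerate(seq):
            marginals[tau, s] += p
    if evidence <= 0:
        raise ValueError("observations impossible under the model")
    return marginals / evidence, float(evidence)


def _modal_trajectory(model, policy, rng):
    """Trajectory following the modal dynamics from a sampled start, with
    modal one-hot observations (the task's self-consistent regime)."""
    n = model.n_states
    states = [int(rng.choice(n, p=np.asarray(model.priors.D, float)))]
    observations = []
    for tau in range(len(policy) + 1):
        obs = {}
        for m, A in model.likelihood.A.items():
            vec = np.zeros(A.shape[0])
            vec[int(np.argmax(A[:, states[-1]]))] = 1.0
            obs[m] = vec
        observations.append(obs)
        if tau < len(policy):
            B = model.transitions.B[policy[tau]]
            states.append(int(np.argmax(B[:, states[-1]])))
    return states, observations


def make_fixture(kind: str, seed: int) -> dict:
    """Emit a ≤3-state model plus exhaustively-enumerated expectations.

    Returns a dict with the model, a policy (action sequence), sampled
    observations, the exact posterior marginals and the exact evidence.
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny_hmm":
        n, T = 3, 4
        actions = ("up", "down")
        geom = GridGeometry(1, n)
        A = {"what": _peaked_permutation_table(n, rng)}
        B = {u: _peaked_permutation_table(n, rng) for u in actions}
        model = GenerativeModel(
            geometry=geom,
            likelihood=LikelihoodModel(A=A),
            transitions=TransitionModel(B=B),
            preferences=PreferenceModel(C={"what": np.zeros(3)}),
            priors=InitialAndHabitPriors(D=rng.dirichlet(np.ones(n) * 5)),
            policy_depth=1,
        )
        policy = tuple(actions[int(rng.integers(2))] for _ in range(T))
    elif kind == "two_state_bandit":
        n, T = 2, 3
        actions = ("stay", "right")
        geom = GridGeometry(1, n)
        A = {"what": _peaked_permutation_table(n, rng)}
        B = {
            "stay": _peaked_permutation_table(n, rng),
            "right": _peaked_permutation_table(n, rng),
        }
        model = GenerativeModel(
            geometry=geom,
            likelihood=LikelihoodModel(A=A),
            transitions=TransitionModel(B=B),
            preferences=PreferenceModel(C={"what": np.zeros(2)}),
            priors=InitialAndHabitPriors(D=np.array([0.5, 0.5])),
            policy_depth=1,
        )
        policy = tuple(actions[int(rng.integers(2))] for _ in range(T))
    elif kind == "mini_grid":
        geom = GridGeometry(2, 2)
        model = build_geocache_model(geom, target_location=int(rng.integers(4)))
        policy = tuple(
            ("up", "down", "left", "right", "stay")[int(rng.integers(5))]
            for _ in range(3)
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    states, observations = _modal_trajectory(model, policy, rng)
    marginals, evidence = exhaustive_smoother(model, policy, observations)
    return {
        "kind": kind,
        "seed": seed,
        "model": model,
        "policy": policy,
        "true_states": states,
        "observations": observations,
        "exact_marginals": marginals,
        "exact_evidence": evidence,
    }


def fixture_to_json(fx: dict) -> str:
    """Deterministic JSON rendering of a fixture (identical bytes per seed)."""
    d = {
        "kind": fx["kind"],
        "seed": fx["seed"],
        "model": fx["model"].to_dict(),
        "policy": list(fx["policy"]),
        "true_states": fx["true_states"],
        "observations": [
            {m: np.asarray(o).tolist() for m, o in obs.items()}
            for obs in fx["observations"]
        ],
        "exact_marginals": np.asarray(fx["exact_marginals"]).tolist(),
        "exact_evidence": fx["exact_evidence"],
    }
    return json.dumps(d, sort_keys=True)
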