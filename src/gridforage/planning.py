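"""Policy enumeration, expected free energy, precision, and action selection.

Policies are ordered action sequences of fixed depth (the planning horizon).
Each policy ``π`` is scored by its expected free energy

    G(π) = Σ_τ Σ_m [ risk + ambiguity − novelty ]

with, for predicted outcome distribution ``o = Ā[m] · s[π, τ]``,

- risk:      ``o · (ln o − C̃[m])`` — KL divergence of predicted outcomes from
  the (log-softmax) preference distribution;
- ambiguity: ``s · H[m]`` — expected outcome entropy given states;
- novelty:   ``o · W · s`` with ``W = ½(1/a − 1/ā)`` — the Dirichlet
  information-gain bound, the value of observing an outcome under a mapping
  that is still uncertain.  It vanishes as counts saturate.

The policy posterior is a precision-weighted softmax, ``Q(π) = σ(ln E − F_π −
γ G_π)``, and the precision ``γ = 1/β`` (the simulated dopamine substrate) is
updated to a fixed point of ``β ← β_prior + (Q − Q₀) · G`` whenever new
observations re-score the policies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._num import log_stable, softmax
from .generative_model import ACTIONS, GenerativeModel, ambiguity_vector

Policy = tuple[str, ...]

#: Floor keeping β (inverse precision) positive.
BETA_FLOOR = 1e-6


def enumerate_policies(
    actions: Sequence[str] = ACTIONS, depth: int = 4
) -> list[Policy]:
    """All ``|actions|^depth`` action sequences in lexicographic order under
    the documented action order (up < down < left < right < stay)."""
    if depth < 1:
        raise ValueError("policy depth must be ≥ 1")
    return [tuple(p) for p in itertools.product(actions, repeat=depth)]


@dataclass
class EFEComponents:
    """Per-policy expected-free-energy decomposition (summed over the future
    horizon and outcome modalities)."""

    risk: np.ndarray
    ambiguity: np.ndarray
    novelty: np.ndarray
    outcomes: Optional[dict] = None  # modality -> (n_policies, depth, n_outcomes)

    @property
    def G(self) -> np.ndarray:
        return self.risk + self.ambiguity - self.novelty


@dataclass
class PrecisionState:
    """Prior/posterior precision over policies (γ = 1/β)."""

    beta_prior: float = 1.0
    beta: float = 1.0
    gamma_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.beta_prior <= 0 or self.beta <= 0:
            raise ValueError("β must be positive")

    @property
    def gamma(self) -> float:
        return 1.0 / self.beta


def predicted_outcomes(
    model: GenerativeModel, state_belief: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-modality outcome distributions ``o = Ā[m] · s`` under the expected
    likelihood (Dirichlet mean when counts are attached)."""
    s = np.asarray(state_belief, dtype=float)
    return {m: model.likelihood.mean(m) @ s for m in model.modalities}


def novelty_term(
    a: np.ndarray, predicted_outcome: np.ndarray, belief: np.ndarray
) -> float:
    """Expected information gain about a Dirichlet-parameterised mapping.

    ``o · W · s`` with ``W_ij = ½(1/a_ij − 1/ā_j)``; nonnegative and strictly
    decreasing in every concentration increment.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("concentration parameters must be strictly positive")
    W = 0.5 * (1.0 / a - 1.0 / a.sum(axis=0, keepdims=True))
    return float(np.asarray(predicted_outcome) @ W @ np.asarray(belief))


def _node_cost_batch(
    model: GenerativeModel,
    S: np.ndarray,
    H: dict[str, np.ndarray],
    lnC: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(risk, ambiguity, novelty) for a batch of predicted state beliefs
    (rows of ``S``), summed over modalities."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    k = S.shape[0]
    risk = np.zeros(k)
    amb = np.zeros(k)
    nov = np.zeros(k)
    for m in model.modalities:
        Abar = model.likelihood.mean(m)
        O = S @ Abar.T
        risk += np.sum(O * (log_stable(O) - lnC[m][None, :]), axis=1)
        amb += S @ H[m]
        if m in model.likelihood.a:
            a = model.likelihood.a[m]
            W = 0.5 * (1.0 / a - 1.0 / a.sum(axis=0, keepdims=True))
            nov += np.sum(O * (S @ W.T), axis=1)
    return risk, amb, nov


def _node_cost(
    model: GenerativeModel,
    s: np.ndarray,
    H: dict[str, np.ndarray],
    lnC: dict[str, np.ndarray],
) -> tuple[float, float, float]:
    """(risk, ambiguity, novelty) of one predicted time point."""
    r, a_, n_ = _node_cost_batch(model, s, H, lnC)
    return float(r[0]), float(a_[0]), float(n_[0])


def _prep_tables(model: GenerativeModel):
    H = {m: ambiguity_vector(model.likelihood.mean(m)) for m in model.modalities}
    lnC = {m: model.preferences.log_softmax(m) for m in model.modalities}
    return H, lnC


def expected_free_energy(
    model: GenerativeModel,
    beliefs: np.ndarray,
    policy: Sequence[str],
) -> EFEComponents:
    """Score one policy given its predicted future state beliefs.

    ``beliefs`` holds one state distribution per future time point of the
    policy (shape ``(depth, n_states)``).
    """
    H, lnC = _prep_tables(model)
    risk = amb = nov = 0.0
    outcomes: dict[str, list] = {m: [] for m in model.modalities}
    for s in np.atleast_2d(np.asarray(beliefs, dtype=float)):
        r, a_, n_ = _node_cost(model, s, H, lnC)
        risk, amb, nov = risk + r, amb + a_, nov + n_
        for m, o in predicted_outcomes(model, s).items():
            outcomes[m].append(o)
    return EFEComponents(
        risk=np.asarray([risk]),
        ambiguity=np.asarray([amb]),
        novelty=np.asarray([nov]),
        outcomes={m: np.asarray(v)[None] for m, v in outcomes.items()},
    )


def score_policy_set(
    model: GenerativeModel,
    current_belief: np.ndarray,
    policies: Sequence[Policy],
    depth: Optional[int] = None,
) -> tuple[EFEComponents, list[np.ndarray]]:
    """Score every policy by propagating beliefs along the shared prefix tree.

    Returns the per-policy EFE components and the per-level predicted beliefs
    (level ℓ holds the ``n_actions^ℓ`` distinct state distributions reached
    after ℓ policy steps; leaf ``i`` at level ℓ is row ``i // n_actions**(depth−ℓ)``).
    Exploits the fact that, with no future observations, the variational fixed
    point for future time points is plain forward propagation.
    """
    depth = model.policy_depth if depth is None else depth
    acts = tuple(u for u in ACTIONS if any(u in p for p in policies)) or ACTIONS
    # the tree layout requires the full lexicographic product of `acts`
    if list(policies) != enumerate_policies(acts, depth):
        return _score_policies_generic(model, current_belief, policies, depth)

    H, lnC = _prep_tables(model)
    Bbar = {u: model.transitions.mean(u) for u in model.transitions.actions}
    n_a = len(acts)

    levels = [np.asarray(current_belief, dtype=float)[None, :]]
    for _ in range(depth):
        parent = levels[-1]
        child = np.empty((parent.shape[0] * n_a, parent.shape[1]))
        for i, u in enumerate(acts):
            # children of parent row r occupy rows r*n_a .. r*n_a+n_a-1
            child[i::n_a] = parent @ Bbar[u].T
        levels.append(child)

    # accumulate the decomposition per leaf from the shared tree nodes
    risk = np.zeros(len(policies))
    amb = np.zeros(len(policies))
    nov = np.zeros(len(policies))
    stride = 1
    for level in range(depth, 0, -1):
        r, a_, n_ = _node_cost_batch(model, levels[level], H, lnC)
        idx = np.arange(len(policies)) // stride
        risk += r[idx]
        amb += a_[idx]
        nov += n_[idx]
        stride *= n_a
    return EFEComponents(risk=risk, ambiguity=amb, novelty=nov), levels


def _score_policies_generic(model, current_belief, policies, depth):
    H, lnC = _prep_tables(model)
    Bbar = {u: model.transitions.mean(u) for u in model.transitions.actions}
    risk = np.zeros(len(policies))
    amb = np.zeros(len(policies))
    nov = np.zeros(len(policies))
    for p_idx, policy in enumerate(policies):
        s = np.asarray(current_belief, dtype=float)
        for u in policy[:depth]:
            s = Bbar[u] @ s
            r, a_, n_ = _node_cost(model, s, H, lnC)
            risk[p_idx] += r
            amb[p_idx] += a_
            nov[p_idx] += n_
    return EFEComponents(risk=risk, ambiguity=amb, novelty=nov), []


def policy_posterior(
    E: np.ndarray, F_vector: np.ndarray, G_vector: np.ndarray, gamma: float
) -> np.ndarray:
    """``Q(π) = σ(ln E − F_π − γ G_π)``."""
    E = np.asarray(E, dtype=float)
    F = np.asarray(F_vector, dtype=float)
    G = np.asarray(G_vector, dtype=float)
    if not (E.shape == F.shape == G.shape):
        raise ValueError("E, F and G must share their length")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return softmax(log_stable(E) - F - gamma * G)


def update_precision(
    precision: PrecisionState,
    E: np.ndarray,
    F_vector: np.ndarray,
    G_vector: np.ndarray,
    n_iter: int = 16,
) -> PrecisionState:
    """Iterate the precision fixed point, recording γ at every iteration.

    Each iteration computes the posterior ``Q = σ(ln E − F − γG)`` and the
    observation-free reference ``Q₀ = σ(ln E − γG)``, then sets
    ``β ← β_prior + (Q − Q₀) · G``.  When observations concentrate Q on
    low-G policies, β falls below its prior and γ rises — the phasic
    dopamine signature of increased confidence in the plan.
    """
    E = np.asarray(E, dtype=float)
    F = np.asarray(F_vector, dtype=float)
    G = np.asarray(G_vector, dtype=float)
    lnE = log_stable(E)
    out = PrecisionState(
        beta_prior=precision.beta_prior,
        beta=precision.beta,
        gamma_trace=list(precision.gamma_trace),
    )
    for _ in range(n_iter):
        gamma = out.gamma
        Q = softmax(lnE - F - gamma * G)
        Q0 = softmax(lnE - gamma * G)
        out.beta = max(precision.beta_prior + float((Q - Q0) @ G), BETA_FLOOR)
        out.gamma_trace.append(out.gamma)
    return out


def action_marginal(
    policy_posterior_: np.ndarray,
    policies: Sequence[Policy],
    step_index: int = 0,
    actions: Sequence[str] = ACTIONS,
) -> np.ndarray:
    """Marginal probability of each action at ``step_index`` under Q(π)."""
    if len(policies) == 0:
        raise ValueError("empty policy set")
    if step_index >= len(policies[0]):
        raise IndexError("step index beyond policy depth")
    q = np.asarray(policy_posterior_, dtype=float)
    marg = np.zeros(len(actions))
    lut = {u: i for i, u in enumerate(actions)}
    for qp, p in zip(q, policies):
        marg[lut[p[step_index]]] += qp
    return marg


def select_action(
    policy_posterior_: np.ndarray,
    policies: Sequence[Policy],
    step_index: int = 0,
    rng: Optional[np.random.Generator] = None,
    sample: bool = False,
) -> str:
    """Most probable action at ``step_index`` under the policy posterior.

    Deterministic argmax by default with ties broken by the documented action
    order; with ``sample=True`` the action is drawn from the marginal using
    the supplied seeded generator.
    """
    marg = action_marginal(policy_posterior_, policies, step_index)
    if sample:
        if rng is None:
            raise ValueError("sampling mode requires a seeded generator")
        return ACTIONS[int(rng.choice(len(ACTIONS), p=marg / marg.sum()))]
    return ACTIONS[int(np.argmax(marg))]
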