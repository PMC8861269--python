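"""Policy-conditioned state estimation by gradient descent on free energy.

Beliefs about the hidden location are held per policy ``π`` and per time point
``τ`` as a softmax of an unnormalised log-belief ``v`` (the "depolarisation"):
``s[π, τ] = σ(v[π, τ])``.  Each update computes a state prediction error

    ε[π, τ] = forward message + backward message + likelihood message − ln s[π, τ]

and moves ``v`` a fraction of the way along ε (mean-centred, exploiting the
softmax gauge).  The messages are the mean-field expectations

- forward:    ``ln B̄[u_{τ−1}] · s[π, τ−1]`` (``ln D`` at τ = 0),
- backward:   ``ln B̄[u_τ]ᵀ · s[π, τ+1]`` (absent at τ = T),
- likelihood: ``Σ_m ln Ā[m]ᵀ · o_τ[m]`` for observed time points τ ≤ t_now
  (omitted, not zero-filled, for future time points),

where the log-tables are digamma expectations whenever Dirichlet counts are
attached and floored logs otherwise.  With these messages ε is exactly the
negative gradient of the mean-field variational free energy, so sequential
(coordinate-wise) damped updates never increase F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._num import log_stable, softmax
from .generative_model import GenerativeModel

#: Default gradient-descent step size (fraction of the coordinate optimum).
DEFAULT_STEP_SIZE = 0.25

Observation = dict[str, np.ndarray]  # modality -> one-hot outcome vector


@dataclass
class BeliefState:
    """Per-policy, per-time-point state expectations.

    ``s[π, τ]`` is a probability vector over locations, ``v[π, τ]`` the
    matching unnormalised log-belief; ``s = softmax(v)`` always holds.
    """

    s: np.ndarray  # (n_policies, T+1, n_states)
    v: np.ndarray  # same shape

    @classmethod
    def uniform(cls, n_policies: int, n_times: int, n_states: int) -> "BeliefState":
        v = np.zeros((n_policies, n_times, n_states))
        return cls(s=softmax(v, axis=-1), v=v)

    def copy(self) -> "BeliefState":
        return BeliefState(s=self.s.copy(), v=self.v.copy())

    @property
    def n_policies(self) -> int:
        return self.s.shape[0]

    @property
    def n_times(self) -> int:
        return self.s.shape[1]


@dataclass
class PredictionError:
    """State prediction error for one (policy, time point)."""

    epsilon: np.ndarray


@dataclass
class BeliefTrace:
    """Ordered record of belief iterations.

    One entry per global iteration: the full (n_policies, T+1, n_states)
    arrays of ``s`` and ``v``.  The global iteration index is
    ``time-step index · iterations_per_step + within-step iteration``.
    """

    iterations: list[int] = field(default_factory=list)
    s: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)

    def append(self, iteration: int, beliefs: BeliefState) -> None:
        if self.iterations and iteration <= self.iterations[-1]:
            raise ValueError("global iteration index must be strictly increasing")
        self.iterations.append(iteration)
        self.s.append(beliefs.s.copy())
        self.v.append(beliefs.v.copy())

    def __len__(self) -> int:
        return len(self.iterations)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export with columns (iteration, policy, tau, state, s, v)."""
        rows = []
        for it, s, v in zip(self.iterations, self.s, self.v):
            P, T, N = s.shape
            idx = np.indices((P, T, N))
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": it,
                        "policy": idx[0].ravel(),
                        "tau": idx[1].ravel(),
                        "state": idx[2].ravel(),
                        "s": s.ravel(),
                        "v": v.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _log_tables(model: GenerativeModel):
    lnB = {u: model.transitions.mean_log(u) for u in model.transitions.actions}
    lnA = {m: model.likelihood.mean_log(m) for m in model.modalities}
    lnD = log_stable(np.asarray(model.priors.D, dtype=float))
    return lnA, lnB, lnD


def likelihood_message(model: GenerativeModel, observation: Observation) -> np.ndarray:
    """``Σ_m ln Ā[m]ᵀ · o`` — the evidence each observed outcome lends to
    every candidate location."""
    lnA, _, _ = _log_tables(model)
    msg = np.zeros(model.n_states)
    for m, o in observation.items():
        msg = msg + lnA[m].T @ np.asarray(o, dtype=float)
    return msg


def state_prediction_error(
    model: GenerativeModel,
    policy: Sequence[str],
    beliefs: BeliefState,
    observations: Sequence[Observation],
    tau: int,
    t_now: int,
    policy_index: int = 0,
) -> PredictionError:
    """Sum of the available messages at ``tau`` minus ``ln s[π, τ]``.

    ``policy`` is the full action sequence of the trial (action at step τ
    drives the τ → τ+1 transition).
    """
    T = beliefs.n_times - 1
    if not 0 <= tau <= T:
        raise IndexError(f"tau {tau} outside [0, {T}]")
    lnA, lnB, lnD = _log_tables(model)
    s = beliefs.s[policy_index]
    msg = np.zeros(model.n_states)
    if tau == 0:
        msg += lnD
    else:
        msg += lnB[policy[tau - 1]] @ s[tau - 1]
    if tau < T:
        msg += lnB[policy[tau]].T @ s[tau + 1]
    if tau <= t_now:
        for m, o in observations[tau].items():
            msg += lnA[m].T @ np.asarray(o, dtype=float)
    return PredictionError(epsilon=msg - log_stable(s[tau]))


def belief_iteration(
    beliefs: BeliefState,
    errors: np.ndarray,
    step_size: float = DEFAULT_STEP_SIZE,
    policy_index: int = 0,
    tau: Optional[int] = None,
) -> BeliefState:
    """One gradient step ``v ← v + η (ε − mean ε)``; ``s`` restored by softmax.

    Mean-centring the error leaves ``s`` unchanged for constant ε (softmax
    gauge) and keeps ``v`` bounded.  Mutates and returns ``beliefs``.
    """
    if not 0 < step_size <= 1:
        raise ValueError("step_size must lie in (0, 1]")
    eps = np.asarray(errors, dtype=float)
    delta = step_size * (eps - eps.mean(axis=-1, keepdims=True))
    if tau is None:
        beliefs.v[policy_index] += delta
        beliefs.s[policy_index] = softmax(beliefs.v[policy_index], axis=-1)
    else:
        beliefs.v[policy_index, tau] += delta
        beliefs.s[policy_index, tau] = softmax(beliefs.v[policy_index, tau])
    return beliefs


def infer_states(
    model: GenerativeModel,
    policies: Sequence[Sequence[str]],
    observations: Sequence[Observation],
    t_now: int,
    n_iter: Optional[int] = None,
    step_size: float = DEFAULT_STEP_SIZE,
    trace: Optional[BeliefTrace] = None,
    beliefs: Optional[BeliefState] = None,
    iteration_offset: int = 0,
    n_times: Optional[int] = None,
) -> tuple[BeliefState, BeliefTrace]:
    """Run ``iterations_per_step`` sweeps over all time points for every policy.

    Each sweep visits τ = 0..T in order (Gauss–Seidel), computing the state
    prediction error and applying a damped update; every iteration is appended
    to the trace.  Policies are full trial-length action sequences.
    """
    if n_times is None:
        n_times = (max(len(p) for p in policies) + 1) if policies else len(observations)
    T = n_times - 1
    if t_now > T:
        raise IndexError("t_now beyond the trial horizon")
    n_iter = model.iterations_per_step if n_iter is None else n_iter
    if beliefs is None:
        beliefs = BeliefState.uniform(len(policies), n_times, model.n_states)
    if trace is None:
        trace = BeliefTrace()
    for k in range(n_iter):
        for p_idx, policy in enumerate(policies):
            for tau in range(n_times):
                err = state_prediction_error(
                    model, policy, beliefs, observations, tau, t_now, p_idx
                )
                belief_iteration(beliefs, err.epsilon, step_size, p_idx, tau)
        trace.append(iteration_offset + k, beliefs)
    return beliefs, trace


def policy_free_energy(
    model: GenerativeModel,
    policy: Sequence[str],
    beliefs: BeliefState,
    observations: Sequence[Observation],
    t_now: int,
    policy_index: int = 0,
) -> float:
    """Variational free energy of one policy over the observed time points.

    ``F_π = Σ_{τ≤t_now} s[π,τ] · (ln s[π,τ] − forward message − likelihood
    message)`` — the complexity-minus-accuracy form.  It upper-bounds the
    negative log evidence of the observations under the policy and is
    non-increasing over belief iterations for fixed observations.
    """
    lnA, lnB, lnD = _log_tables(model)
    s = beliefs.s[policy_index]
    F = 0.0
    for tau in range(t_now + 1):
        fwd = lnD if tau == 0 else lnB[policy[tau - 1]] @ s[tau - 1]
        like = np.zeros(model.n_states)
        for m, o in observations[tau].items():
            like += lnA[m].T @ np.asarray(o, dtype=float)
        F += float(s[tau] @ (log_stable(s[tau]) - fwd - like))
    return F


def bayesian_model_average(
    beliefs: BeliefState, policy_posterior: np.ndarray
) -> np.ndarray:
    """Policy-posterior-weighted mixture of state beliefs, per time point.

    Returns an array of shape (T+1, n_states); each row sums to 1.
    """
    q = np.asarray(policy_posterior, dtype=float)
    if q.shape[0] != beliefs.n_policies:
        raise ValueError("policy posterior length mismatch")
    if abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("policy posterior must sum to 1")
    return np.einsum("p,ptn->tn", q, beliefs.s)
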