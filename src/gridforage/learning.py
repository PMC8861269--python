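"""Dirichlet concentration-parameter accumulation (associative plasticity).

Experience updates beliefs about the likelihood and transition mappings by
adding outer products of (posterior state expectation, observed outcome) —
``a ← a + η Σ_τ o_τ ⊗ s_τ`` — and analogously ``b[u] ← b[u] + η s_{τ+1} ⊗ s_τ``
for each executed action.  Counts only ever grow (no forgetting), and each
accumulated time point adds exactly ``η`` of total mass per modality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class LearningConfig:
    """What to learn and how fast.

    ``online`` applies updates after every observed step (so visited
    locations lose their novelty within a trial); when False, updates are
    deferred to the trial end (batch).
    """

    eta: float = 1.0
    learn_what: bool = True
    learn_transitions: bool = True
    online: bool = True

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")


def update_likelihood_counts(
    a: np.ndarray,
    belief_per_tau: Sequence[np.ndarray],
    outcome_per_tau: Sequence[np.ndarray],
    eta: float = 1.0,
) -> np.ndarray:
    """``a_ij ← a_ij + η Σ_τ o_τ[i] s_τ[j]`` with Bayesian-model-average
    beliefs; returns a new array."""
    a = np.asarray(a, dtype=float).copy()
    for s, o in zip(belief_per_tau, outcome_per_tau, strict=True):
        s = np.asarray(s, dtype=float)
        o = np.asarray(o, dtype=float)
        if (o.shape[0], s.shape[0]) != a.shape:
            raise ValueError("belief/outcome shape mismatch with a")
        a += eta * np.outer(o, s)
    return a


def update_transition_counts(
    b: dict[str, np.ndarray],
    belief_per_tau: Sequence[np.ndarray],
    actions: Sequence[str],
    eta: float = 1.0,
) -> dict[str, np.ndarray]:
    """``b[u]_ij ← b[u]_ij + η s_{τ+1}[i] s_τ[j]`` for the action executed at
    each τ; tables of unexecuted actions are returned unchanged."""
    out = {u: np.asarray(t, dtype=float).copy() for u, t in b.items()}
    for tau, u in enumerate(actions):
        if u not in out:
            continue
        s_now = np.asarray(belief_per_tau[tau], dtype=float)
        s_next = np.asarray(belief_per_tau[tau + 1], dtype=float)
        out[u] += eta * np.outer(s_next, s_now)
    return out
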