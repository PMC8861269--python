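"""POMDP generative model of the grid-world geocaching task.

The model has a single hidden-state factor — *location* on an ``n_rows × n_cols``
grid — and two outcome modalities:

``what``
    two levels, ``reward`` and ``null``; the true process emits ``reward`` only
    at the rewarding location.
``where``
    one level per location; the true mapping is the identity (the agent is told
    unambiguously where it is).

The arrays follow the conventional discrete-state-space parameterisation:

- ``A[m]`` — likelihood, column-stochastic over outcomes given location;
- ``B[u]`` — transitions, column-stochastic over next location given location,
  one table per action (up, down, left, right, stay);
- ``C[m]`` — prior preferences (utilities, natural-log relative probabilities);
- ``D``    — prior over the initial location;
- ``E``    — habit prior over policies.

Uncertain mappings carry Dirichlet concentration tables ``a[m]`` / ``b[u]`` of
the same shape; their categorical expectations and expected logs (digamma form)
are exposed through :func:`expected_likelihood` and
:func:`expected_log_likelihood`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma

from ._num import (
    STOCHASTIC_TOL,
    is_column_stochastic,
    log_stable,
    normalise_columns,
    softmax,
)

#: Documented action order; ties in action selection break in this order.
ACTIONS: tuple[str, ...] = ("up", "down", "left", "right", "stay")

#: Outcome levels of the ``what`` modality.
WHAT_LEVELS: tuple[str, str] = ("reward", "null")

#: Additive floor for transition concentration tables so that digamma
#: expectations of deterministic tables stay finite.
B_JITTER = 1e-4


class ModelConstructionError(ValueError):
    """Raised when arrays passed to a model constructor are inconsistent."""


@dataclass(frozen=True)
class GridGeometry:
    """Row-major indexing of an ``n_rows × n_cols`` grid.

    Location ``k`` maps to ``(row, col) = divmod(k, n_cols)``; ``(0, 0)`` is the
    top-left corner and the ``up`` action decreases the row index.
    """

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ModelConstructionError("grid dimensions must be positive")

    @property
    def n_locations(self) -> int:
        return self.n_rows * self.n_cols

    def to_rc(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.n_locations:
            raise IndexError(f"location index {index} out of range")
        return divmod(index, self.n_cols)

    def to_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) out of range")
        return row * self.n_cols + col

    def manhattan(self, i: int, j: int) -> int:
        ri, ci = self.to_rc(i)
        rj, cj = self.to_rc(j)
        return abs(ri - rj) + abs(ci - cj)

    def move(self, index: int, action: str) -> int:
        """Deterministic grid move with edge-stay (off-grid maps to stay)."""
        row, col = self.to_rc(index)
        if action == "up":
            row -= 1
        elif action == "down":
            row += 1
        elif action == "left":
            col -= 1
        elif action == "right":
            col += 1
        elif action != "stay":
            raise KeyError(f"unknown action {action!r}")
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return self.to_index(row, col)
        return index


@dataclass
class LikelihoodModel:
    """Per-modality likelihood tables with optional Dirichlet concentrations."""

    A: dict[str, np.ndarray]
    a: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, table in self.A.items():
            if not is_column_stochastic(table):
                raise ModelConstructionError(f"A[{m}] is not column-stochastic")
        for m, counts in self.a.items():
            if m not in self.A:
                raise ModelConstructionError(f"a[{m}] has no matching A table")
            if np.asarray(counts).shape != np.asarray(self.A[m]).shape:
                raise ModelConstructionError(f"a[{m}] shape mismatch")
            if np.any(np.asarray(counts) <= 0):
                raise ModelConstructionError(f"a[{m}] must be strictly positive")

    @property
    def modalities(self) -> list[str]:
        return list(self.A)

    def mean(self, m: str) -> np.ndarray:
        """Expected likelihood table (Dirichlet mean when counts exist)."""
        if m in self.a:
            return expected_likelihood(self.a[m])
        return self.A[m]

    def mean_log(self, m: str) -> np.ndarray:
        """Log of the posterior-predictive (Dirichlet-mean) table.

        Messages use the predictive distribution rather than the geometric
        expectation E[ln A]: at minuscule concentrations (1/100) the latter is
        ≈ ψ(a) − ψ(ā) ≈ −50 for *every* entry of an unvisited column, which
        would swamp the evidence of the other modalities; the predictive mean
        stays a proper categorical.  The geometric form remains available as
        :func:`expected_log_likelihood` and drives the novelty bound.
        """
        if m in self.a:
            return log_stable(expected_likelihood(self.a[m]))
        return log_stable(self.A[m])


@dataclass
class TransitionModel:
    """Per-action transition tables with optional Dirichlet concentrations."""

    B: dict[str, np.ndarray]
    b: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u in self.B:
            if u not in ACTIONS:
                raise ModelConstructionError(f"unknown action {u!r}")
            if not is_column_stochastic(self.B[u]):
                raise ModelConstructionError(f"B[{u}] is not column-stochastic")
        for u, counts in self.b.items():
            if u not in self.B:
                raise ModelConstructionError(f"b[{u}] has no matching B table")
            if np.asarray(counts).shape != np.asarray(self.B[u]).shape:
                raise ModelConstructionError(f"b[{u}] shape mismatch")
            if np.any(np.asarray(counts) <= 0):
                raise ModelConstructionError(f"b[{u}] must be strictly positive")

    @property
    def actions(self) -> list[str]:
        return list(self.B)

    def mean(self, u: str) -> np.ndarray:
        if u in self.b:
            return expected_likelihood(self.b[u])
        return self.B[u]

    def mean_log(self, u: str) -> np.ndarray:
        """Log of the posterior-predictive transition table (see
        :meth:`LikelihoodModel.mean_log` for why not the digamma form)."""
        if u in self.b:
            return log_stable(expected_likelihood(self.b[u]))
        return log_stable(self.B[u])


@dataclass
class PreferenceModel:
    """Utility vectors (log relative probabilities) per outcome modality."""

    C: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for m, c in self.C.items():
            if not np.all(np.isfinite(np.asarray(c, dtype=float))):
                raise ModelConstructionError(f"C[{m}] must be finite")

    def log_softmax(self, m: str) -> np.ndarray:
        """Normalised log preference distribution (softmax gauge removed)."""
        c = np.asarray(self.C[m], dtype=float)
        return c - np.log(np.sum(np.exp(c - c.max()))) - c.max()


@dataclass
class InitialAndHabitPriors:
    """D — prior over initial location; E — habit prior over policies."""

    D: np.ndarray
    E: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if np.any(D < 0) or abs(D.sum() - 1.0) > STOCHASTIC_TOL:
            raise ModelConstructionError("D must be a probability vector")
        if self.E is not None:
            E = np.asarray(self.E, dtype=float)
            if np.any(E < 0) or abs(E.sum() - 1.0) > STOCHASTIC_TOL:
                raise ModelConstructionError("E must be a probability vector")


@dataclass
class GenerativeModel:
    """Complete generative model for one grid-world task."""

    geometry: GridGeometry
    likelihood: LikelihoodModel
    transitions: TransitionModel
    preferences: PreferenceModel
    priors: InitialAndHabitPriors
    policy_depth: int = 4
    iterations_per_step: int = 16
    target_location: Optional[int] = None

    def __post_init__(self) -> None:
        n = self.geometry.n_locations
        for m, table in self.likelihood.A.items():
            if np.asarray(table).shape[1] != n:
                raise ModelConstructionError(f"A[{m}] must have {n} columns")
        for u, table in self.transitions.B.items():
            if np.asarray(table).shape != (n, n):
                raise ModelConstructionError(f"B[{u}] must be {n}×{n}")
        if np.asarray(self.priors.D).shape != (n,):
            raise ModelConstructionError(f"D must have length {n}")
        if self.policy_depth < 1:
            raise ModelConstructionError("policy_depth must be ≥ 1")
        if self.iterations_per_step < 1:
            raise ModelConstructionError("iterations_per_step must be ≥ 1")

    @property
    def n_states(self) -> int:
        return self.geometry.n_locations

    @property
    def modalities(self) -> list[str]:
        return self.likelihood.modalities

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def arrs(d):
            return {k: np.asarray(v).tolist() for k, v in d.items()}

        return {
            "geometry": {"n_rows": self.geometry.n_rows, "n_cols": self.geometry.n_cols},
            "A": arrs(self.likelihood.A),
            "a": arrs(self.likelihood.a),
            "B": arrs(self.transitions.B),
            "b": arrs(self.transitions.b),
            "C": arrs(self.preferences.C),
            "D": np.asarray(self.priors.D).tolist(),
            "E": None if self.priors.E is None else np.asarray(self.priors.E).tolist(),
            "policy_depth": self.policy_depth,
            "iterations_per_step": self.iterations_per_step,
            "target_location": self.target_location,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeModel":
        geom = GridGeometry(**d["geometry"])
        arr = lambda x: np.asarray(x, dtype=float)  # noqa: E731
        return cls(
            geometry=geom,
            likelihood=LikelihoodModel(
                A={m: arr(t) for m, t in d["A"].items()},
                a={m: arr(t) for m, t in d.get("a", {}).items()},
            ),
            transitions=TransitionModel(
                B={u: arr(t) for u, t in d["B"].items()},
                b={u: arr(t) for u, t in d.get("b", {}).items()},
            ),
            preferences=PreferenceModel(C={m: arr(c) for m, c in d["C"].items()}),
            priors=InitialAndHabitPriors(
                D=arr(d["D"]), E=None if d.get("E") is None else arr(d["E"])
            ),
            policy_depth=int(d["policy_depth"]),
            iterations_per_step=int(d["iterations_per_step"]),
            target_location=d.get("target_location"),
        )

    @classmethod
    def load(cls, path) -> "GenerativeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- Dirichlet expectations (the two branches of the conjugate update) -----


def expected_likelihood(a: np.ndarray) -> np.ndarray:
    """Categorical expectation of a Dirichlet-parameterised table.

    Column ``j`` of the result is ``a[:, j] / a[:, j].sum()``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("concentration parameters must be strictly positive")
    s = a.sum(axis=0, keepdims=True)
    if np.any(s == 0):
        raise ValueError("zero column sum")
    return a / s


def expected_log_likelihood(a: np.ndarray) -> np.ndarray:
    """Expected elementwise log of a Dirichlet-parameterised table.

    ``E[ln A_ij] = ψ(a_ij) − ψ(Σ_k a_kj)`` with ψ the digamma function.  Each
    entry lies below the log of the Dirichlet mean (Jensen) and approaches it
    as the counts grow.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("concentration parameters must be strictly positive")
    return digamma(a) - digamma(a.sum(axis=0, keepdims=True))


def ambiguity_vector(A: dict[str, np.ndarray] | np.ndarray) -> np.ndarray:
    """Outcome entropy H_j = −Σ_i A_ij ln A_ij per location, summed over
    modalities (the aleatoric-uncertainty vector entering expected free
    energy).  Zero exactly when every modality maps the location
    deterministically."""
    if isinstance(A, np.ndarray):
        A = {"": A}
    H = None
    for table in A.values():
        table = np.asarray(table, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(table > 0, table * np.log(table), 0.0)
        h = -term.sum(axis=0)
        H = h if H is None else H + h
    return np.maximum(H, 0.0)


# -- geocaching instantiation ---------------------------------------------


def build_geocache_model(
    geometry: GridGeometry,
    target_location: int,
    utilities: Sequence[float] = (3.0, 0.0),
    dirichlet_prior_scale: Optional[float] = None,
    transition_prior_scale: Optional[float] = None,
    proximity_weight: float = 0.25,
    start_location: Optional[int] = None,
    policy_depth: int = 4,
    iterations_per_step: int = 16,
) -> GenerativeModel:
    """Build the grid-world generative model.

    Parameters
    ----------
    geometry
        Grid shape; the hidden-state space is its set of locations.
    target_location
        The rewarding location (navigation target or hidden object).
    utilities
        ``C[what]`` utilities for (reward, null); the default ``(3, 0)`` makes
        reward about 20 times more expected than null.
    dirichlet_prior_scale
        When given, the ``what`` likelihood is unknown with a uniform Dirichlet
        prior at this concentration (1/100 in the foraging condition); when
        absent the map is known exactly.
    transition_prior_scale
        When given, every transition table carries Dirichlet counts
        ``scale · B_true + jitter`` (uncertain contingencies).
    proximity_weight
        Weight of the graded preference for being near the target:
        ``C[where](loc) = −weight · ManhattanDistance(loc, target)``.  Zero
        disables it (used in the foraging patch, where the rewarding location
        is unknown to the agent).
    start_location
        When given, ``D`` is a delta at this location; otherwise uniform.
    """
    if dirichlet_prior_scale is not None and dirichlet_prior_scale <= 0:
        raise ModelConstructionError("dirichlet_prior_scale must be positive")
    if transition_prior_scale is not None and transition_prior_scale <= 0:
        raise ModelConstructionError("transition_prior_scale must be positive")
    n = geometry.n_locations
    if not 0 <= target_location < n:
        raise ModelConstructionError("target_location outside the grid")

    # where: identity mapping (location observed unambiguously).
    A_where = np.eye(n)
    # what: reward only at the target.
    A_what = np.zeros((2, n))
    A_what[0, target_location] = 1.0
    A_what[1, :] = 1.0
    A_what[1, target_location] = 0.0

    a = {}
    if dirichlet_prior_scale is not None:
        a["what"] = np.full((2, n), float(dirichlet_prior_scale))

    B: dict[str, np.ndarray] = {}
    b: dict[str, np.ndarray] = {}
    for u in ACTIONS:
        table = np.zeros((n, n))
        for j in range(n):
            table[geometry.move(j, u), j] = 1.0
        B[u] = table
        if transition_prior_scale is not None:
            b[u] = transition_prior_scale * table + B_JITTER

    C_what = np.asarray(utilities, dtype=float)
    if C_what.shape != (2,):
        raise ModelConstructionError("utilities must have two entries")
    dist = np.array([geometry.manhattan(j, target_location) for j in range(n)], float)
    C_where = -float(proximity_weight) * dist

    D = np.full(n, 1.0 / n)
    if start_location is not None:
        D = np.zeros(n)
        D[start_location] = 1.0

    return GenerativeModel(
        geometry=geometry,
        likelihood=LikelihoodModel(A={"what": A_what, "where": A_where}, a=a),
        transitions=TransitionModel(B=B, b=b),
        preferences=PreferenceModel(C={"what": C_what, "where": C_where}),
        priors=InitialAndHabitPriors(D=D),
        policy_depth=policy_depth,
        iterations_per_step=iterations_per_step,
        target_location=target_location,
    )


def preference_ratio(model: GenerativeModel, modality: str = "what") -> float:
    """Ratio of softmax preference masses between the first two outcome
    levels of ``modality`` (≈ e³ ≈ 20 for the default utilities)."""
    p = softmax(np.asarray(model.preferences.C[modality], dtype=float))
    return float(p[0] / p[1])
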