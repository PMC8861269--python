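"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: Log-floor applied before taking logarithms of probability tables.  A value
#: of e^-32 keeps deterministic (zero-containing) tables finite while being
#: far below any probability the softmax dynamics can resolve.
LOG_FLOOR = np.exp(-32.0)

#: Tolerance for column-stochasticity checks.
STOCHASTIC_TOL = 1e-10


def softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    v = np.asarray(v, dtype=float)
    m = np.max(v, axis=axis, keepdims=True)
    e = np.exp(v - m)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_stable(p: np.ndarray) -> np.ndarray:
    """Elementwise log with the probabilities floored at ``LOG_FLOOR``."""
    return np.log(np.maximum(np.asarray(p, dtype=float), LOG_FLOOR))


def is_column_stochastic(table: np.ndarray, tol: float = STOCHASTIC_TOL) -> bool:
    """True when every column of ``table`` is a probability vector."""
    table = np.asarray(table, dtype=float)
    if np.any(table < -tol):
        return False
    return bool(np.all(np.abs(table.sum(axis=0) - 1.0) <= tol))


def normalise_columns(table: np.ndarray) -> np.ndarray:
    """Divide each column by its sum (zero columns become uniform)."""
    table = np.asarray(table, dtype=float)
    s = table.sum(axis=0, keepdims=True)
    out = np.where(s > 0, table / np.where(s == 0, 1.0, s), 1.0 / table.shape[0])
    return out


def entropy_of(p: np.ndarray) -> float:
    """Shannon entropy (nats) with the 0·log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))
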