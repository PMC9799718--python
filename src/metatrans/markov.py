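"""Continuous-time Markov machinery: generators, P(t) = exp(Qt), sojourns.

The process is a time-homogeneous CTMC on the six phenotypes with generator
(intensity matrix) Q: off-diagonal q_rs ≥ 0 is the instantaneous per-year
rate of moving r → s (zero off the 14-edge adjacency mask), and each row
sums to zero, q_rr = −Σ_{s≠r} q_rs.  Over a finite interval the transition
probability matrix is the matrix exponential P(t) = exp(Qt), computed by
scaling-and-squaring with Padé approximation (scipy.linalg.expm).  The mean
sojourn time in state r is −1/q_rr, the mean of the exponential holding
time; there is no absorbing state in this model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .states import (
    N_STATES,
    STATE_LABELS,
    TransitionStructure,
    six_state_structure,
    state_index,
)

__all__ = [
    "build_intensity",
    "validate_intensity",
    "transition_probability",
    "sojourn_times",
    "predict_state_distribution",
    "intensity_to_frame",
]


def build_intensity(rates, structure: TransitionStructure | None = None) -> np.ndarray:
    """Assemble a generator from per-edge rates.

    ``rates`` is either an array aligned with ``structure.edge_list`` or a
    mapping {(origin, destination): rate} keyed by labels or 0-based indices.
    The diagonal is filled so every row sums to zero.
    """
    structure = structure or six_state_structure()
    n = structure.n_states
    Q = np.zeros((n, n))
    edges = structure.edge_list
    if isinstance(rates, dict):
        label_to_idx = {lab: i for i, lab in enumerate(structure.labels)}
        for key, rate in rates.items():
            r, s = key
            i = label_to_idx[r] if isinstance(r, str) else int(r)
            j = label_to_idx[s] if isinstance(s, str) else int(s)
            if not structure.allowed[i, j]:
                raise ValueError(f"edge {key} is not in the transition structure")
            Q[i, j] = rate
    else:
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (len(edges),):
            raise ValueError(
                f"expected {len(edges)} edge rates, got shape {rates.shape}"
            )
        for (i, j), rate in zip(edges, rates):
            Q[i, j] = rate
    if (Q[structure.allowed] < 0).any():
        raise ValueError("edge rates must be non-negative")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def validate_intensity(
    Q: np.ndarray,
    structure: TransitionStructure | None = None,
    atol: float = 1e-10,
) -> np.ndarray:
    """Check generator validity (shape, sign pattern, zero row sums, and the
    structural zeros if a structure is given); returns Q as ndarray."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    if not np.isfinite(Q).all():
        raise ValueError("Q must be finite")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < -atol).any():
        raise ValueError("off-diagonal intensities must be non-negative")
    if np.abs(Q.sum(axis=1)).max() > max(atol, 1e-9 * max(1.0, np.abs(Q).max())):
        raise ValueError("rows of Q must sum to zero")
    if structure is not None:
        if Q.shape[0] != structure.n_states:
            raise ValueError("Q size does not match structure")
        disallowed = ~structure.allowed & ~np.eye(structure.n_states, dtype=bool)
        if np.abs(Q[disallowed]).max(initial=0.0) > atol:
            raise ValueError("Q has nonzero entries on disallowed edges")
    return Q


def transition_probability(
    Q: np.ndarray,
    t: float,
    structure: TransitionStructure | None = None,
) -> np.ndarray:
    """P(t) = exp(Qt): probability of being in state s at time t given state
    r at time 0.  Rows sum to one; all entries lie in [0, 1]."""
    Q = validate_intensity(Q, structure=structure)
    t = float(t)
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if t == 0.0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    # clean up tiny negative round-off without disturbing genuine entries
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def sojourn_times(Q: np.ndarray) -> np.ndarray:
    """Mean sojourn time per state, −1/q_rr (years).

    A zero diagonal entry (absorbing state) yields ``inf`` — the explicit
    infinite-sojourn signal; the phenotype model itself has no absorbing
    state."""
    Q = validate_intensity(Q)
    d = np.diag(Q)
    out = np.full(Q.shape[0], np.inf)
    nz = d < 0
    out[nz] = -1.0 / d[nz]
    return out


def predict_state_distribution(
    Q: np.ndarray,
    origin,
    horizon: float,
    step: float = 1.0,
    structure: TransitionStructure | None = None,
) -> pd.DataFrame:
    """Occupancy probabilities over a time grid for one origin state.

    Returns a long-format frame (origin, time, destination, probability);
    each time's six probabilities sum to one.  ``origin`` may be a label,
    1-based index or PhenotypeState.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if not 0 < step <= horizon:
        raise ValueError("step must satisfy 0 < step <= horizon")
    labels = structure.labels if structure is not None else STATE_LABELS
    o = state_index(origin) - 1 if len(labels) == N_STATES else int(origin) - 1
    n_steps = int(round(horizon / step))
    times = np.arange(0, n_steps + 1) * step
    rows = []
    for t in times:
        p = transition_probability(Q, float(t), structure=structure)[o]
        for j, lab in enumerate(labels):
            rows.append((labels[o], float(t), lab, float(p[j])))
    return pd.DataFrame(rows, columns=["origin", "time", "destination", "probability"])


def intensity_to_frame(Q: np.ndarray, labels: tuple = STATE_LABELS) -> pd.DataFrame:
    """Labelled 6×6 view of a generator for TSV serialisation."""
    return pd.DataFrame(np.asarray(Q, dtype=float), index=list(labels), columns=list(labels))
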