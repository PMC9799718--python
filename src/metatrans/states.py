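"""State space and transition structure for metabolism-weight phenotypes.

Six mutually exclusive phenotypes are cross-defined by a weight category
(normal weight / overweight / obese, Chinese BMI cut-offs 24 and 28 kg/m²)
and a metabolic status (healthy / unhealthy under the revised NCEP ATP III
criteria, abdominal obesity excluded):

    index 1  MHNW  metabolically healthy normal weight
    index 2  MHOW  metabolically healthy overweight
    index 3  MHO   metabolically healthy obesity
    index 4  MUNW  metabolically unhealthy normal weight
    index 5  MUOW  metabolically unhealthy overweight
    index 6  MUO   metabolically unhealthy obesity

Instantaneous transitions are only allowed between *adjacent* phenotypes on
the 2×3 grid: horizontal moves change the weight category by one level while
the metabolic status is kept, vertical moves flip the metabolic status while
the weight category is kept.  That yields exactly 14 directed edges; diagonal
or weight-skipping moves have structurally zero intensity (though they can
still occur over a finite interval through intermediate states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WEIGHT_LABELS = ("normal", "overweight", "obese")
METABOLIC_LABELS = ("healthy", "unhealthy")

#: Fixed state order; index in this tuple + 1 is the 1-based state index.
STATE_LABELS = ("MHNW", "MHOW", "MHO", "MUNW", "MUOW", "MUO")

N_STATES = len(STATE_LABELS)


@dataclass(frozen=True)
class PhenotypeState:
    """One of the six phenotypes, addressed by (weight_level, metabolic_level).

    weight_level: 0 = normal, 1 = overweight, 2 = obese.
    metabolic_level: 0 = healthy, 1 = unhealthy.
    """

    weight_level: int
    metabolic_level: int

    def __post_init__(self) -> None:
        if self.weight_level not in (0, 1, 2):
            raise ValueError(f"weight_level must be 0, 1 or 2, got {self.weight_level}")
        if self.metabolic_level not in (0, 1):
            raise ValueError(
                f"metabolic_level must be 0 or 1, got {self.metabolic_level}"
            )

    @property
    def index(self) -> int:
        """1-based state index in the fixed MHNW..MUO order."""
        return self.metabolic_level * 3 + self.weight_level + 1

    @property
    def label(self) -> str:
        return STATE_LABELS[self.index - 1]

    @classmethod
    def from_label(cls, label: str) -> "PhenotypeState":
        try:
            idx = STATE_LABELS.index(label.upper())
        except ValueError:
            raise ValueError(f"unknown phenotype label {label!r}") from None
        return cls.from_index(idx + 1)

    @classmethod
    def from_index(cls, index: int) -> "PhenotypeState":
        if not 1 <= index <= N_STATES:
            raise ValueError(f"state index must be in 1..{N_STATES}, got {index}")
        i = index - 1
        return cls(weight_level=i % 3, metabolic_level=i // 3)


def state_index(state) -> int:
    """Coerce a label, 1-based index or PhenotypeState to a 1-based index."""
    if isinstance(state, PhenotypeState):
        return state.index
    if isinstance(state, str):
        return PhenotypeState.from_label(state).index
    idx = int(state)
    if not 1 <= idx <= N_STATES:
        raise ValueError(f"state index must be in 1..{N_STATES}, got {state}")
    return idx


@dataclass(frozen=True)
class TransitionStructure:
    """Sparsity pattern of a multistate generator.

    ``allowed`` is an (n, n) boolean mask of permitted instantaneous
    transitions (diagonal always False); ``edge_list`` enumerates the allowed
    (origin, destination) pairs in row-major order, 0-based.
    """

    allowed: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.allowed, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("allowed mask must be square")
        if a.diagonal().any():
            raise ValueError("diagonal entries cannot be allowed edges")
        object.__setattr__(self, "allowed", a)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"S{i + 1}" for i in range(a.shape[0]))
            )
        elif len(self.labels) != a.shape[0]:
            raise ValueError("labels length must match mask size")

    @property
    def n_states(self) -> int:
        return self.allowed.shape[0]

    @property
    def edge_list(self) -> tuple:
        """Allowed (origin, destination) pairs, 0-based, row-major order."""
        return tuple(zip(*np.nonzero(self.allowed)))

    @property
    def n_edges(self) -> int:
        return int(self.allowed.sum())

    def edge_labels(self) -> list:
        return [(self.labels[i], self.labels[j]) for i, j in self.edge_list]


def six_state_structure() -> TransitionStructure:
    """The 14-edge adjacency of the 2×3 metabolism-weight grid."""
    allowed = np.zeros((N_STATES, N_STATES), dtype=bool)
    for idx in range(N_STATES):
        w, m = idx % 3, idx // 3
        for dw in (-1, 1):  # horizontal: weight level ±1, same metabolic row
            if 0 <= w + dw <= 2:
                allowed[idx, m * 3 + (w + dw)] = True
        allowed[idx, (1 - m) * 3 + w] = True  # vertical: metabolic flip
    return TransitionStructure(allowed=allowed, labels=STATE_LABELS)


def chain_structure(n_states: int, labels: tuple = ()) -> TransitionStructure:
    """Birth-death chain on ``n_states`` states (used for small test models)."""
    allowed = np.zeros((n_states, n_states), dtype=bool)
    for i in range(n_states - 1):
        allowed[i, i + 1] = True
        allowed[i + 1, i] = True
    return TransitionStructure(allowed=allowed, labels=labels)
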