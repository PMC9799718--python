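"""Bundled reference tabulations from a longitudinal health check-up cohort.

These are the printed summary tables of a real cohort of 9,742 Chinese
adults (aged 20–60 at entry, check-ups 2010–2017, ~annual visits): the
baseline phenotype composition, the observed visit-to-visit transition
frequency table, the fitted mean sojourn times and the six printed metabolic
transition intensities.  The raw subject-level data behind them are not
publicly deposited, so the tables serve three roles here:

* worked-example inputs for the descriptive operations,
* validation anchors (the tabulation code must reproduce every printed
  percentage exactly at two decimals), and
* anchors for the synthetic cohort generator's default configuration.

``reference_transition_panel`` and ``reference_baseline_panel`` rebuild
minimal :class:`~metatrans.panel.PanelDataset` objects whose tabulations
reproduce the printed counts (one two-visit pseudo-subject per observed
transition pair; they carry no biochemistry and are *not* the real cohort).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import PanelDataset
from .states import STATE_LABELS

__all__ = [
    "reference_baseline_counts",
    "reference_transition_counts",
    "reference_sojourn_table",
    "reference_metabolic_intensities",
    "reference_baseline_distribution",
    "reference_transition_panel",
    "reference_baseline_panel",
]


def reference_baseline_counts() -> np.ndarray:
    """Baseline phenotype counts (MHNW..MUO); total 9,742 subjects."""
    return np.array([4387, 1761, 351, 918, 1552, 773])


def reference_baseline_distribution() -> np.ndarray:
    """Baseline phenotype proportions (printed percentages, renormalised)."""
    p = np.array([0.4503, 0.1808, 0.0360, 0.0942, 0.1593, 0.0793])
    return p / p.sum()


def reference_transition_counts() -> np.ndarray:
    """Observed transition frequency table n[origin, follow-up] over all
    consecutive check-up pairs (≈1-year intervals); 25,985 pairs in total."""
    return np.array(
        [
            [9234, 877, 23, 1069, 278, 32],
            [660, 2904, 192, 107, 1017, 102],
            [18, 149, 449, 4, 54, 300],
            [943, 148, 3, 1164, 231, 6],
            [251, 948, 68, 201, 2380, 236],
            [28, 104, 275, 7, 197, 1326],
        ]
    )


def reference_sojourn_table() -> pd.DataFrame:
    """Fitted mean sojourn time per phenotype (years) with SE and 95% CI."""
    data = {
        "mean": [3.84, 1.56, 1.16, 1.23, 1.59, 2.34],
        "se": [0.09, 0.04, 0.06, 0.04, 0.04, 0.11],
        "lower": [3.69, 1.48, 1.06, 1.16, 1.51, 2.15],
        "upper": [4.02, 1.63, 1.28, 1.30, 1.68, 2.56],
    }
    return pd.DataFrame(data, index=list(STATE_LABELS))


def reference_metabolic_intensities() -> dict:
    """The six printed per-year intensities on the vertical (metabolic) edges.

    Deterioration runs down the grid (healthy → unhealthy at fixed weight),
    improvement runs up.  The improvement rate printed as 0.44 belongs to the
    MUOW→MHOW edge (the only grid-adjacent reading)."""
    return {
        ("MHNW", "MUNW"): 0.15,
        ("MHOW", "MUOW"): 0.38,
        ("MHO", "MUO"): 0.56,
        ("MUNW", "MHNW"): 0.64,
        ("MUOW", "MHOW"): 0.44,
        ("MUO", "MHO"): 0.27,
    }


def reference_transition_panel() -> PanelDataset:
    """A panel of two-visit pseudo-subjects reproducing the printed
    transition-count table: one subject per observed (origin, follow-up)
    pair, visits at 0 and 1 year."""
    counts = reference_transition_counts()
    origins, dests = np.nonzero(counts)
    reps = counts[origins, dests]
    s0 = np.repeat(origins + 1, reps)
    s1 = np.repeat(dests + 1, reps)
    n = len(s0)
    ids = np.arange(n)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(ids, 2),
            "time": np.tile([0.0, 1.0], n),
            "state": np.stack([s0, s1], axis=1).ravel(),
        }
    )
    return PanelDataset(df)


def reference_baseline_panel() -> PanelDataset:
    """A panel whose baseline composition equals the printed baseline counts
    (each pseudo-subject observed twice in the same state)."""
    counts = reference_baseline_counts()
    states = np.repeat(np.arange(1, 7), counts)
    n = len(states)
    ids = np.arange(n)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(ids, 2),
            "time": np.tile([0.0, 1.0], n),
            "state": np.repeat(states, 2),
        }
    )
    return PanelDataset(df)
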