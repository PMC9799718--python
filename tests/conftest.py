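import numpy as np
import pandas as pd
import pytest

from metatrans import GeneratorConfig, PanelDataset, fit, simulate_cohort


@pytest.fixture(scope="session")
def recovery_run():
    """Shared expensive fixture: the standard recovery experiment.

    2,000 subjects with 6 exactly-annual visits simulated from the default
    generator, then refitted without covariates.  Used by the recovery and
    goodness-of-fit tests.
    """
    cfg = GeneratorConfig(
        n_subjects=2000, seed=0, visit_count=6, interval_jitter_sd=0.0
    )
    cohort = simulate_cohort(cfg)
    fitted = fit(cohort.panel)
    return cfg, cohort, fitted


def make_panel(sequences, n_states=6, times=None, covariates=None):
    """Build a PanelDataset from per-subject state sequences (1-based)."""
    rows = []
    for sid, states in enumerate(sequences):
        ts = times[sid] if times is not None else list(range(len(states)))
        for t, s in zip(ts, states):
            rows.append((sid, float(t), int(s)))
    df = pd.DataFrame(rows, columns=["subject_id", "time", "state"])
    if covariates:
        for name, values in covariates.items():
            df[name] = np.asarray(values)[df["subject_id"].to_numpy()]
    return PanelDataset(df, n_states=n_states)


@pytest.fixture
def two_state_one_way():
    """Structure allowing only 1 -> 2 (one free rate)."""
    from metatrans import TransitionStructure

    allowed = np.array([[False, True], [False, False]])
    return TransitionStructure(allowed=allowed, labels=("S1", "S2"))
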