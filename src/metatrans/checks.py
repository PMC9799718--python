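"""Goodness-of-fit: observed vs. model-expected phenotype prevalence.

The assessment is the standard multistate-model prevalence comparison: at
each grid time t, the *observed* percentage of each state is computed over
subjects still under observation (last visit ≥ t), carrying each subject's
most recent observed state forward; the *expected* percentage averages, over
the same subjects, the model's occupancy probabilities P_z(t)[baseline
state, ·] using each subject's baseline covariates.  Closeness of the two
curve families indicates a well-fitting model; the discrepancy is summarised
by the maximum absolute gap per state (the assessment is visual/descriptive,
not a formal test).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import FittedModel
from .markov import transition_probability, validate_intensity
from .panel import PanelDataset

__all__ = [
    "observed_prevalence",
    "expected_prevalence",
    "prevalence_comparison",
    "max_absolute_gap",
]


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if (times < 0).any():
        raise ValueError("grid times must be non-negative")
    return times


def _subject_arrays(panel: PanelDataset):
    df = panel.data
    ids, starts = np.unique(df["subject_id"].to_numpy(), return_index=True)
    order = np.argsort(starts)
    ids = ids[order]
    starts = np.sort(starts)
    bounds = np.append(starts, len(df))
    times = df["time"].to_numpy(dtype=float)
    states = df["state"].to_numpy(dtype=int)
    return ids, bounds, times, states


def observed_prevalence(panel: PanelDataset, times) -> pd.DataFrame:
    """Observed state percentages over subjects under observation at each
    grid time (last observed state carried forward).

    Returns a frame indexed by time with one column per state label plus
    ``n`` (subjects contributing).  A grid time past every subject's last
    visit yields an empty denominator, signalled by n = 0 and NaN rows.
    """
    times = _check_times(times)
    n_states = panel.n_states
    _, bounds, vtimes, states = _subject_arrays(panel)
    n_subj = len(bounds) - 1
    labels = _labels(panel)
    rows = []
    for t in times:
        counts = np.zeros(n_states)
        n_obs = 0
        for s in range(n_subj):
            lo, hi = bounds[s], bounds[s + 1]
            if vtimes[hi - 1] < t:  # dropped out of observation
                continue
            k = np.searchsorted(vtimes[lo:hi], t, side="right")
            if k == 0:
                continue  # not yet entered (cannot happen with baseline 0)
            counts[states[lo + k - 1] - 1] += 1
            n_obs += 1
        if n_obs:
            rows.append([t, *(100.0 * counts / n_obs), n_obs])
        else:
            rows.append([t, *([np.nan] * n_states), 0])
    out = pd.DataFrame(rows, columns=["time", *labels, "n"]).set_index("time")
    out["n"] = out["n"].astype(int)
    return out


def expected_prevalence(model, panel: PanelDataset, times) -> pd.DataFrame:
    """Model-expected state percentages at each grid time.

    ``model`` is a :class:`FittedModel` or a plain generator matrix Q.  Each
    subject under observation at t contributes the row of P_z(t) for its
    baseline state and baseline covariates; percentages average those rows.
    """
    times = _check_times(times)
    n_states = panel.n_states
    labels = _labels(panel)
    base = panel.baseline()
    base_states = base["state"].to_numpy(dtype=int) - 1

    if isinstance(model, FittedModel):
        covs = model.spec.covariates
        if covs:
            missing = sorted(set(covs) - set(base.columns))
            if missing:
                raise KeyError(f"panel lacks covariate columns: {missing}")
            Zb = base[list(covs)].to_numpy(dtype=float)
        else:
            Zb = np.zeros((len(base), 0))
        patterns, inverse = np.unique(Zb, axis=0, return_inverse=True)
        Qs = [model.intensity_matrix(z if len(z) else None) for z in patterns]
    else:
        Q = validate_intensity(model)
        patterns = np.zeros((1, 0))
        inverse = np.zeros(len(base), dtype=int)
        Qs = [Q]

    # under-observation mask per subject per time
    last_time = panel.data.groupby("subject_id", sort=False)["time"].max().to_numpy()

    rows = []
    for t in times:
        Ps = [transition_probability(Q, float(t)) for Q in Qs]
        under = last_time >= t
        n_obs = int(under.sum())
        if n_obs == 0:
            rows.append([t, *([np.nan] * n_states), 0])
            continue
        occ = np.zeros(n_states)
        for g in range(len(patterns)):
            sel = under & (inverse == g)
            if sel.any():
                occ += Ps[g][base_states[sel]].sum(axis=0)
        rows.append([t, *(100.0 * occ / n_obs), n_obs])
    out = pd.DataFrame(rows, columns=["time", *labels, "n"]).set_index("time")
    out["n"] = out["n"].astype(int)
    return out


def prevalence_comparison(
    model, panel: PanelDataset, times=None
) -> pd.DataFrame:
    """Long-format (time, state, observed, expected, n) table; default grid
    is yearly from 0 to the panel's follow-up span (capped at 7 years)."""
    if times is None:
        span = float(panel.data["time"].max())
        times = np.arange(0.0, min(span, 7.0) + 1e-9, 1.0)
    obs = observed_prevalence(panel, times)
    exp_ = expected_prevalence(model, panel, times)
    labels = _labels(panel)
    rows = []
    for t in obs.index:
        for lab in labels:
            rows.append(
                (t, lab, obs.loc[t, lab], exp_.loc[t, lab], int(obs.loc[t, "n"]))
            )
    return pd.DataFrame(rows, columns=["time", "state", "observed", "expected", "n"])


def max_absolute_gap(comparison: pd.DataFrame) -> pd.Series:
    """Per-state max |observed − expected| over the grid (percentage points)."""
    d = comparison.dropna(subset=["observed", "expected"]).copy()
    d["gap"] = (d["observed"] - d["expected"]).abs()
    return d.groupby("state", sort=False)["gap"].max()


def _labels(panel: PanelDataset):
    from .states import N_STATES, STATE_LABELS

    if panel.n_states == N_STATES:
        return list(STATE_LABELS)
    return [f"S{i+1}" for i in range(panel.n_states)]


def plot_prevalence(comparison: pd.DataFrame, path=None):
    """Optional visual: observed (solid) vs expected (dashed) per state.

    Requires matplotlib (the ``plot`` extra); returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    states = list(dict.fromkeys(comparison["state"]))
    fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
    for ax, state in zip(axes.ravel(), states):
        sub = comparison[comparison["state"] == state]
        ax.plot(sub["time"], sub["observed"], "-", label="observed")
        ax.plot(sub["time"], sub["expected"], "--", label="expected")
        ax.set_title(state)
        ax.set_xlabel("years")
        ax.set_ylabel("%")
    axes.ravel()[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
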