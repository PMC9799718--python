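"""Cohort eligibility filtering, panel assembly and descriptive tabulations.

A *panel* is the interval-censored observation scheme of the cohort: each
subject contributes an ordered sequence of (visit time in years since that
subject's first visit, phenotype state 1–6, covariate vector).  States are
only known at visit snapshots; nothing is observed in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .phenotyping import COVARIATE_NAMES, classify_checkups
from .states import N_STATES, STATE_LABELS

__all__ = [
    "PanelDataset",
    "TransitionCountMatrix",
    "BaselineSummary",
    "round_half_up",
    "filter_eligible",
    "tabulate_transitions",
    "baseline_summary",
    "stratify",
]

_ELIGIBILITY_COLUMNS = (
    "sex",
    "age",
    "bmi",
    "sbp",
    "dbp",
    "fpg",
    "tg",
    "hdl",
    "alt",
    "ast",
    "scr",
    "ua",
)


def round_half_up(x, ndigits: int = 2):
    """Decimal round-half-up (the convention of the printed tables; numpy's
    banker's rounding would turn e.g. 0.125 into 0.12)."""
    q = Decimal(1).scaleb(-ndigits)

    def _one(v: float) -> float:
        return float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))

    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return _one(float(arr))
    return np.vectorize(_one)(arr)


@dataclass
class PanelDataset:
    """Per-subject ordered state sequences with covariates.

    ``data`` columns: ``subject_id``, ``time`` (years from the subject's
    baseline, strictly increasing within subject), ``state`` (1-based index)
    and any covariate columns.  Every subject has at least two visits.
    """

    data: pd.DataFrame
    n_states: int = N_STATES

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "time", "state"):
            if col not in df.columns:
                raise ValueError(f"panel data needs a {col!r} column")
        df = df.sort_values(["subject_id", "time"], kind="stable").reset_index(drop=True)
        states = df["state"].to_numpy()
        if len(df):
            if states.min() < 1 or states.max() > self.n_states:
                raise ValueError(f"state indices must be in 1..{self.n_states}")
            counts = df.groupby("subject_id", sort=False).size()
            if (counts < 2).any():
                bad = counts[counts < 2].index.tolist()[:5]
                raise ValueError(f"subjects with < 2 visits: {bad}")
            same = df["subject_id"].to_numpy()[1:] == df["subject_id"].to_numpy()[:-1]
            dt = np.diff(df["time"].to_numpy(dtype=float))
            if (dt[same] <= 0).any():
                raise ValueError("visit times must be strictly increasing per subject")
        self.data = df

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_transitions(self) -> int:
        """Number of consecutive visit pairs, Σ_subjects (visits − 1)."""
        return len(self.data) - self.n_subjects

    @property
    def covariate_columns(self) -> tuple:
        return tuple(c for c in COVARIATE_NAMES if c in self.data.columns)

    def intervals(self, covariates: tuple = ()):
        """Arrays (s0, s1, dt, Z) over consecutive visit pairs.

        States are 0-based; Z holds the covariate values at the *start* of
        each interval (time-varying covariates are stepwise constant).
        """
        df = self.data
        subj = df["subject_id"].to_numpy()
        same = subj[1:] == subj[:-1]
        states = df["state"].to_numpy(dtype=int)
        times = df["time"].to_numpy(dtype=float)
        s0 = states[:-1][same] - 1
        s1 = states[1:][same] - 1
        dt = (times[1:] - times[:-1])[same]
        if covariates:
            missing = sorted(set(covariates) - set(df.columns))
            if missing:
                raise KeyError(f"panel lacks covariate columns: {missing}")
            Z = df[list(covariates)].to_numpy(dtype=float)[:-1][same]
        else:
            Z = np.zeros((len(s0), 0))
        return s0, s1, dt, Z

    def baseline(self) -> pd.DataFrame:
        """First visit row of every subject."""
        return self.data.groupby("subject_id", sort=False).head(1)

    def subset(self, subject_ids) -> "PanelDataset":
        keep = self.data["subject_id"].isin(set(subject_ids))
        return PanelDataset(self.data.loc[keep].copy(), n_states=self.n_states)


@dataclass
class TransitionCountMatrix:
    """Observed visit-to-visit transition frequencies (origin × follow-up)."""

    counts: np.ndarray
    labels: tuple = STATE_LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (len(self.labels), len(self.labels)) or (c < 0).any():
            raise ValueError("counts must be a non-negative square matrix")
        self.counts = c

    @property
    def row_percent(self) -> np.ndarray:
        """Row-normalised percentages, round-half-up to 2 decimals."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        pct = np.where(totals > 0, pct, 0.0)
        return round_half_up(pct, 2)

    def to_dataframe(self, percent: bool = False) -> pd.DataFrame:
        values = self.row_percent if percent else self.counts
        return pd.DataFrame(values, index=list(self.labels), columns=list(self.labels))


@dataclass
class BaselineSummary:
    """Baseline phenotype composition and metabolic-unhealthy shares."""

    counts: np.ndarray
    n_total: int
    percent: np.ndarray
    unhealthy_percent: float
    unhealthy_percent_by_weight: dict
    labels: tuple = STATE_LABELS

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "percent": self.percent}, index=list(self.labels)
        )


def filter_eligible(
    records: pd.DataFrame,
    baseline_age_range: tuple = (20.0, 60.0),
    **classify_kwargs,
):
    """Apply the cohort eligibility rules and build a :class:`PanelDataset`.

    Rules, applied in order so each excluded subject has one primary reason:

    1. baseline BMI < 18.5 kg/m² (underweight),
    2. baseline age outside ``baseline_age_range`` (inclusive),
    3. an excluded-disease-history flag at baseline or any follow-up visit,
    4. a missing required measurement at baseline,
    5. fewer than two visits.

    Returns ``(panel, report)`` where ``report`` counts exclusions per reason.
    ``records`` is a raw check-up table; retained records are classified with
    :func:`metatrans.phenotyping.classify_checkups` (extra keyword arguments
    are forwarded).
    """
    report = {
        "underweight": 0,
        "age_out_of_range": 0,
        "disease_history": 0,
        "missing_baseline": 0,
        "too_few_visits": 0,
        "eligible": 0,
    }
    if len(records) == 0:
        empty = pd.DataFrame(columns=["subject_id", "time", "state"])
        return PanelDataset(empty), report

    df = records.sort_values(["subject_id", "visit_time"], kind="stable")
    grouped = df.groupby("subject_id", sort=False)
    base = grouped.head(1).set_index("subject_id")

    lo, hi = baseline_age_range
    excluded: set = set()

    underweight = base.index[base["bmi"] < 18.5]
    report["underweight"] = len(underweight)
    excluded.update(underweight)

    age_bad = base.index[(base["age"] < lo) | (base["age"] > hi)].difference(excluded)
    report["age_out_of_range"] = len(age_bad)
    excluded.update(age_bad)

    if "excluded_disease_history" in df.columns:
        flagged = df.loc[
            df["excluded_disease_history"].astype(bool), "subject_id"
        ].unique()
        disease = pd.Index(flagged).difference(pd.Index(sorted(excluded)))
        report["disease_history"] = len(disease)
        excluded.update(disease)

    present = [c for c in _ELIGIBILITY_COLUMNS if c in base.columns]
    absent_cols = [c for c in _ELIGIBILITY_COLUMNS if c not in base.columns]
    missing_mask = base[present].isna().any(axis=1)
    if absent_cols:
        missing_mask |= True  # a wholly absent required column fails everyone
    missing = base.index[missing_mask].difference(pd.Index(sorted(excluded)))
    report["missing_baseline"] = len(missing)
    excluded.update(missing)

    sizes = grouped.size()
    few = sizes.index[sizes < 2].difference(pd.Index(sorted(excluded)))
    report["too_few_visits"] = len(few)
    excluded.update(few)

    keep = df[~df["subject_id"].isin(excluded)].copy()
    report["eligible"] = keep["subject_id"].nunique()
    if len(keep) == 0:
        empty = pd.DataFrame(columns=["subject_id", "time", "state"])
        return PanelDataset(empty), report

    classified = classify_checkups(keep, **classify_kwargs)
    panel_df = classified[
        ["subject_id", "visit_time", "state", *COVARIATE_NAMES]
    ].rename(columns={"visit_time": "time"})
    return PanelDataset(panel_df), report


def tabulate_transitions(panel: PanelDataset) -> TransitionCountMatrix:
    """Count all consecutive visit-pair transitions (origin → next state)."""
    s0, s1, _, _ = panel.intervals()
    n = panel.n_states
    counts = np.zeros((n, n), dtype=int)
    np.add.at(counts, (s0, s1), 1)
    labels = STATE_LABELS if n == N_STATES else tuple(f"S{i+1}" for i in range(n))
    return TransitionCountMatrix(counts=counts, labels=labels)


def baseline_summary(panel: PanelDataset) -> BaselineSummary:
    """Baseline phenotype mix and % metabolically unhealthy overall and by
    weight stratum (states 4–6 are the unhealthy row of the grid)."""
    base_states = panel.baseline()["state"].to_numpy(dtype=int)
    n_total = len(base_states)
    counts = np.bincount(base_states - 1, minlength=N_STATES)
    percent = (
        round_half_up(100.0 * counts / n_total, 2)
        if n_total
        else np.zeros(N_STATES)
    )
    unhealthy = counts[3:].sum()
    overall = round_half_up(100.0 * unhealthy / n_total, 2) if n_total else 0.0
    by_weight = {}
    for w, name in enumerate(("normal", "overweight", "obese")):
        stratum = counts[w] + counts[w + 3]
        by_weight[name] = (
            round_half_up(100.0 * counts[w + 3] / stratum, 2) if stratum else float("nan")
        )
    return BaselineSummary(
        counts=counts,
        n_total=n_total,
        percent=np.atleast_1d(percent),
        unhealthy_percent=float(overall),
        unhealthy_percent_by_weight=by_weight,
    )


def stratify(panel: PanelDataset, by: tuple = ("female", "middle_aged")) -> dict:
    """Partition subjects by their *baseline* values of the given binary
    covariates.  Returns {tuple of 0/1 values: PanelDataset}; every
    combination is present (possibly empty), so the default yields the four
    sex × age-group subgroups."""
    for col in by:
        if col not in panel.data.columns:
            raise KeyError(f"panel lacks stratification column {col!r}")
    base = panel.baseline().set_index("subject_id")
    n_cells = 2 ** len(by)
    strata: dict = {}
    for cell in range(n_cells):
        key = tuple((cell >> i) & 1 for i in range(len(by)))
        mask = np.ones(len(base), dtype=bool)
        for col, val in zip(by, key):
            mask &= base[col].to_numpy(dtype=int) == val
        strata[key] = panel.subset(base.index[mask])
    return strata
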