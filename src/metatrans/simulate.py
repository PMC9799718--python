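"""Synthetic check-up cohorts with the statistical structure the model assumes.

The generator works at two levels:

* **state level** — exact (event-driven) simulation of the latent six-state
  CTMC per subject, sampled at jittered ~annual visit times, for estimator
  recovery tests; the latent jump paths are kept so oracle comparisons are
  unbiased by discretisation;
* **measurement level** — biochemistry and anthropometry drawn from
  state-conditional distributions *guaranteed* to classify back to the
  latent state (BMI sampled inside the weight category's interval; metabolic
  measurements placed on the correct side of each criterion's threshold so
  the criterion count matches), for end-to-end pipeline tests.

The default configuration emulates the reference check-up cohort: baseline
phenotype mix from the printed baseline table; the six printed metabolic
intensities (deterioration 0.15/0.38/0.56 per year down the weight grid,
improvement 0.64/0.44/0.27 up it); weight-transition rates derived so each
state's total exit rate is the reciprocal of its printed mean sojourn time,
with multi-exit budgets split in proportion to the observed transition
frequencies; ~annual visits over at most 8 years with a visit-count
distribution matching the cohort's printed follow-up anchors.  Measurement
medians sit near the printed baseline medians but the joint biochemistry
distribution is deliberately simple (independent given the state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import (
    reference_baseline_distribution,
    reference_metabolic_intensities,
    reference_sojourn_table,
    reference_transition_counts,
)
from .markov import build_intensity, validate_intensity
from .panel import PanelDataset
from .phenotyping import COVARIATE_NAMES, CHECKUP_COLUMNS, classify_checkups
from .states import six_state_structure

__all__ = [
    "GeneratorConfig",
    "SimulatedCohort",
    "default_intensity_matrix",
    "simulate_trajectory",
    "simulate_cohort",
    "emit_measurements",
]


def default_intensity_matrix() -> np.ndarray:
    """Default generator Q anchored to the printed estimates.

    The six vertical (metabolic) rates are the printed intensities.  The
    eight horizontal (weight) rates are *derived*, not printed: each state's
    total exit rate is fixed to 1/sojourn from the printed sojourn table, and
    states with two remaining exits (MHOW, MUOW) split the residual budget in
    proportion to the corresponding observed transition frequencies.
    """
    structure = six_state_structure()
    sojourn = reference_sojourn_table()["mean"].to_numpy()
    exit_rates = 1.0 / sojourn
    rates: dict = dict(reference_metabolic_intensities())
    counts = reference_transition_counts().astype(float)
    row_frac = counts / counts.sum(axis=1, keepdims=True)

    # MHNW: exits to MHOW and MUNW
    rates[("MHNW", "MHOW")] = exit_rates[0] - rates[("MHNW", "MUNW")]
    # MHOW: exits to MHNW, MHO, MUOW — split residual by observed frequencies
    resid = exit_rates[1] - rates[("MHOW", "MUOW")]
    w = np.array([row_frac[1, 0], row_frac[1, 2]])
    w = w / w.sum()
    rates[("MHOW", "MHNW")] = resid * w[0]
    rates[("MHOW", "MHO")] = resid * w[1]
    # MHO: exits to MHOW and MUO
    rates[("MHO", "MHOW")] = exit_rates[2] - rates[("MHO", "MUO")]
    # MUNW: exits to MHNW and MUOW
    rates[("MUNW", "MUOW")] = exit_rates[3] - rates[("MUNW", "MHNW")]
    # MUOW: exits to MHOW, MUNW, MUO
    resid = exit_rates[4] - rates[("MUOW", "MHOW")]
    w = np.array([row_frac[4, 3], row_frac[4, 5]])
    w = w / w.sum()
    rates[("MUOW", "MUNW")] = resid * w[0]
    rates[("MUOW", "MUO")] = resid * w[1]
    # MUO: exits to MUOW and MHO
    rates[("MUO", "MUOW")] = exit_rates[5] - rates[("MUO", "MHO")]

    return build_intensity(rates, structure)


def _default_visit_probs() -> dict:
    # total visits per subject; tuned once to the cohort's printed anchors
    # (31% of subjects with >= 5 total check-ups, median follow-up ~3 years)
    return {2: 0.24, 3: 0.22, 4: 0.23, 5: 0.12, 6: 0.08, 7: 0.06, 8: 0.05}


def _default_covariate_prevalence() -> dict:
    return {
        "female": 0.5227,
        "middle_aged": 0.253,
        "alt_elevated": 0.10,
        "ast_elevated": 0.05,
        "scr_elevated": 0.02,
        "ua_elevated": 0.15,
    }


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    ``beta`` has one row per edge of the 14-edge structure (edge_list order)
    and one column per name in ``covariates``; the subject-level generator
    applies exp(β'z) edgewise.  ``visit_count`` fixes the number of visits
    per subject; when None the ``visit_count_probs`` distribution is drawn
    from.  ``seed`` is mandatory (reproducibility is part of the contract).
    """

    n_subjects: int = 9742
    seed: int | None = None
    baseline_distribution: np.ndarray = field(
        default_factory=reference_baseline_distribution
    )
    Q: np.ndarray = field(default_factory=default_intensity_matrix)
    covariates: tuple = ()
    beta: np.ndarray | None = None
    covariate_prevalence: dict = field(default_factory=_default_covariate_prevalence)
    mean_interval: float = 1.0
    interval_jitter_sd: float = 0.15
    min_interval: float = 0.3
    visit_count: int | None = None
    visit_count_probs: dict = field(default_factory=_default_visit_probs)
    follow_up_cap: float = 8.0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        p = np.asarray(self.baseline_distribution, dtype=float)
        if p.shape != (6,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("baseline_distribution must be a 6-probability vector")
        validate_intensity(self.Q, structure=six_state_structure())
        k = len(self.covariates)
        if k:
            unknown = sorted(set(self.covariates) - set(COVARIATE_NAMES))
            if unknown:
                raise ValueError(f"unknown covariates: {unknown}")
            b = np.zeros((14, k)) if self.beta is None else np.asarray(self.beta, float)
            if b.shape != (14, k):
                raise ValueError(f"beta must have shape (14, {k})")
        if self.visit_count is not None and self.visit_count < 2:
            raise ValueError("visit_count must be at least 2")
        if self.visit_count is None:
            probs = np.asarray(list(self.visit_count_probs.values()), float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError("visit_count_probs must be a probability distribution")
            if min(self.visit_count_probs) < 2:
                raise ValueError("every subject needs at least 2 visits")
        if not (0 < self.mean_interval <= self.follow_up_cap):
            raise ValueError("mean_interval must be positive and within the cap")
        if self.interval_jitter_sd < 0 or self.min_interval <= 0:
            raise ValueError("invalid visit-schedule parameters")


@dataclass
class SimulatedCohort:
    """Panel snapshots plus the exact latent jump paths that produced them."""

    panel: PanelDataset
    latent_paths: dict
    config: GeneratorConfig
    seed: int


def simulate_trajectory(Q: np.ndarray, start_state: int, horizon: float, rng) -> tuple:
    """Exact CTMC path from ``start_state`` (0-based) over [0, horizon].

    Repeatedly draws an exponential holding time with rate −q_rr and a
    destination with probability q_rs/(−q_rr), truncating at the horizon.
    Returns (jump_times, states) with jump_times[0] = 0; an absorbing row
    (all-zero) simply holds the state to the horizon.
    """
    Q = np.asarray(Q, dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    times = [0.0]
    states = [int(start_state)]
    t, s = 0.0, int(start_state)
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        probs = Q[s].copy()
        probs[s] = 0.0
        probs = probs / rate
        s = int(rng.choice(len(probs), p=probs))
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=int)


def _states_at(times, states, query) -> np.ndarray:
    idx = np.searchsorted(times, query, side="right") - 1
    return states[np.maximum(idx, 0)]


def simulate_cohort(config: GeneratorConfig, seed: int | None = None) -> SimulatedCohort:
    """Draw a full cohort: baseline states and covariates, subject-specific
    covariate-adjusted generators, jittered visit schedules, and panel states
    read off the exact latent paths.  Fully reproducible under a fixed seed.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (pass it in the config or the call)")
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    structure = six_state_structure()
    edges = structure.edge_list
    base_rates = np.array([config.Q[i, j] for i, j in edges])

    baseline_states = rng.choice(6, size=n, p=np.asarray(config.baseline_distribution))
    cov_values = {
        name: (rng.random(n) < config.covariate_prevalence.get(name, 0.0)).astype(int)
        for name in COVARIATE_NAMES
    }

    k = len(config.covariates)
    beta = (
        np.zeros((len(edges), 0))
        if not k
        else (np.zeros((len(edges), k)) if config.beta is None else np.asarray(config.beta, float))
    )
    Zsel = (
        np.stack([cov_values[c] for c in config.covariates], axis=1).astype(float)
        if k
        else np.zeros((n, 0))
    )

    # visit counts and times
    if config.visit_count is not None:
        m = np.full(n, config.visit_count)
    else:
        ks = np.array(sorted(config.visit_count_probs))
        ps = np.array([config.visit_count_probs[v] for v in ks], dtype=float)
        m = rng.choice(ks, size=n, p=ps / ps.sum())

    records = []
    latent: dict = {}
    # cache adjusted generators per distinct covariate pattern
    q_cache: dict = {}
    for i in range(n):
        z = Zsel[i]
        key = tuple(z.astype(int))
        Qi = q_cache.get(key)
        if Qi is None:
            rates = base_rates * np.exp(beta @ z) if k else base_rates
            Qi = build_intensity(rates, structure)
            q_cache[key] = Qi
        gaps = rng.normal(config.mean_interval, config.interval_jitter_sd, size=m[i] - 1)
        gaps = np.maximum(gaps, config.min_interval)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        times = times[times <= config.follow_up_cap]
        if len(times) < 2:  # keep the contract of >= 2 visits
            times = np.array([0.0, config.min_interval])
        jt, js = simulate_trajectory(Qi, baseline_states[i], float(times[-1]) + 1e-9, rng)
        visit_states = _states_at(jt, js, times)
        latent[i] = (jt, js)
        for t, s in zip(times, visit_states):
            records.append((i, float(t), int(s) + 1))

    df = pd.DataFrame(records, columns=["subject_id", "time", "state"])
    for name in COVARIATE_NAMES:
        df[name] = cov_values[name][df["subject_id"].to_numpy()]
    panel = PanelDataset(df)
    return SimulatedCohort(panel=panel, latent_paths=latent, config=config, seed=seed)


# ---------------------------------------------------------------------------
# measurement emission

_BMI_RANGES = ((19.0, 23.9), (24.1, 27.8), (28.0, 32.0))  # per weight level


def emit_measurements(
    cohort: SimulatedCohort,
    seed: int | None = None,
    max_attempts: int = 100,
) -> pd.DataFrame:
    """Emit a check-up table whose classification reproduces the latent
    states exactly.

    Per visit: BMI is drawn inside the latent weight category's interval;
    the number of metabolic criteria met is drawn as ≤1 (healthy) or ≥2
    (unhealthy), the met criteria are chosen at random, and each measurement
    is placed on the matching side of its threshold.  ALT/AST/SCr/UA are
    emitted consistently with the subject's elevated-marker flags.  The
    emitted frame is verified by re-classification; a mismatch raises (it
    would indicate an inconsistent configuration).
    """
    rng = np.random.default_rng(cohort.seed + 1 if seed is None else seed)
    df = cohort.panel.data
    n = len(df)
    state0 = df["state"].to_numpy(dtype=int) - 1
    weight = state0 % 3
    unhealthy = (state0 // 3).astype(bool)
    female = df["female"].to_numpy(dtype=bool)

    for _ in range(max_attempts):
        lo = np.array([_BMI_RANGES[w][0] for w in weight])
        hi = np.array([_BMI_RANGES[w][1] for w in weight])
        bmi = rng.uniform(lo, hi)

        # number of criteria met: healthy subjects 0 or 1, unhealthy 2-4
        k_healthy = rng.choice([0, 1], size=n, p=[0.6, 0.4])
        k_unhealthy = rng.choice([2, 3, 4], size=n, p=[0.6, 0.3, 0.1])
        k = np.where(unhealthy, k_unhealthy, k_healthy)
        # choose which criteria by ranking random scores per row
        ranks = np.argsort(rng.random((n, 4)), axis=1).argsort(axis=1)
        met = ranks < k[:, None]  # columns: BP, glucose, TG, HDL

        sbp = np.where(met[:, 0], rng.uniform(130, 148, n), rng.uniform(102, 128, n))
        dbp = np.where(met[:, 0], rng.uniform(72, 94, n), rng.uniform(62, 84, n))
        fpg = np.where(met[:, 1], rng.uniform(5.6, 6.8, n), rng.uniform(4.6, 5.55, n))
        tg = np.where(met[:, 2], rng.uniform(1.7, 2.9, n), rng.uniform(0.6, 1.65, n))
        hdl_low = np.where(female, rng.uniform(0.95, 1.29, n), rng.uniform(0.78, 0.99, n))
        hdl_ok = np.where(female, rng.uniform(1.32, 1.95, n), rng.uniform(1.02, 1.85, n))
        hdl = np.where(met[:, 3], hdl_low, hdl_ok)

        alt_e = df["alt_elevated"].to_numpy(dtype=bool)
        ast_e = df["ast_elevated"].to_numpy(dtype=bool)
        scr_e = df["scr_elevated"].to_numpy(dtype=bool)
        ua_e = df["ua_elevated"].to_numpy(dtype=bool)
        alt = np.where(alt_e, rng.uniform(41, 85, n), rng.uniform(9, 38, n))
        ast = np.where(ast_e, rng.uniform(41, 75, n), rng.uniform(13, 38, n))
        scr = np.where(
            scr_e,
            np.where(female, rng.uniform(107, 145, n), rng.uniform(134, 175, n)),
            np.where(female, rng.uniform(40, 92, n), rng.uniform(50, 110, n)),
        )
        ua = np.where(
            ua_e,
            np.where(female, rng.uniform(361, 470, n), rng.uniform(421, 540, n)),
            np.where(female, rng.uniform(130, 355, n), rng.uniform(160, 415, n)),
        )

        middle = df["middle_aged"].to_numpy(dtype=bool)
        base_age = np.where(middle, rng.uniform(45.5, 59.5, n), rng.uniform(20.5, 44.5, n))
        # keep one baseline age per subject; emit it at every visit so the
        # dichotomised age group matches the latent (baseline-fixed) covariate
        first = ~df["subject_id"].duplicated().to_numpy()
        subj_age = pd.Series(base_age[first], index=df.loc[first, "subject_id"])
        age = subj_age.loc[df["subject_id"]].to_numpy()

        out = pd.DataFrame(
            {
                "subject_id": df["subject_id"].to_numpy(),
                "visit_time": df["time"].to_numpy(),
                "sex": np.where(female, "female", "male"),
                "age": age,
                "bmi": bmi,
                "sbp": sbp,
                "dbp": dbp,
                "fpg": fpg,
                "pg2h": np.nan,
                "tg": tg,
                "hdl": hdl,
                "alt": alt,
                "ast": ast,
                "scr": scr,
                "ua": ua,
                "on_antihypertensive": False,
                "on_hypoglycemic": False,
                "excluded_disease_history": False,
            }
        )[list(CHECKUP_COLUMNS)]

        check = classify_checkups(out)
        if (check["state"].to_numpy() == state0 + 1).all():
            return out
    raise RuntimeError(
        "measurement emission failed to reproduce latent states "
        f"after {max_attempts} attempts (inconsistent configuration)"
    )
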