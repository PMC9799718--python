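"""Likelihood correctness, fitting, and the reported estimate tables."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from metatrans import (
    FittedModel,
    GeneratorConfig,
    ModelSpec,
    chain_structure,
    crude_init,
    fit,
    hazard_ratio_table,
    intensity_table,
    panel_loglik,
    simulate_cohort,
    sojourn_table,
    six_state_structure,
)
from tests.conftest import make_panel


class TestPanelLoglik:
    def test_zero_intensities_and_constant_panel_give_zero(self):
        spec = ModelSpec()
        panel = make_panel([(1, 1, 1), (4, 4)])
        params = np.full(spec.n_params, np.log(1e-12))
        assert abs(panel_loglik(params, panel, spec)) < 1e-9

    def test_zero_intensities_make_observed_change_impossible(self):
        spec = ModelSpec()
        panel = make_panel([(1, 2)])
        params = np.full(spec.n_params, np.log(1e-300))
        ll = panel_loglik(params, panel, spec)
        # P is numerically the identity, so the observed move is impossible
        assert ll == -np.inf or ll < -600.0

    def test_two_state_closed_form(self, two_state_one_way):
        # one subject: state 1 at t=0, state 2 at t=1; only 1->2 allowed
        spec = ModelSpec(structure=two_state_one_way)
        panel = make_panel([(1, 2)], n_states=2)
        for a in (0.2, 0.9, 2.3):
            ll = panel_loglik(np.array([np.log(a)]), panel, spec)
            assert abs(ll - np.log(1 - np.exp(-a))) < 1e-10

    def test_invariance_to_subject_relabelling_and_time_units(self):
        cfg = GeneratorConfig(n_subjects=60, seed=5)
        panel = simulate_cohort(cfg).panel
        spec = ModelSpec()
        params = crude_init(panel)
        ll = panel_loglik(params, panel, spec)
        # relabel subjects in reverse order
        relabelled = panel.data.copy()
        relabelled["subject_id"] = relabelled["subject_id"].max() - relabelled["subject_id"]
        from metatrans import PanelDataset

        ll_perm = panel_loglik(params, PanelDataset(relabelled), spec)
        assert abs(ll - ll_perm) < 1e-9
        # months instead of years, rates rescaled by 1/12
        months = panel.data.copy()
        months["time"] = months["time"] * 12.0
        ll_months = panel_loglik(
            params - np.log(12.0), PanelDataset(months), spec
        )
        assert abs(ll - ll_months) < 1e-9


class TestCrudeInit:
    def test_moves_over_person_time(self):
        # 10 intervals of 1 year starting in state 1, two end in state 2
        seqs = [(1, 2)] * 2 + [(1, 1)] * 8
        rates = np.exp(crude_init(make_panel(seqs)))
        edges = six_state_structure().edge_list
        assert abs(rates[edges.index((0, 1))] - 0.2) < 1e-12

    def test_unobserved_edges_floored(self):
        rates = np.exp(crude_init(make_panel([(1, 1)] * 3)))
        assert np.allclose(rates, 1e-3, rtol=1e-12)

    def test_empty_panel_errors(self):
        from metatrans import PanelDataset
        import pandas as pd

        empty = PanelDataset(pd.DataFrame(columns=["subject_id", "time", "state"]))
        with pytest.raises(ValueError):
            crude_init(empty)


class TestFit:
    def test_one_parameter_mle_matches_grid_search_oracle(self, two_state_one_way):
        # panel observed at 1-year gaps; closed-form likelihood in the rate a
        rng = np.random.default_rng(6)
        a_true = 0.7
        stay = np.exp(-a_true)
        seqs = [(1, 1) if rng.random() < stay else (1, 2) for _ in range(200)]
        panel = make_panel(seqs, n_states=2)
        spec = ModelSpec(structure=two_state_one_way)
        fitted = fit(panel, spec, compute_vcov=False)
        n12 = sum(s == (1, 2) for s in seqs)
        n11 = len(seqs) - n12

        def neg_closed_form(a):
            return -(n11 * (-a) + n12 * np.log1p(-np.exp(-a)))

        oracle = minimize_scalar(neg_closed_form, bounds=(1e-3, 5.0), method="bounded",
                                 options={"xatol": 1e-10}).x
        assert abs(np.exp(fitted.log_q0[0]) - oracle) < 1e-4
        assert fitted.converged

    def test_loglik_never_below_crude_init(self):
        cfg = GeneratorConfig(n_subjects=150, seed=7)
        panel = simulate_cohort(cfg).panel
        spec = ModelSpec()
        init = crude_init(panel)
        fitted = fit(panel, spec, compute_vcov=False, maxiter=200)
        assert fitted.loglik >= panel_loglik(init, panel, spec)

    def test_all_zero_covariate_leaves_baselines_unchanged(self):
        cfg = GeneratorConfig(n_subjects=120, seed=8, covariate_prevalence={"female": 0.0})
        panel = simulate_cohort(cfg).panel
        assert (panel.data["female"] == 0).all()
        plain = fit(panel, ModelSpec(), compute_vcov=False)
        withcov = fit(panel, ModelSpec(covariates=("female",)), compute_vcov=False)
        assert np.abs(withcov.beta).max() < 1e-8  # no signal, no movement
        assert np.abs(np.exp(plain.log_q0) - np.exp(withcov.log_q0)).max() < 1e-6


def _toy_fitted(log_q0, vcov, covariates=(), beta=None):
    structure = six_state_structure() if len(log_q0) == 14 else chain_structure(2)
    spec = ModelSpec(structure=structure, covariates=covariates)
    params = np.asarray(log_q0, dtype=float)
    if covariates:
        params = np.concatenate([params, np.asarray(beta, float).ravel()])
    return FittedModel(
        spec=spec, params=params, loglik=0.0, converged=True, n_subjects=1,
        n_transitions=1, n_iter=0, grad_norm=0.0, vcov=vcov,
    )


class TestReportTables:
    def test_intensity_ci_formula(self):
        p = 14
        fitted = _toy_fitted(np.zeros(p), np.zeros((p, p)))
        tab = intensity_table(fitted)
        assert np.allclose(tab["estimate"], 1.0)
        assert np.allclose(tab["lower"], 1.0) and np.allclose(tab["upper"], 1.0)
        vcov = np.zeros((p, p))
        vcov[0, 0] = 0.1**2
        fitted = _toy_fitted(np.full(p, np.log(0.64)), vcov)
        tab = intensity_table(fitted)
        assert abs(tab["lower"][0] - 0.64 * np.exp(-1.959964 * 0.1)) < 1e-6
        assert abs(tab["upper"][0] - 0.64 * np.exp(+1.959964 * 0.1)) < 1e-6

    def test_sojourn_reciprocal_with_degenerate_ci(self):
        # chain on 2 states: rates q12 = 0.26, q21 = 0.26; zero variance
        fitted = _toy_fitted(np.log([0.26, 0.26]), np.zeros((2, 2)))
        tab = sojourn_table(fitted)
        assert abs(tab.loc["S1", "mean"] - 1 / 0.26) < 1e-12
        assert tab.loc["S1", "lower"] == tab.loc["S1", "upper"] == tab.loc["S1", "mean"]
        assert list(tab.columns) == ["mean", "se", "lower", "upper"]
        assert len(tab) == 2

    def test_hazard_ratio_formula(self):
        p = 14
        vcov = np.zeros((2 * p, 2 * p))
        vcov[p, p] = 0.1**2
        beta = np.zeros((p, 1))
        beta[0, 0] = np.log(2.0)
        fitted = _toy_fitted(np.zeros(p), vcov, covariates=("female",), beta=beta)
        tab = hazard_ratio_table(fitted)
        first = tab.iloc[0]
        assert abs(first["hr"] - 2.0) < 1e-12
        assert abs(first["lower"] - 2.0 * np.exp(-1.959964 * 0.1)) < 1e-6
        others = tab.iloc[1:]
        assert np.allclose(others["hr"], 1.0)
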