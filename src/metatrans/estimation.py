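"""Maximum-likelihood estimation of the panel-observed multistate model.

States are seen only at visit snapshots, so the likelihood of one subject is
a product over consecutive visit pairs of matrix-exponential transition
probabilities,

    L = Π_k P_{z_k}(t_{k+1} − t_k)[s_k, s_{k+1}],

where the generator for the interval applies a proportional-intensity
covariate model edgewise,

    q_rs(z) = q_rs(0) · exp(β_rs' z),

with z the covariate vector at the interval's *start* (time-varying
covariates are stepwise constant between visits).  exp(β_rs) is reported as
a hazard ratio for the covariate's effect on that transition.

Free parameters are the 14 baseline log-intensities plus one β per
(edge, covariate); the log-likelihood is maximised by quasi-Newton (BFGS)
iteration with central-difference gradients, and standard errors come from
the inverse of the numerically differentiated observed information at the
optimum.  Confidence intervals for intensities, sojourn times and hazard
ratios are normal-theory intervals on the log scale, hence asymmetric on
the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .markov import build_intensity, sojourn_times
from .panel import PanelDataset
from .states import TransitionStructure, six_state_structure

__all__ = [
    "ModelSpec",
    "FittedModel",
    "panel_loglik",
    "crude_init",
    "fit",
    "fit_stratified",
    "intensity_table",
    "sojourn_table",
    "hazard_ratio_table",
]

_Z975 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass(frozen=True)
class ModelSpec:
    """Transition structure plus the ordered covariate set (possibly empty)."""

    structure: TransitionStructure = field(default_factory=six_state_structure)
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariate names must be unique")

    @property
    def n_edges(self) -> int:
        return self.structure.n_edges

    @property
    def n_params(self) -> int:
        return self.n_edges * (1 + len(self.covariates))

    def split(self, params: np.ndarray):
        """(log_q0, beta) views of a flat parameter vector."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} parameters, got shape {params.shape}"
            )
        E, k = self.n_edges, len(self.covariates)
        return params[:E], params[E:].reshape(E, k)


@dataclass
class FittedModel:
    """Point estimates, covariance and diagnostics of one ML fit."""

    spec: ModelSpec
    params: np.ndarray
    loglik: float
    converged: bool
    n_subjects: int
    n_transitions: int
    n_iter: int
    grad_norm: float
    vcov: np.ndarray | None = None

    @property
    def log_q0(self) -> np.ndarray:
        return self.spec.split(self.params)[0]

    @property
    def beta(self) -> np.ndarray:
        return self.spec.split(self.params)[1]

    def intensity_matrix(self, z=None) -> np.ndarray:
        """Generator at covariate vector ``z`` (defaults to the reference
        level, all covariates zero)."""
        log_rates = self.log_q0.copy()
        if z is not None and len(self.spec.covariates):
            z = np.asarray(z, dtype=float)
            log_rates = log_rates + self.beta @ z
        return build_intensity(np.exp(log_rates), self.spec.structure)

    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.diag(self.vcov))


# ---------------------------------------------------------------------------
# likelihood


def _prepare(panel: PanelDataset, spec: ModelSpec):
    s0, s1, dt, Z = panel.intervals(covariates=spec.covariates)
    if len(s0) == 0:
        raise ValueError("panel contains no observed visit pairs")
    if s0.max() >= spec.structure.n_states or s1.max() >= spec.structure.n_states:
        raise ValueError("panel states exceed the structure's state count")
    # group intervals by distinct covariate pattern: one generator per group
    if Z.shape[1]:
        patterns, inverse = np.unique(Z, axis=0, return_inverse=True)
    else:
        patterns, inverse = np.zeros((1, 0)), np.zeros(len(s0), dtype=int)
    groups = [
        (patterns[g], np.nonzero(inverse == g)[0]) for g in range(len(patterns))
    ]
    return s0, s1, dt, groups


def _prob_entries(Q: np.ndarray, dts, i, j) -> np.ndarray:
    """P(dt)[i, j] for arrays of intervals sharing one generator.

    Fast path: one eigendecomposition serves every interval length
    (P(t) = V e^{Λt} V⁻¹); falls back to one expm per distinct length when
    the eigenvector basis is ill-conditioned or the decomposition fails to
    reproduce Q.
    """
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        recon = (V * w) @ Vinv
        scale = max(1.0, np.abs(Q).max())
        if np.abs(recon - Q).max() < 1e-10 * scale:
            E = np.exp(np.multiply.outer(dts, w))
            vals = np.einsum("ml,ml->m", V[i, :] * E, Vinv[:, j].T)
            p = np.clip(vals.real, 0.0, 1.0)
            # entries near round-off level are recomputed exactly: the eig
            # path cannot resolve probabilities below ~1e-15
            tiny = p < 1e-12
            if tiny.any():
                p[tiny] = _prob_entries_expm(Q, dts[tiny], i[tiny], j[tiny])
            return p
    except np.linalg.LinAlgError:
        pass
    return _prob_entries_expm(Q, dts, i, j)


def _prob_entries_expm(Q: np.ndarray, dts, i, j) -> np.ndarray:
    uniq, inv = np.unique(dts, return_inverse=True)
    Ps = np.stack([expm(Q * u) for u in uniq])
    return np.clip(Ps[inv, i, j], 0.0, 1.0)


def _loglik_core(params, prepared, spec: ModelSpec, floor: float | None):
    """Σ log P(Δt)[s0, s1]; with ``floor`` None, a zero probability yields
    −inf (the impossibility signal), otherwise probabilities are floored for
    optimizer robustness."""
    s0, s1, dt, groups = prepared
    log_q0, beta = spec.split(params)
    if not np.isfinite(params).all():
        raise ValueError("non-finite parameters")
    total = 0.0
    for z, idx in groups:
        log_rates = log_q0 + (beta @ z if beta.size else 0.0)
        Q = build_intensity(np.exp(log_rates), spec.structure)
        p = _prob_entries(Q, dt[idx], s0[idx], s1[idx])
        if floor is None:
            if (p <= 0.0).any():
                return -np.inf
        else:
            p = np.maximum(p, floor)
        total += float(np.log(p).sum())
    return total


def panel_loglik(params, panel: PanelDataset, spec: ModelSpec) -> float:
    """Panel log-likelihood at ``params``; −inf when the data contain a
    transition the parameterised model gives zero probability."""
    prepared = _prepare(panel, spec)
    return _loglik_core(np.asarray(params, dtype=float), prepared, spec, floor=None)


# ---------------------------------------------------------------------------
# initial values


def crude_init(
    panel: PanelDataset,
    structure: TransitionStructure | None = None,
    rate_floor: float = 1e-3,
) -> np.ndarray:
    """Per-edge initial log-rates from observed moves / person-time.

    Person-time in state r is approximated by the summed lengths of
    intervals *starting* in r; each directly observed adjacent move r → s
    between consecutive visits counts once.  Edges with no observed direct
    move get the ``rate_floor`` (1e-3/year).
    """
    structure = structure or six_state_structure()
    s0, s1, dt, _ = panel.intervals()
    if len(s0) == 0:
        raise ValueError("panel contains no observed visit pairs")
    n = structure.n_states
    person_time = np.bincount(s0, weights=dt, minlength=n)
    if person_time.sum() <= 0:
        raise ValueError("zero total person-time in panel")
    moves = np.zeros((n, n))
    np.add.at(moves, (s0, s1), 1.0)
    rates = []
    for i, j in structure.edge_list:
        if person_time[i] > 0 and moves[i, j] > 0:
            rates.append(max(moves[i, j] / person_time[i], rate_floor))
        else:
            rates.append(rate_floor)
    return np.log(np.asarray(rates))


# ---------------------------------------------------------------------------
# numerical differentiation (central differences)


def _fd_grad(f, x: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    h = rel * np.maximum(1.0, np.abs(x))
    g = np.empty_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        g[i] = (f(xp) - f(xm)) / (2 * h[i])
    return g


def _fd_hessian(f, x: np.ndarray, rel: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian with step rel·max(1, |θ|) per coordinate.

    The step is chosen so the difference quotient is not swamped by rounding
    at log-likelihood magnitudes ~1e4 in double precision.
    """
    p = len(x)
    h = rel * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[i] = f(xp)
        fm[i] = f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xpm = x.copy()
            xpm[i] += h[i]
            xpm[j] -= h[j]
            xmp = x.copy()
            xmp[i] -= h[i]
            xmp[j] += h[j]
            xmm = x.copy()
            xmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4 * h[i] * h[j]
            )
    return H


# ---------------------------------------------------------------------------
# fitting


def fit(
    panel: PanelDataset,
    spec: ModelSpec | None = None,
    init="crude",
    tol: float = 1e-8,
    gtol: float = 1e-3,
    maxiter: int = 500,
    compute_vcov: bool = True,
) -> FittedModel:
    """Maximise the panel log-likelihood by BFGS from crude (or given)
    initial values.

    ``tol`` is kept as the relative log-likelihood change target mirrored in
    the optimizer's termination; ``gtol`` bounds the gradient sup-norm.  The
    ``converged`` flag is honest: it reports the optimizer's own success
    status (or a post-hoc gradient check), never assumed.
    """
    spec = spec or ModelSpec()
    prepared = _prepare(panel, spec)
    E, k = spec.n_edges, len(spec.covariates)

    if isinstance(init, str) and init == "crude":
        x0 = np.concatenate([crude_init(panel, spec.structure), np.zeros(E * k)])
    else:
        x0 = np.asarray(init, dtype=float)
        if x0.shape == (E,) and k:
            x0 = np.concatenate([x0, np.zeros(E * k)])
        if x0.shape != (spec.n_params,):
            raise ValueError(f"init must have {spec.n_params} entries")

    floor = 1e-300

    def negll(x):
        return -_loglik_core(x, prepared, spec, floor=floor)

    def grad(x):
        return _fd_grad(negll, x)

    res = minimize(
        negll,
        x0,
        jac=grad,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter, "xrtol": tol},
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success) or grad_norm < 10 * gtol

    vcov = None
    if compute_vcov:
        H = _fd_hessian(negll, res.x)
        try:
            vcov = np.linalg.inv(H)
            if not np.isfinite(vcov).all() or (np.diag(vcov) <= 0).any():
                vcov = None
        except np.linalg.LinAlgError:
            vcov = None

    return FittedModel(
        spec=spec,
        params=res.x,
        loglik=float(-res.fun),
        converged=converged,
        n_subjects=panel.n_subjects,
        n_transitions=panel.n_transitions,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        vcov=vcov,
    )


def fit_stratified(panel: PanelDataset, spec: ModelSpec | None = None, by=("female", "middle_aged"), **kwargs) -> dict:
    """Refit the model within each baseline sex × age-group stratum (the
    sensitivity-analysis convenience); returns {stratum key: FittedModel}."""
    from .panel import stratify

    spec = spec or ModelSpec()
    out = {}
    for key, sub in stratify(panel, by=by).items():
        if sub.n_subjects == 0:
            out[key] = None
            continue
        out[key] = fit(sub, spec, **kwargs)
    return out


# ---------------------------------------------------------------------------
# reported tables


def _edge_frame(spec: ModelSpec) -> pd.DataFrame:
    labels = spec.structure.edge_labels()
    return pd.DataFrame(labels, columns=["from", "to"])


def intensity_table(fitted: FittedModel) -> pd.DataFrame:
    """Per-edge baseline intensity with log-scale 95% CI."""
    tab = _edge_frame(fitted.spec)
    log_q0 = fitted.log_q0
    tab["estimate"] = np.exp(log_q0)
    se = fitted.se()
    if se is None:
        tab["lower"] = np.nan
        tab["upper"] = np.nan
    else:
        s = se[: fitted.spec.n_edges]
        tab["lower"] = np.exp(log_q0 - _Z975 * s)
        tab["upper"] = np.exp(log_q0 + _Z975 * s)
    return tab


def sojourn_table(fitted: FittedModel) -> pd.DataFrame:
    """Mean sojourn time per state at reference covariates with SE and 95% CI.

    mean_r = −1/q_rr = 1/λ_r with λ_r the total exit rate; the SE comes from
    the delta method on log λ_r, giving the asymmetric log-scale CI.
    """
    spec = fitted.spec
    Q = fitted.intensity_matrix()
    means = sojourn_times(Q)
    edges = spec.structure.edge_list
    rates = np.exp(fitted.log_q0)
    rows = []
    for r, label in enumerate(spec.structure.labels):
        lam = -Q[r, r]
        if fitted.vcov is not None and lam > 0:
            g = np.zeros(spec.n_params)
            for e, (i, _) in enumerate(edges):
                if i == r:
                    g[e] = rates[e]  # ∂λ_r/∂log q_e = q_e
            var_lam = float(g @ fitted.vcov @ g)
            se_log = np.sqrt(max(var_lam, 0.0)) / lam
            mean = means[r]
            rows.append(
                (
                    label,
                    mean,
                    mean * se_log,
                    mean * np.exp(-_Z975 * se_log),
                    mean * np.exp(_Z975 * se_log),
                )
            )
        else:
            rows.append((label, means[r], np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["state", "mean", "se", "lower", "upper"]).set_index(
        "state"
    )


def hazard_ratio_table(fitted: FittedModel) -> pd.DataFrame:
    """exp(β) per (edge, covariate) with log-scale 95% CI."""
    spec = fitted.spec
    if not spec.covariates:
        raise ValueError("model was fitted without covariates")
    E, k = spec.n_edges, len(spec.covariates)
    beta = fitted.beta
    se = fitted.se()
    se_beta = None if se is None else se[E:].reshape(E, k)
    labels = spec.structure.edge_labels()
    rows = []
    for e, (src, dst) in enumerate(labels):
        for c, cov in enumerate(spec.covariates):
            b = beta[e, c]
            if se_beta is None:
                lo = hi = np.nan
            else:
                lo = np.exp(b - _Z975 * se_beta[e, c])
                hi = np.exp(b + _Z975 * se_beta[e, c])
            rows.append((src, dst, cov, np.exp(b), lo, hi))
    return pd.DataFrame(
        rows, columns=["from", "to", "covariate", "hr", "lower", "upper"]
    )


# ---------------------------------------------------------------------------
# serialisation (machine-readable fit reports)


def fitted_to_dict(fitted: FittedModel) -> dict:
    spec = fitted.spec
    return {
        "labels": list(spec.structure.labels),
        "edges": [[int(i), int(j)] for i, j in spec.structure.edge_list],
        "covariates": list(spec.covariates),
        "params": [float(v) for v in fitted.params],
        "loglik": float(fitted.loglik),
        "converged": bool(fitted.converged),
        "n_subjects": int(fitted.n_subjects),
        "n_transitions": int(fitted.n_transitions),
        "n_iter": int(fitted.n_iter),
        "grad_norm": float(fitted.grad_norm),
        "vcov": None if fitted.vcov is None else [[float(v) for v in row] for row in fitted.vcov],
    }


def fitted_from_dict(d: dict) -> FittedModel:
    n = len(d["labels"])
    allowed = np.zeros((n, n), dtype=bool)
    for i, j in d["edges"]:
        allowed[i, j] = True
    structure = TransitionStructure(allowed=allowed, labels=tuple(d["labels"]))
    spec = ModelSpec(structure=structure, covariates=tuple(d["covariates"]))
    return FittedModel(
        spec=spec,
        params=np.asarray(d["params"], dtype=float),
        loglik=d["loglik"],
        converged=d["converged"],
        n_subjects=d["n_subjects"],
        n_transitions=d["n_transitions"],
        n_iter=d["n_iter"],
        grad_norm=d["grad_norm"],
        vcov=None if d["vcov"] is None else np.asarray(d["vcov"], dtype=float),
    )
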