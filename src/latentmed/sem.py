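"""Structural equation models estimated by full-information maximum likelihood.

The model is held in RAM (reticular action model) form over the combined
vector of observed and latent variables: a directed-path matrix ``A``
(factor loadings and regressions), a symmetric matrix ``S`` (residual
variances/covariances and exogenous moments), a mean/intercept vector ``m``
and a filter selecting the observed rows.  The implied moments are

.. math::

    \\Sigma(\\theta) = F (I-A)^{-1} S (I-A)^{-\\top} F^\\top, \\qquad
    \\mu(\\theta) = F (I-A)^{-1} m.

Estimation maximizes the casewise (full-information) multivariate-normal
log-likelihood, so each participant contributes through the subvector of
:math:`\\mu` and submatrix of :math:`\\Sigma` matching their observed
pattern — unbiased under data missing at random.  The gradient is analytic
(chain rule through the RAM algebra), standard errors come from the inverse
observed information (numerical Hessian of the analytic gradient), and the
usual global fit indices (RMSEA with CI, SRMR, CFI, TLI) are computed
against FIML-estimated saturated and independence baselines.

Latents are identified by the marker-variable convention (first loading
fixed to 1, latent residual variance free, latent intercept 0).  Observed
exogenous predictors get free means, variances and pairwise covariances so
their own missingness is covered by FIML as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import brentq, minimize

__all__ = [
    "SEMSpec",
    "SEMMatrices",
    "SEMFit",
    "SEMModel",
    "parse_model_syntax",
    "default_pathway_spec",
    "implied_moments",
    "loglik_fiml",
    "fit_sem",
    "saturated_baseline",
    "fit_indices",
    "standardize_solution",
    "mvn_missing_ml",
]

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# model specification


@dataclass
class SEMSpec:
    """Declarative SEM: measurement, structural and covariance parts.

    Parameters
    ----------
    latents
        Mapping latent name -> ordered indicator list.  The first indicator
        is the marker (loading fixed to 1).
    regressions
        Mapping endogenous variable -> list of predictors (observed or
        latent).
    covariances
        Pairs given free (residual) covariances, e.g. among the mediators.
    """

    latents: dict[str, list[str]] = field(default_factory=dict)
    regressions: dict[str, list[str]] = field(default_factory=dict)
    covariances: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- derived views ------------------------------------------------
    @property
    def indicators(self) -> list[str]:
        seen: list[str] = []
        for inds in self.latents.values():
            for v in inds:
                if v not in seen:
                    seen.append(v)
        return seen

    @property
    def endogenous(self) -> set[str]:
        return set(self.latents) | set(self.regressions) | set(self.indicators)

    @property
    def endogenous_observed(self) -> list[str]:
        """Observed regression targets that are not factor indicators."""
        return [
            t
            for t in self.regressions
            if t not in self.latents and t not in self.indicators
        ]

    @property
    def exogenous(self) -> list[str]:
        """Observed predictors never appearing as a target or indicator."""
        out: list[str] = []
        for preds in self.regressions.values():
            for p in preds:
                if p not in self.endogenous and p not in self.latents and p not in out:
                    out.append(p)
        return out

    @property
    def observed(self) -> list[str]:
        return self.indicators + self.endogenous_observed + self.exogenous

    @property
    def variables(self) -> list[str]:
        return self.observed + list(self.latents)

    def validate(self) -> None:
        for lat, inds in self.latents.items():
            if lat in self.indicators:
                raise ValueError(f"{lat!r} is both a latent and an indicator")
            if len(inds) < 1:
                raise ValueError(f"latent {lat!r} has no indicators")
        # acyclicity of the directed part (loadings + regressions)
        edges: dict[str, list[str]] = {}
        for lat, inds in self.latents.items():
            for ind in inds:
                edges.setdefault(lat, []).append(ind)
        for tgt, preds in self.regressions.items():
            for p in preds:
                edges.setdefault(p, []).append(tgt)
        state: dict[str, int] = {}

        def dfs(v):
            state[v] = 1
            for w in edges.get(v, ()):
                if state.get(w, 0) == 1:
                    raise ValueError(f"directed cycle through {v!r} -> {w!r}")
                if state.get(w, 0) == 0:
                    dfs(w)
            state[v] = 2

        for v in list(edges):
            if state.get(v, 0) == 0:
                dfs(v)


def parse_model_syntax(text: str) -> SEMSpec:
    """Parse the compact model syntax.

    Three operators, one relation per line (``#`` comments allowed)::

        Latent =~ ind1 + ind2 + ind3      # measurement
        outcome ~ pred1 + pred2           # regression
        var1 ~~ var2                      # free (residual) covariance
    """
    latents: dict[str, list[str]] = {}
    regressions: dict[str, list[str]] = {}
    covariances: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for op in ("=~", "~~", "~"):
            if op in line:
                lhs, rhs = (s.strip() for s in line.split(op, 1))
                terms = [t.strip() for t in rhs.split("+") if t.strip()]
                if op == "=~":
                    latents.setdefault(lhs, []).extend(terms)
                elif op == "~~":
                    if len(terms) != 1:
                        raise ValueError(f"one variable per covariance line: {line!r}")
                    covariances.append((lhs, terms[0]))
                else:
                    regressions.setdefault(lhs, []).extend(terms)
                break
        else:
            raise ValueError(f"cannot parse model line: {line!r}")
    return SEMSpec(latents=latents, regressions=regressions, covariances=covariances)


def default_pathway_spec(
    exposures: tuple[str, str] = ("si_score", "li_score"),
    covariates: tuple[str, ...] = ("age", "sex", "apoe4"),
) -> SEMSpec:
    """The life-course pathway model: three pathology mediators between the
    social/lifestyle exposures and latent cognition, every path adjusted for
    age, sex and APOE-e4 carriage, mediator residuals freely correlated."""
    preds = list(exposures) + list(covariates)
    return SEMSpec(
        latents={
            "SVD": ["wmh_t", "fazekas_peri", "fazekas_deep"],
            # ptau_t is the marker so the latent points toward pathology;
            # the Abeta42/40 ratio loads negatively (lower ratio = worse)
            "ADpath": ["ptau_t", "ab_ratio", "amyloid_t"],
            "Neuro": ["hippo_nd", "thickness_nd", "bpf_nd", "fdg_nd"],
            "Cognition": ["verbal_fluency", "fcsrt_free_recall", "tmtb_t", "rey_score"],
        },
        regressions={
            "SVD": preds,
            "ADpath": preds,
            "Neuro": preds,
            "Cognition": preds + ["SVD", "ADpath", "Neuro"],
        },
        covariances=[("SVD", "ADpath"), ("SVD", "Neuro"), ("ADpath", "Neuro")],
    )


# ---------------------------------------------------------------------------
# RAM matrices and parameter map


@dataclass
class SEMMatrices:
    """RAM-form matrices over the combined observed + latent vector."""

    A: np.ndarray          # directed paths (loadings, regressions)
    S: np.ndarray          # symmetric (residual variances/covariances)
    m: np.ndarray          # means / intercepts
    obs_idx: np.ndarray    # row filter: positions of observed variables
    variables: list[str]


@dataclass(frozen=True)
class _Param:
    label: str
    mat: str               # 'A', 'S' or 'm'
    i: int
    j: int
    lhs: str
    op: str                # '=~', '~', '~~' or '~1'
    rhs: str
    lower: float = -np.inf


def implied_moments(matrices: SEMMatrices) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance over the observed variables."""
    n = matrices.A.shape[0]
    ImA = np.eye(n) - matrices.A
    try:
        B = np.linalg.inv(ImA)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "I - A is singular: the directed part of the model is cyclic or "
            "ill-posed"
        ) from err
    T = B[matrices.obs_idx, :]
    sigma = T @ matrices.S @ T.T
    mu = T @ matrices.m
    return mu, sigma


# ---------------------------------------------------------------------------
# FIML kernel over missingness patterns


def _pattern_groups(X: np.ndarray):
    """Group rows by missingness pattern.

    Returns a list of ``(var_positions, data_block, n_rows)`` with the block
    restricted to observed columns.  Rows with nothing observed are rejected.
    """
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("participants with no observed modelled variable")
    keys = np.asarray([hash(r.tobytes()) for r in obs])
    groups = []
    for key in np.unique(keys):
        rows = np.where(keys == key)[0]
        cols = np.where(obs[rows[0]])[0]
        groups.append((cols, X[np.ix_(rows, cols)], len(rows)))
    return groups


def mvn_missing_ml(mu: np.ndarray, sigma: np.ndarray, patterns) -> float:
    """Casewise multivariate-normal log-likelihood over missingness patterns."""
    ll = 0.0
    for cols, block, n_p in patterns:
        sig = sigma[np.ix_(cols, cols)]
        try:
            c, low = cho_factor(sig, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diag(c)).sum()
        xc = block - mu[cols]
        sol = cho_solve((c, low), xc.T)
        quad = np.einsum("ij,ji->", xc, sol)
        ll -= 0.5 * (n_p * (len(cols) * np.log(_TWO_PI) + logdet) + quad)
    return float(ll)


def _mvn_missing_ml_grad(mu, sigma, patterns, p):
    """Log-likelihood plus its gradients w.r.t. mu and sigma (full p x p)."""
    ll = 0.0
    G = np.zeros((p, p))
    g = np.zeros(p)
    for cols, block, n_p in patterns:
        sig = sigma[np.ix_(cols, cols)]
        try:
            c, low = cho_factor(sig, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, G, g
        logdet = 2.0 * np.log(np.diag(c)).sum()
        xc = block - mu[cols]
        sol = cho_solve((c, low), xc.T)          # sigma^-1 (x - mu)^T
        quad = np.einsum("ij,ji->", xc, sol)
        ll -= 0.5 * (n_p * (len(cols) * np.log(_TWO_PI) + logdet) + quad)
        isig = cho_solve((c, low), np.eye(len(cols)))
        C = sol @ sol.T                          # sigma^-1 Xc^T Xc sigma^-1
        G[np.ix_(cols, cols)] += 0.5 * (C - n_p * isig)
        g[cols] += sol.sum(axis=1)
    return float(ll), G, g


# ---------------------------------------------------------------------------
# the model object: parameter map, likelihood, gradient


class SEMModel:
    """A spec bound to data: parameter bookkeeping, FIML value and gradient."""

    def __init__(self, spec: SEMSpec, data: pd.DataFrame):
        self.spec = spec
        missing_cols = [v for v in spec.observed if v not in data.columns]
        if missing_cols:
            raise ValueError(f"data lacks modelled columns: {missing_cols}")
        X = data[spec.observed].to_numpy(dtype=float)
        keep = ~np.all(np.isnan(X), axis=1)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} participant(s) with no observed "
                "modelled variable",
                RuntimeWarning,
            )
            X = X[keep]
        self.X = X
        self.n_obs = X.shape[0]
        self.variables = spec.variables
        self.n_var = len(self.variables)
        self.obs_idx = np.arange(len(spec.observed))
        self._vi = {v: k for k, v in enumerate(self.variables)}
        self.patterns = _pattern_groups(X)
        self.params = self._build_params()
        self.n_free = len(self.params)
        self._fixed_A, self._fixed_S = self._fixed_matrices()

    # -- parameter table ----------------------------------------------
    def _build_params(self) -> list[_Param]:
        vi = self._vi
        spec = self.spec
        ps: list[_Param] = []
        for lat, inds in spec.latents.items():
            for ind in inds[1:]:
                ps.append(_Param(f"{lat}=~{ind}", "A", vi[ind], vi[lat], lat, "=~", ind))
        for tgt, preds in spec.regressions.items():
            for pr in preds:
                ps.append(_Param(f"{tgt}~{pr}", "A", vi[tgt], vi[pr], tgt, "~", pr))
        for lat in spec.latents:
            ps.append(
                _Param(f"{lat}~~{lat}", "S", vi[lat], vi[lat], lat, "~~", lat, 1e-8)
            )
        for a, b in spec.covariances:
            ps.append(_Param(f"{a}~~{b}", "S", vi[a], vi[b], a, "~~", b))
        for ind in spec.indicators + spec.endogenous_observed:
            ps.append(
                _Param(f"{ind}~~{ind}", "S", vi[ind], vi[ind], ind, "~~", ind, 1e-8)
            )
            ps.append(_Param(f"{ind}~1", "m", vi[ind], -1, ind, "~1", ""))
        exog = spec.exogenous
        for v in exog:
            ps.append(_Param(f"{v}~1", "m", vi[v], -1, v, "~1", ""))
            ps.append(_Param(f"{v}~~{v}", "S", vi[v], vi[v], v, "~~", v, 1e-8))
        declared = {frozenset(pair) for pair in spec.covariances}
        for a_i in range(len(exog)):
            for b_i in range(a_i + 1, len(exog)):
                a, b = exog[a_i], exog[b_i]
                if frozenset((a, b)) in declared:
                    continue
                ps.append(_Param(f"{a}~~{b}", "S", vi[a], vi[b], a, "~~", b))
        return ps

    def _fixed_matrices(self):
        """A and S cells fixed by identification (marker loadings = 1)."""
        A = np.zeros((self.n_var, self.n_var))
        S = np.zeros((self.n_var, self.n_var))
        for lat, inds in self.spec.latents.items():
            A[self._vi[inds[0]], self._vi[lat]] = 1.0
        return A, S

    def matrices(self, theta: np.ndarray) -> SEMMatrices:
        A = self._fixed_A.copy()
        S = self._fixed_S.copy()
        m = np.zeros(self.n_var)
        for val, prm in zip(theta, self.params):
            if prm.mat == "A":
                A[prm.i, prm.j] = val
            elif prm.mat == "S":
                S[prm.i, prm.j] = val
                S[prm.j, prm.i] = val
            else:
                m[prm.i] = val
        return SEMMatrices(A=A, S=S, m=m, obs_idx=self.obs_idx, variables=self.variables)

    # -- likelihood ----------------------------------------------------
    def implied(self, theta: np.ndarray):
        return implied_moments(self.matrices(theta))

    def loglik(self, theta: np.ndarray) -> float:
        mu, sigma = self.implied(theta)
        return mvn_missing_ml(mu, sigma, self.patterns)

    def loglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """FIML log-likelihood and its analytic gradient.

        Chain rule through the RAM algebra with ``B = (I-A)^{-1}`` and
        ``T = F B``: the observed-moment gradients ``G = dL/dSigma`` and
        ``g = dL/dmu`` are accumulated per missingness pattern and pulled
        back onto each free cell of A, S and m.
        """
        mat = self.matrices(theta)
        ImA = np.eye(self.n_var) - mat.A
        B = np.linalg.inv(ImA)
        T = B[mat.obs_idx, :]
        sigma = T @ mat.S @ T.T
        mu = T @ mat.m
        ll, G, g = _mvn_missing_ml_grad(mu, sigma, self.patterns, len(mat.obs_idx))
        if not np.isfinite(ll):
            return -np.inf, np.zeros(self.n_free)
        U = T.T @ G @ T                       # dL/dS pullback
        P = B @ (mat.S @ U)                   # for dL/dA
        Tg = T.T @ g
        Bm = B @ mat.m
        grad = np.empty(self.n_free)
        for k, prm in enumerate(self.params):
            if prm.mat == "A":
                grad[k] = 2.0 * P[prm.j, prm.i] + Tg[prm.i] * Bm[prm.j]
            elif prm.mat == "S":
                grad[k] = U[prm.i, prm.i] if prm.i == prm.j else 2.0 * U[prm.i, prm.j]
            else:
                grad[k] = Tg[prm.i]
        return ll, grad

    # -- parameter scaling -----------------------------------------------
    def param_scales(self) -> np.ndarray:
        """Natural scale of each free parameter, for optimizer conditioning.

        Each variable gets a scale factor: its observed SD for observed
        variables, the marker indicator's SD for latents.  A path i <- j
        scales as s_i / s_j, a (co)variance as s_i * s_j, a mean as s_i.
        Optimizing theta / scale makes every parameter O(1) regardless of
        measurement units (the FIML solution itself is equivariant).
        """
        s = np.ones(self.n_var)
        for k, v in enumerate(self.spec.observed):
            x = self.X[:, k]
            x = x[~np.isnan(x)]
            sd = float(x.std()) if x.size > 1 else 1.0
            s[self._vi[v]] = sd if sd > 0 else 1.0
        for lat, inds in self.spec.latents.items():
            s[self._vi[lat]] = s[self._vi[inds[0]]]
        d = np.empty(self.n_free)
        for k, prm in enumerate(self.params):
            if prm.mat == "A":
                d[k] = s[prm.i] / s[prm.j]
            elif prm.mat == "S":
                d[k] = s[prm.i] * s[prm.j]
            else:
                d[k] = s[prm.i]
        return d

    # -- starting values -------------------------------------------------
    def start_values(self) -> np.ndarray:
        X = self.X
        obs_names = self.spec.observed
        col = {v: X[:, k] for k, v in enumerate(obs_names)}

        def _mean(v):
            x = col[v]
            x = x[~np.isnan(x)]
            return float(x.mean()) if x.size else 0.0

        def _var(v):
            x = col[v]
            x = x[~np.isnan(x)]
            return float(x.var()) if x.size > 1 else 1.0

        def _cov(a, b):
            x, y = col[a], col[b]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3:
                return 0.0
            return float(np.cov(x[ok], y[ok], ddof=0)[0, 1])

        start = np.empty(self.n_free)
        for k, prm in enumerate(self.params):
            if prm.op == "=~":
                marker = self.spec.latents[prm.lhs][0]
                v = _var(marker)
                start[k] = _cov(prm.rhs, marker) / v if v > 0 else 1.0
            elif prm.op == "~":
                start[k] = 0.0
            elif prm.op == "~1":
                start[k] = _mean(prm.lhs)
            else:  # '~~'
                if prm.lhs != prm.rhs:
                    if prm.lhs in col and prm.rhs in col:
                        start[k] = 0.9 * _cov(prm.lhs, prm.rhs)
                    else:
                        start[k] = 0.0
                elif prm.lhs in self.spec.latents:
                    marker = self.spec.latents[prm.lhs][0]
                    start[k] = max(0.5 * _var(marker), 1e-3)
                else:
                    start[k] = max(
                        (0.5 if prm.lhs in self.spec.indicators else 1.0)
                        * _var(prm.lhs),
                        1e-3,
                    )
        return start


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SEMFit:
    """A fitted structural equation model."""

    model: SEMModel
    theta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int
    grad_norm: float
    n_obs: int
    ll_saturated: float = np.nan
    ll_baseline: float = np.nan
    df_model: int = 0
    df_baseline: int = 0
    indices: dict = field(default_factory=dict)
    std_theta: np.ndarray | None = None
    std_cov: np.ndarray | None = None

    @property
    def param_labels(self) -> list[str]:
        return [p.label for p in self.model.params]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def chi_square(self) -> float:
        return 2.0 * (self.ll_saturated - self.loglik)

    def params_frame(self, standardized: bool = False) -> pd.DataFrame:
        est = self.theta
        se = self.se
        if standardized:
            if self.std_theta is None:
                standardize_solution(self)
            est = self.std_theta
            se = np.sqrt(np.clip(np.diag(self.std_cov), 0.0, None))
        z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "label": self.param_labels,
                "lhs": [q.lhs for q in self.model.params],
                "op": [q.op for q in self.model.params],
                "rhs": [q.rhs for q in self.model.params],
                "estimate": est,
                "se": se,
                "z": z,
                "p": p,
            }
        )

    def lookup(self, lhs: str, op: str, rhs: str) -> int:
        for k, prm in enumerate(self.model.params):
            if (prm.lhs, prm.op, prm.rhs) == (lhs, op, rhs):
                return k
        raise KeyError(f"no free parameter {lhs!r} {op} {rhs!r} in the model")


def loglik_fiml(model: SEMModel, theta: np.ndarray) -> float:
    """FIML log-likelihood of the model at ``theta`` (casewise MVN)."""
    return model.loglik(theta)


def _numeric_hessian_of_grad(fun_grad, theta, step=1e-5):
    """Hessian by central differences of an analytic gradient."""
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        h = step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_sem(
    spec: SEMSpec,
    data: pd.DataFrame,
    *,
    grad_tol: float = 1e-6,
    max_iter: int = 5000,
    n_restarts: int = 3,
    bound_variances: bool = True,
    compute_indices: bool = True,
    compute_se: bool = True,
    restart_seed: int = 20230,
) -> SEMFit:
    """Fit the SEM by quasi-Newton maximization of the FIML log-likelihood.

    Starts from data-derived values (marker regressions for loadings, halved
    variances, zero structural paths); on non-convergence, up to
    ``n_restarts`` jittered restarts are attempted before the fit is flagged.
    Variance parameters are bounded away from zero by default; an estimate
    pinned near that bound is reported as a possible Heywood case.
    """
    model = SEMModel(spec, data)
    start = model.start_values()
    d = model.param_scales()

    # optimize on the scale-free parameterization theta = d * u so that
    # mixed measurement units (volumes, ratios, seconds) stay conditioned
    def objective(u):
        ll, gr = model.loglik_grad(d * u)
        if not np.isfinite(ll):
            return 1e15, np.zeros_like(u)
        return -ll / model.n_obs, -(gr * d) / model.n_obs

    bounds = None
    if bound_variances:
        bounds = [
            (prm.lower / dk, None) if np.isfinite(prm.lower) else (None, None)
            for prm, dk in zip(model.params, d)
        ]

    rng = np.random.default_rng(restart_seed)
    best = None
    attempts = 0
    u_start = start / d
    u0 = u_start.copy()
    for attempt in range(1 + n_restarts):
        attempts += 1
        res = minimize(
            objective,
            u0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 0.0, "gtol": grad_tol,
                     "maxcor": 30},
        )
        fval, gru = objective(res.x)
        ll = -fval * model.n_obs
        gnorm = float(np.max(np.abs(gru))) if np.isfinite(ll) else np.inf
        cand = (ll, d * res.x, res.nit, gnorm)
        if best is None or ll > best[0]:
            best = cand
        if gnorm <= max(grad_tol, 1e-8):
            break
        jitter = rng.normal(scale=0.1, size=u_start.size) * np.maximum(
            np.abs(u_start), 0.1
        )
        u0 = u_start + jitter
        if bounds is not None:
            lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
            u0 = np.maximum(u0, lo + 1e-6)

    ll, theta, nit, gnorm = best
    converged = gnorm <= max(grad_tol, 1e-8)
    if not converged:
        warnings.warn(
            f"SEM fit did not reach gradient tolerance after {attempts} "
            f"attempt(s): max |grad| = {gnorm:.3g}",
            RuntimeWarning,
        )

    for k, prm in enumerate(model.params):
        if prm.op == "~~" and prm.lhs == prm.rhs and theta[k] < 1e-6:
            warnings.warn(
                f"residual variance {prm.label} pinned near zero "
                "(possible Heywood case)",
                RuntimeWarning,
            )

    cov = np.full((model.n_free, model.n_free), np.nan)
    if compute_se:
        H = -_numeric_hessian_of_grad(model.loglik_grad, theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            warnings.warn("observed information singular; SEs use pseudo-inverse",
                          RuntimeWarning)
        if np.any(np.diag(cov) < 0):
            warnings.warn(
                "negative variance in inverse information; SEs unreliable",
                RuntimeWarning,
            )

    fit = SEMFit(
        model=model,
        theta=theta,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iterations=nit,
        grad_norm=gnorm,
        n_obs=model.n_obs,
    )

    if compute_indices:
        sat_ll, base_ll, df_model, df_base = saturated_baseline(
            data[spec.observed], n_free_model=model.n_free
        )
        fit.ll_saturated = sat_ll
        fit.ll_baseline = base_ll
        fit.df_model = df_model
        fit.df_baseline = df_base
        fit.indices = fit_indices(fit, model.n_obs)
    return fit


# ---------------------------------------------------------------------------
# saturated and baseline models


def _em_saturated(X: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """FIML-saturated MVN moments via the EM algorithm for missing data.

    E-step: per missingness pattern, expected sufficient statistics of the
    missing block given the observed block.  M-step: update mean and
    covariance.  With complete data this converges in one step to the sample
    mean and the n-denominator covariance.
    """
    n, p = X.shape
    obs_mask = ~np.isnan(X)
    mu = np.array([np.nanmean(X[:, j]) for j in range(p)])
    var = np.array([max(np.nanvar(X[:, j]), 1e-6) for j in range(p)])
    sigma = np.diag(var)
    patterns = {}
    for i in range(n):
        patterns.setdefault(obs_mask[i].tobytes(), []).append(i)

    ll_prev = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for key, rows in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            o = np.where(mask)[0]
            mvars = np.where(~mask)[0]
            Xo = X[np.ix_(rows, o)]
            n_p = len(rows)
            sig_oo = sigma[np.ix_(o, o)]
            c, low = cho_factor(sig_oo, lower=True)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            xc = Xo - mu[o]
            sol = cho_solve((c, low), xc.T)
            ll -= 0.5 * (
                n_p * (len(o) * np.log(_TWO_PI) + logdet)
                + np.einsum("ij,ji->", xc, sol)
            )
            if mvars.size:
                sig_mo = sigma[np.ix_(mvars, o)]
                Em = mu[mvars][None, :] + (sig_mo @ sol).T
                cond_cov = sigma[np.ix_(mvars, mvars)] - sig_mo @ cho_solve(
                    (c, low), sig_mo.T
                )
            else:
                Em = np.empty((n_p, 0))
                cond_cov = np.empty((0, 0))
            full = np.empty((n_p, p))
            full[:, o] = Xo
            if mvars.size:
                full[:, mvars] = Em
            sum_x += full.sum(axis=0)
            sum_xx += full.T @ full
            if mvars.size:
                sum_xx[np.ix_(mvars, mvars)] += n_p * cond_cov
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        mu, sigma = mu_new, sigma_new
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
        ll_prev = ll
    pattern_groups = _pattern_groups(X)
    return mu, sigma, mvn_missing_ml(mu, sigma, pattern_groups)


def saturated_baseline(
    data: pd.DataFrame, n_free_model: int | None = None
) -> tuple[float, float, int, int]:
    """FIML log-likelihoods of the saturated and independence models.

    The saturated model frees every mean and covariance (estimated by EM);
    the baseline frees means and variances only.  Returns
    ``(ll_saturated, ll_baseline, df_model, df_baseline)``; ``df_model`` is
    computed when the model's free-parameter count is supplied, else 0.
    """
    X = data.to_numpy(dtype=float)
    X = X[~np.all(np.isnan(X), axis=1)]
    p = X.shape[1]
    _, _, ll_sat = _em_saturated(X)
    # baseline: each variable separately, per-variable ML mean and variance
    ll_base = 0.0
    for j in range(p):
        x = X[:, j]
        x = x[~np.isnan(x)]
        v = max(x.var(), 1e-12)
        ll_base += -0.5 * x.size * (np.log(_TWO_PI) + np.log(v) + 1.0)
    n_moments = p * (p + 3) // 2
    df_model = (n_moments - n_free_model) if n_free_model is not None else 0
    df_base = n_moments - 2 * p
    return float(ll_sat), float(ll_base), df_model, df_base


# ---------------------------------------------------------------------------
# fit indices


def _rmsea_ci(T: float, df: int, n: int, level: float) -> tuple[float, float]:
    """Noncentrality-based RMSEA confidence bounds by root-finding."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def bound(q):
        # find lambda with ncx2.cdf(T; df, lambda) = q
        f = lambda lam: stats.ncx2.cdf(T, df, lam) - q
        if f(0.0) < 0:
            return 0.0
        hi = max(T, 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2.0
        if f(hi) > 0:
            return np.nan
        return brentq(f, 0.0, hi, xtol=1e-10)

    lam_lo = bound(lo_q)
    lam_hi = bound(hi_q)
    scale = df * n
    return (
        float(np.sqrt(max(lam_lo, 0.0) / scale)),
        float(np.sqrt(max(lam_hi, 0.0) / scale)),
    )


def fit_indices(fit: SEMFit, n: int, rmsea_ci_level: float = 0.90) -> dict:
    """RMSEA (with CI), SRMR, CFI and TLI from the fitted chi-squares.

    ``T = 2(ll_sat - ll_model)`` against ``df`` degrees of freedom; the
    baseline statistic analogously.  SRMR compares FIML-saturated and
    model-implied covariances on the correlation scale.  With ``df = 0``
    RMSEA/CFI/TLI are reported as NaN (undefined).
    """
    T = 2.0 * (fit.ll_saturated - fit.loglik)
    Tb = 2.0 * (fit.ll_saturated - fit.ll_baseline)
    df, df_b = fit.df_model, fit.df_baseline

    out = {"chi_square": float(T), "df": int(df),
           "baseline_chi_square": float(Tb), "baseline_df": int(df_b)}
    if df > 0:
        out["rmsea"] = float(np.sqrt(max(T - df, 0.0) / (df * n)))
        lo, hi = _rmsea_ci(T, df, n, rmsea_ci_level)
        out["rmsea_ci_lower"], out["rmsea_ci_upper"] = lo, hi
        out["rmsea_ci_level"] = rmsea_ci_level
        denom = max(Tb - df_b, T - df, 0.0)
        out["cfi"] = 1.0 - (max(T - df, 0.0) / denom if denom > 0 else 0.0)
        out["tli"] = (
            ((Tb / df_b) - (T / df)) / ((Tb / df_b) - 1.0)
            if df_b > 0 and (Tb / df_b) != 1.0
            else np.nan
        )
    else:
        out["rmsea"] = out["rmsea_ci_lower"] = out["rmsea_ci_upper"] = np.nan
        out["cfi"] = out["tli"] = np.nan

    # SRMR: residual standardized moments, FIML-saturated vs implied
    X = fit.model.X
    _, sig_sat, _ = _em_saturated(X)
    _, sig_hat = fit.model.implied(fit.theta)
    d = np.sqrt(np.diag(sig_sat))
    resid = (sig_sat - sig_hat) / np.outer(d, d)
    iu = np.triu_indices_from(resid)
    out["srmr"] = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return out


# ---------------------------------------------------------------------------
# standardized solution


def _standardize_map(model: SEMModel, theta: np.ndarray) -> np.ndarray:
    """Map raw free parameters to the standardized solution.

    Paths are multiplied by sd(source)/sd(target) under the model-implied
    full covariance (latents included); covariances become correlations on
    the implied-SD scale; intercepts/means are divided by the variable's SD.
    """
    mat = model.matrices(theta)
    B = np.linalg.inv(np.eye(model.n_var) - mat.A)
    V = B @ mat.S @ B.T
    sd = np.sqrt(np.clip(np.diag(V), 0.0, None))
    if np.any(sd <= 0):
        bad = model.variables[int(np.argmin(sd))]
        raise ValueError(f"zero implied variance for {bad!r}; cannot standardize")
    out = np.empty(model.n_free)
    for k, prm in enumerate(model.params):
        if prm.mat == "A":
            out[k] = theta[k] * sd[prm.j] / sd[prm.i]
        elif prm.mat == "S":
            out[k] = theta[k] / (sd[prm.i] * sd[prm.j])
        else:
            out[k] = theta[k] / sd[prm.i]
    return out


def standardize_solution(fit: SEMFit) -> pd.DataFrame:
    """Standardized estimates with delta-method SEs.

    The standardization map is differentiated numerically (central
    differences) and the raw estimate covariance is propagated through it;
    results are cached on the fit.
    """
    model = fit.model
    theta = fit.theta
    std = _standardize_map(model, theta)
    J = np.zeros((model.n_free, model.n_free))
    for i in range(model.n_free):
        h = 1e-6 * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        J[:, i] = (_standardize_map(model, tp) - _standardize_map(model, tm)) / (2 * h)
    fit.std_theta = std
    fit.std_cov = J @ fit.cov @ J.T
    return fit.params_frame(standardized=True)
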