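"""Binomial-logit mixed model with one random intercept per social group.

The marginal likelihood

    L(beta, sigma) = prod_g  integral  prod_{i in g} Bernoulli(y_i | expit(x_i' beta + u))
                               * Normal(u; 0, sigma^2) du

is maximized by adaptive Gauss-Hermite quadrature (AGQ): per group the
integrand is re-centered at its mode u_g-hat and re-scaled by the curvature
there, so a modest node count (default 15) integrates it essentially
exactly. sigma is optimized on the log scale with a boundary guard that
falls back to the plain-logistic limit when sigma-hat collapses to zero.

Also provides the Wald machinery used downstream: likelihood-ratio tests of
nested fits, pairwise contrasts for a categorical fixed effect, and
generalized variance-inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2, norm

from shellrank.design import Design, ModelSpec, build_design
from shellrank.errors import ConvergenceError, NestingError, SchemaError, ValidationError

_LOG_SIGMA_LO, _LOG_SIGMA_HI = np.log(1e-3), np.log(25.0)
_SEPARATION_THRESHOLD = 10.0


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return y * eta - np.logaddexp(0.0, eta)


def _find_modes(
    eta0: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    n_groups: int,
    sigma: float,
    u0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group Newton ascent of the joint log-density in u.

    The objective is concave in u (logistic log-likelihood plus a Gaussian
    penalty), so undamped Newton with a step cap converges quickly.
    Returns the modes and the curvature -h''(u) at the mode.
    """
    inv_s2 = 1.0 / (sigma * sigma)
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    w = None
    for _ in range(max_iter):
        mu = expit(eta0 + u[g])
        grad = np.bincount(g, weights=y - mu, minlength=n_groups) - u * inv_s2
        w = np.bincount(g, weights=mu * (1.0 - mu), minlength=n_groups) + inv_s2
        step = np.clip(grad / w, -4.0, 4.0)
        u += step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(eta0 + u[g])
    w = np.bincount(g, weights=mu * (1.0 - mu), minlength=n_groups) + inv_s2
    return u, w


def agq_group_logliks(
    X: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    n_groups: int,
    beta: np.ndarray,
    sigma: float,
    n_nodes: int = 15,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group AGQ marginal log-likelihood contributions and modes."""
    eta0 = X @ beta
    u, w = _find_modes(eta0, y, g, n_groups, sigma, u0=u0)
    tau = 1.0 / np.sqrt(w)

    # probabilists' Hermite rule: integral f(z) exp(-z^2/2) dz ~ sum w_k f(z_k)
    z, wq = hermegauss(n_nodes)
    log_wq = np.log(wq)
    inv_2s2 = 0.5 / (sigma * sigma)

    # all (group, node) displacements at once; group sums via reduceat over
    # rows sorted by group (every group code occurs at least once)
    order = np.argsort(g, kind="stable")
    starts = np.flatnonzero(np.r_[True, np.diff(g[order]) > 0])
    U = u[:, None] + tau[:, None] * z[None, :]  # (G, K)
    ETA = eta0[:, None] + U[g, :]  # (n, K)
    LL = y[:, None] * ETA - np.logaddexp(0.0, ETA)
    lg = np.add.reduceat(LL[order], starts, axis=0)  # (G, K)
    contrib = log_wq[None, :] + 0.5 * z[None, :] ** 2 + lg - U * U * inv_2s2
    m = contrib.max(axis=1)
    log_int = m + np.log(np.exp(contrib - m[:, None]).sum(axis=1)) + np.log(tau)
    # Gaussian density normalizer for u ~ N(0, sigma^2)
    ll_g = log_int - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    return ll_g, u


def agq_marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    n_nodes: int = 15,
) -> float:
    """Marginal log-likelihood at a fixed parameter point (oracle-testable)."""
    n_groups = int(groups.max()) + 1
    ll_g, _ = agq_group_logliks(X, y, groups, n_groups, np.asarray(beta, float), float(sigma), n_nodes)
    return float(ll_g.sum())


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Plain logistic regression by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        zr = eta + (y - mu) / w
        beta_new = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ zr)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    ll = float(_bernoulli_loglik(X @ beta, y).sum())
    return beta, ll


def _numdiff_hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] * h[i])
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


@dataclass
class GLMMFit:
    """Fitted binomial random-intercept GLMM."""

    spec: ModelSpec
    columns: list[str]
    beta: np.ndarray  # fixed effects, log-odds scale
    se: np.ndarray
    vcov: np.ndarray  # fixed-effects covariance
    sigma: float  # random-intercept SD
    u_modes: np.ndarray  # posterior modes, one per group
    group_levels: list
    factor_levels: dict
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    n_nodes: int
    n_params: int  # fixed effects + variance parameter

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.columns)

    def coef_table(self) -> pd.DataFrame:
        z = np.where(self.se > 0, self.beta / self.se, np.nan)
        return pd.DataFrame(
            {
                "term": self.columns,
                "estimate": self.beta,
                "se": self.se,
                "z": z,
                "p": 2.0 * norm.sf(np.abs(z)),
            }
        )

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "vcov": self.vcov.tolist(),
            "sigma": self.sigma,
            "u_modes": self.u_modes.tolist(),
            "group_levels": list(map(str, self.group_levels)),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


def fit_glmm(
    spec: ModelSpec,
    df: pd.DataFrame,
    n_nodes: int = 15,
    start: tuple[np.ndarray, float] | None = None,
    max_iter: int = 500,
    design: Design | None = None,
    y_override: np.ndarray | None = None,
    compute_se: bool = True,
) -> GLMMFit:
    """Maximum-likelihood fit of the binomial random-intercept GLMM.

    Parameters
    ----------
    start:
        Optional warm start ``(beta, sigma)`` (used heavily by the
        permutation refits of the attractiveness index).
    design, y_override:
        Internal fast path: a prebuilt design and a replacement response
        vector, so permutation refits skip design construction.
    compute_se:
        Skip the numerical Hessian when standard errors are not needed
        (again for permutation refits, which only use predictions).
    """
    if spec.group is None:
        raise SchemaError("GLMM requires a grouping column for the random intercept")
    d = design if design is not None else build_design(spec, df)
    y = np.asarray(y_override if y_override is not None else d.y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("GLMM response must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("GLMM response has a single level")
    X, g = d.X, d.groups
    n_groups = len(d.group_levels)
    if n_groups < 2:
        raise ValidationError("GLMM requires at least 2 groups")
    p = X.shape[1]

    if start is not None:
        beta0 = np.asarray(start[0], dtype=float)
        logsig0 = np.log(max(float(start[1]), 2e-3))
    else:
        beta0, _ = _irls_logistic(X, y)
        logsig0 = np.log(0.5)
    theta0 = np.append(beta0, logsig0)

    u_state = {"u": np.zeros(n_groups)}

    def nll(theta: np.ndarray) -> float:
        beta, sigma = theta[:p], float(np.exp(theta[p]))
        ll_g, u = agq_group_logliks(X, y, g, n_groups, beta, sigma, n_nodes, u0=u_state["u"])
        u_state["u"] = u
        val = ll_g.sum()
        return -val if np.isfinite(val) else 1e12

    res = minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(_LOG_SIGMA_LO, _LOG_SIGMA_HI)],
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
    )
    theta = res.x
    converged = bool(res.success)
    if not converged:
        # accept a line-search stall if we are already at a stationary point
        gmax = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        if gmax < 1e-3:
            converged = True
        else:
            raise ConvergenceError(f"GLMM optimizer failed: {res.message}", trace=res)

    sigma = float(np.exp(theta[p]))
    if theta[p] <= _LOG_SIGMA_LO + 1e-9:
        # boundary guard: the random intercept collapses; report the
        # plain-logistic limit with sigma = 0
        beta_hat, ll0 = _irls_logistic(X, y)
        theta = np.append(beta_hat, _LOG_SIGMA_LO)
        sigma = 0.0
        loglik = ll0
        u_modes = np.zeros(n_groups)
    else:
        beta_hat = theta[:p]
        ll_g, u_modes = agq_group_logliks(X, y, g, n_groups, beta_hat, sigma, n_nodes)
        loglik = float(ll_g.sum())

    if np.any(np.abs(beta_hat) > _SEPARATION_THRESHOLD):
        warnings.warn(
            "possible complete separation: |beta| > 10 on the fitted scale",
            RuntimeWarning,
            stacklevel=2,
        )

    if compute_se and sigma > 0.0:
        H = _numdiff_hessian(nll, theta)
        vcov_all = _safe_inverse(H)
        vcov = vcov_all[:p, :p]
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    elif compute_se:
        # sigma = 0: observed information of the plain logistic model
        mu = expit(X @ beta_hat)
        info = (X * (mu * (1.0 - mu))[:, None]).T @ X
        vcov = _safe_inverse(info)
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    else:
        vcov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)

    return GLMMFit(
        spec=spec,
        columns=d.columns,
        beta=np.asarray(beta_hat, dtype=float),
        se=se,
        vcov=vcov,
        sigma=sigma,
        u_modes=u_modes,
        group_levels=d.group_levels,
        factor_levels=d.factor_levels,
        loglik=loglik,
        converged=converged,
        n_obs=len(y),
        n_groups=n_groups,
        n_nodes=n_nodes,
        n_params=p + 1,
    )


def _safe_inverse(A: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


def predict_conditional(fit: GLMMFit, df: pd.DataFrame) -> np.ndarray:
    """Conditional predictions expit(x' beta-hat + u-hat_g), strictly in (0,1).

    Rows whose group did not appear in fitting raise; the model has no
    marginal fallback.
    """
    d = build_design(fit.spec, df, response=False)
    level_index = {lvl: i for i, lvl in enumerate(fit.group_levels)}
    ids = df[fit.spec.group].astype(str)
    unseen = sorted(set(ids) - set(level_index))
    if unseen:
        raise ValidationError(f"groups not seen in fitting: {', '.join(unseen)}")
    if d.columns != fit.columns:
        raise SchemaError(
            "prediction design does not match the fitted design "
            f"({d.columns} vs {fit.columns})"
        )
    g = np.array([level_index[i] for i in ids])
    return expit(d.X @ fit.beta + fit.u_modes[g])


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str


def lrt(full: GLMMFit, reduced: GLMMFit) -> TestResult:
    """Likelihood-ratio test of nested fits (same rows, reduced terms subset)."""
    if full.n_obs != reduced.n_obs or full.spec.response != reduced.spec.response:
        raise NestingError("LRT requires the same response on the same rows")
    if not set(reduced.columns) <= set(full.columns):
        raise NestingError("reduced model terms are not a subset of the full model")
    df_diff = full.n_params - reduced.n_params
    if df_diff < 0:
        raise NestingError("full model has fewer parameters than reduced")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        warnings.warn(
            f"LRT statistic {stat:.3g} < 0 beyond numerical tolerance; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df_diff)) if df_diff > 0 else 1.0
    return TestResult(statistic=float(stat), df=df_diff, p_value=p, method="LRT")


def contrast(fit: GLMMFit, factor: str, a: str, b: str) -> dict:
    """Wald contrast of level ``a`` minus level ``b`` of a fitted factor."""
    if factor not in fit.factor_levels:
        raise SchemaError(f"{factor!r} is not a fitted categorical fixed effect")
    levels = fit.factor_levels[factor]
    for lvl in (a, b):
        if lvl not in levels:
            raise SchemaError(f"unknown level {lvl!r} of factor {factor!r}")
    c = np.zeros(len(fit.beta))
    for lvl, sign in ((a, 1.0), (b, -1.0)):
        if lvl != levels[0]:  # reference level has an implicit zero coefficient
            c[fit.columns.index(f"{factor}[{lvl}]")] += sign
    est = float(c @ fit.beta)
    var = float(c @ fit.vcov @ c)
    se = float(np.sqrt(var)) if var > 0 else 0.0
    z = est / se if se > 0 else float("nan")
    p = 2.0 * float(norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return {"level_a": a, "level_b": b, "estimate": est, "se": se, "z": z, "p": p}


def wald_contrasts(fit: GLMMFit, factor: str) -> pd.DataFrame:
    """All pairwise level contrasts of ``factor`` with univariate (unadjusted)
    normal p-values."""
    if factor not in fit.factor_levels:
        raise SchemaError(f"{factor!r} is not a fitted categorical fixed effect")
    levels = fit.factor_levels[factor]
    rows = [contrast(fit, factor, a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    return pd.DataFrame(rows)


def vif(spec: ModelSpec, df: pd.DataFrame) -> dict:
    """Generalized variance-inflation factors per fixed-effect term.

    Uses the determinant-ratio formulation on the correlation matrix of the
    design columns, so multi-column (categorical or interaction) terms get
    a single GVIF. All values are >= 1 for a full-rank design.
    """
    d = build_design(spec, df, response=False)
    cols = [i for i in range(d.p) if d.columns[i] != "(Intercept)"]
    Xc = d.X[:, cols]
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [d.columns[cols[i]] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant design columns: {', '.join(bad)}")
    R = np.corrcoef(Xc, rowvar=False)
    if R.ndim == 0:
        R = np.array([[1.0]])
    det_R = np.linalg.det(R)
    out = {}
    index_of = {c: k for k, c in enumerate(cols)}
    for term, tcols in d.term_columns.items():
        if term == "(Intercept)":
            continue
        idx = [index_of[c] for c in tcols]
        rest = [k for k in range(len(cols)) if k not in idx]
        if not rest:
            out[term] = 1.0
            continue
        g = (
            np.linalg.det(R[np.ix_(idx, idx)])
            * np.linalg.det(R[np.ix_(rest, rest)])
            / det_R
        )
        out[term] = float(max(g, 1.0)) if np.isfinite(g) else float("inf")
    return out
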