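"""Baseline-category multinomial logit for occupant-class partitioning.

For K occupant classes the model is

    log[ P(class k) / P(baseline) ] = x' gamma_k,   k = 2..K,

fit by Newton-Raphson with step-halving on the exact multinomial
log-likelihood. Releveling to a new baseline is the linear identity
gamma_{a|b} = gamma_{a|c} - gamma_{b|c}, with the covariance propagated
through the same linear map, which is how all pairwise class comparisons
are read off one fit.

Group identity enters as fixed-effect dummies; groups with few occupants
can separate, in which case the fit warns and an optional tiny ridge on the
group dummies (off by default) is available to stabilize them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from shellrank.design import ModelSpec, build_design
from shellrank.errors import ConvergenceError, SchemaError, ValidationError

_SEPARATION_THRESHOLD = 15.0


@dataclass
class MNLogitFit:
    baseline: str
    category_names: list  # baseline first
    predictor_names: list  # design columns incl. intercept and dummies
    gamma: np.ndarray  # (K-1, p)
    se: np.ndarray  # (K-1, p)
    vcov: np.ndarray  # ((K-1)p, (K-1)p), class-major flattening
    loglik: float
    converged: bool
    n_obs: int
    spec: ModelSpec
    separation_warning: bool = False

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    def coef_table(self, hide_terms: tuple = ()) -> pd.DataFrame:
        """Long coefficient table (one block per non-baseline category)."""
        rows = []
        for k, cat in enumerate(self.category_names[1:]):
            for j, term in enumerate(self.predictor_names):
                if any(term.startswith(h) for h in hide_terms):
                    continue
                est, se = self.gamma[k, j], self.se[k, j]
                z = est / se if se > 0 else float("nan")
                rows.append(
                    {
                        "baseline": self.baseline,
                        "category": cat,
                        "term": term,
                        "estimate": est,
                        "se": se,
                        "z": z,
                        "p": 2.0 * float(norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
                    }
                )
        return pd.DataFrame(rows)


def _category_order(levels: list, baseline: str) -> list:
    canonical = sorted(levels)
    if baseline not in canonical:
        raise ValidationError(f"baseline {baseline!r} not among categories {canonical}")
    return [baseline] + [c for c in canonical if c != baseline]


def _log_probs(X: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """(n, K) log category probabilities, baseline column first (pinned at 0)."""
    eta = np.hstack([np.zeros((X.shape[0], 1)), X @ gamma.T])
    return eta - logsumexp(eta, axis=1, keepdims=True)


def fit_mnlogit(
    df: pd.DataFrame,
    predictors: list[str],
    response: str,
    baseline: str,
    references: dict | None = None,
    categories: list | None = None,
    ridge: float = 0.0,
    ridge_prefix: str | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MNLogitFit:
    """Maximum-likelihood baseline-category logit.

    ``ridge``/``ridge_prefix`` optionally penalize (0.5*ridge*gamma^2) only
    the design columns whose names start with ``ridge_prefix`` (intended
    for group-ID dummies); the default is the unpenalized likelihood.
    """
    spec = ModelSpec(response=response, fixed=predictors, references=references)
    d = build_design(spec, df, response=False)
    X = d.X
    levels = pd.unique(df[response].dropna()).tolist()
    cats = _category_order(levels, baseline)
    if categories is not None:
        missing = sorted(set(categories) - set(levels))
        if missing:
            raise ValidationError(f"categories with zero rows: {', '.join(map(str, missing))}")
    y = pd.Categorical(df[response], categories=cats).codes.astype(int)
    if (y < 0).any():
        raise ValidationError("response contains values outside the category set")
    n, p = X.shape
    K = len(cats)
    if K < 2:
        raise ValidationError("need at least 2 response categories")

    pen = np.zeros(p)
    if ridge > 0.0 and ridge_prefix is not None:
        pen[[j for j, c in enumerate(d.columns) if c.startswith(ridge_prefix)]] = ridge

    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0

    gamma = np.zeros((K - 1, p))

    def penalized_loglik(gam: np.ndarray) -> float:
        lp = _log_probs(X, gam)
        return float(lp[np.arange(n), y].sum() - 0.5 * np.sum(pen * gam * gam))

    ll = penalized_loglik(gamma)
    converged = False
    for _ in range(max_iter):
        P = np.exp(_log_probs(X, gamma))  # (n, K)
        grad = np.empty((K - 1, p))
        for k in range(1, K):
            grad[k - 1] = X.T @ (Y[:, k] - P[:, k]) - pen * gamma[k - 1]
        gvec = grad.ravel()
        if np.max(np.abs(gvec)) < tol:
            converged = True
            break
        H = np.empty(((K - 1) * p, (K - 1) * p))
        for k in range(1, K):
            for l in range(k, K):
                w = P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
                blk = (X * w[:, None]).T @ X
                if k == l:
                    blk = blk + np.diag(pen)
                H[(k - 1) * p : k * p, (l - 1) * p : l * p] = blk
                H[(l - 1) * p : l * p, (k - 1) * p : k * p] = blk.T
        try:
            step = np.linalg.solve(H, gvec).reshape(K - 1, p)
        except np.linalg.LinAlgError:
            step = (np.linalg.pinv(H) @ gvec).reshape(K - 1, p)
        # step-halving: insist the (penalized) log-likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = gamma + scale * step
            ll_new = penalized_loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            converged = np.max(np.abs(gvec)) < 1e-3
            break
        gamma, ll = cand, ll_new

    if not converged:
        P = np.exp(_log_probs(X, gamma))
        gmax = max(
            float(np.max(np.abs(X.T @ (Y[:, k] - P[:, k]) - pen * gamma[k - 1])))
            for k in range(1, K)
        )
        if gmax >= 1e-3:
            raise ConvergenceError(
                f"multinomial Newton-Raphson did not converge (grad max {gmax:.2e})"
            )
        converged = True

    separation = bool(np.any(np.abs(gamma) > _SEPARATION_THRESHOLD))
    if separation:
        warnings.warn(
            "possible separation in multinomial fit: |gamma| > 15",
            RuntimeWarning,
            stacklevel=2,
        )

    # observed information at the optimum
    P = np.exp(_log_probs(X, gamma))
    H = np.empty(((K - 1) * p, (K - 1) * p))
    for k in range(1, K):
        for l in range(k, K):
            w = P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
            blk = (X * w[:, None]).T @ X
            if k == l:
                blk = blk + np.diag(pen)
            H[(k - 1) * p : k * p, (l - 1) * p : l * p] = blk
            H[(l - 1) * p : l * p, (k - 1) * p : k * p] = blk.T
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None)).reshape(K - 1, p)

    return MNLogitFit(
        baseline=baseline,
        category_names=cats,
        predictor_names=d.columns,
        gamma=gamma,
        se=se,
        vcov=vcov,
        loglik=float(penalized_loglik(gamma)) if ridge == 0.0 else _unpenalized(X, y, gamma),
        converged=converged,
        n_obs=n,
        spec=spec,
        separation_warning=separation,
    )


def _unpenalized(X: np.ndarray, y: np.ndarray, gamma: np.ndarray) -> float:
    lp = _log_probs(X, gamma)
    return float(lp[np.arange(len(y)), y].sum())


def relevel(fit: MNLogitFit, new_baseline: str) -> MNLogitFit:
    """Re-express the fit against a new baseline category.

    Uses gamma_{a|b} = gamma_{a|old} - gamma_{b|old} (with the old
    baseline's coefficients pinned at zero) and pushes the covariance
    through the same linear map, so no refit is needed.
    """
    if new_baseline not in fit.category_names:
        raise ValidationError(f"unknown category {new_baseline!r}")
    if new_baseline == fit.baseline:
        return replace(fit)
    p = len(fit.predictor_names)
    old_nonbase = fit.category_names[1:]
    new_cats = _category_order(fit.category_names, new_baseline)

    def old_rows(cat):
        """Row-selection vector over old non-baseline categories (len K-1)."""
        v = np.zeros(len(old_nonbase))
        if cat != fit.baseline:
            v[old_nonbase.index(cat)] = 1.0
        return v

    L = np.zeros(((fit.n_categories - 1) * p, (fit.n_categories - 1) * p))
    for knew, cat in enumerate(new_cats[1:]):
        coef = old_rows(cat) - old_rows(new_baseline)
        for kold in range(len(old_nonbase)):
            if coef[kold] != 0.0:
                L[knew * p : (knew + 1) * p, kold * p : (kold + 1) * p] = coef[kold] * np.eye(p)

    gamma_old = fit.gamma.reshape(-1)
    gamma_new = (L @ gamma_old).reshape(fit.n_categories - 1, p)
    vcov_new = L @ fit.vcov @ L.T
    se_new = np.sqrt(np.clip(np.diag(vcov_new), 0.0, None)).reshape(fit.n_categories - 1, p)
    return replace(
        fit,
        baseline=new_baseline,
        category_names=new_cats,
        gamma=gamma_new,
        se=se_new,
        vcov=vcov_new,
    )


def predict_category_probs(fit: MNLogitFit, df: pd.DataFrame) -> pd.DataFrame:
    """Per-row category probabilities (softmax with the baseline pinned at 0)."""
    d = build_design(fit.spec, df, response=False)
    if d.columns != fit.predictor_names:
        raise SchemaError(
            "prediction design does not match the fitted design; "
            "check factor levels (e.g. unseen group dummies)"
        )
    P = np.exp(_log_probs(d.X, fit.gamma))
    return pd.DataFrame(P, columns=fit.category_names, index=df.index)
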