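"""Random-intercept logistic regression (binomial GLMM).

The model is

    logit P(y = 1) = xᵀβ + u_g,    u_g ~ N(0, σ_g²)

with one scalar random intercept per group (a mouse or an
experiment).  The marginal likelihood integrates the random intercept
out of each group's contribution; the integral is evaluated by
*adaptive* Gauss–Hermite quadrature — nodes centred on each group's
posterior mode and scaled by the curvature there — which is accurate
for binary data even with few groups, and the fixed effects, the
random-intercept standard deviation σ_g (optimised on the log scale)
and the per-group posterior modes are estimated by direct maximisation
of the marginal log-likelihood.  A fit that collapses to the σ_g → 0
boundary is refitted as a plain logistic GLM.

Data may be supplied as Bernoulli rows or grouped (successes, trials);
rows sharing a group and covariate pattern are aggregated internally,
which leaves the likelihood unchanged and makes large per-cell tables
cheap to fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .errors import ConvergenceError, ValidationError
from .glm import GLMFit, fit_binomial_glm

_SIGMA2_BOUNDARY = 1e-8


@dataclass
class GLMMFit:
    """A fitted random-intercept logistic model."""

    params: pd.Series               # fixed effects on the logit scale
    vcov: pd.DataFrame              # fixed-effect covariance
    sigma2: float                   # random-intercept variance σ_g²
    group_effects: pd.Series        # posterior modes of u_g
    loglik: float
    n_obs: int
    n_groups: int
    n_quad: int
    converged: bool
    method: str                     # "adaptive-gauss-hermite" or "collapsed-glm"
    use_t: bool = False
    dispersion: float = 1.0
    df_resid: int = 0
    kind: str = "binomial-glmm"
    link: str = "logit"

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index
        )

    def summary(self) -> pd.DataFrame:
        from scipy.stats import norm

        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = self.params / se
        return pd.DataFrame(
            {"estimate": self.params, "se": se, "stat": stat,
             "p": 2 * norm.sf(np.abs(stat))}
        )


def _aggregate(X, y, trials, groups, names):
    """Collapse rows sharing (group, covariate pattern) into binomial cells."""
    df = pd.DataFrame(X, columns=names)
    df["__y"] = y
    df["__n"] = trials
    df["__g"] = groups
    agg = df.groupby(["__g"] + names, sort=True, as_index=False)[["__y", "__n"]].sum()
    out = []
    for g, sub in agg.groupby("__g", sort=True):
        out.append(
            (g, sub[names].to_numpy(dtype=float),
             sub["__y"].to_numpy(dtype=float), sub["__n"].to_numpy(dtype=float))
        )
    return out


def _group_mode(Xb, s, n, sigma2, tol=1e-10, max_iter=100):
    """Posterior mode of u for one group (Newton on the log joint)."""
    u = 0.0
    for _ in range(max_iter):
        p = expit(Xb + u)
        g = np.sum(s - n * p) - u / sigma2
        h = -np.sum(n * p * (1 - p)) - 1.0 / sigma2
        step = -g / h
        step = np.clip(step, -5.0, 5.0)
        u += step
        if abs(step) < tol:
            break
    p = expit(Xb + u)
    h = -np.sum(n * p * (1 - p)) - 1.0 / sigma2
    return u, h


def _marginal_loglik(beta, log_sigma, blocks, nodes, weights):
    """Adaptive Gauss–Hermite marginal log-likelihood over all groups."""
    sigma = np.exp(log_sigma)
    sigma2 = sigma * sigma
    total = 0.0
    modes = []
    for _, Xg, s, n, lchoose in blocks:
        Xb = Xg @ beta
        u_hat, h = _group_mode(Xb, s, n, sigma2)
        modes.append(u_hat)
        tau = 1.0 / np.sqrt(-h)
        u_k = u_hat + np.sqrt(2.0) * tau * nodes
        eta = Xb[:, None] + u_k[None, :]
        # grouped-binomial log joint at each node, including the N(0, σ²) prior
        ll = (s[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)).sum(axis=0)
        ll += lchoose
        ll += -0.5 * u_k**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        total += logsumexp(ll + nodes**2 + np.log(weights)) + 0.5 * np.log(2.0) + np.log(tau)
    return total, np.array(modes)


def fit_binomial_glmm(
    design,
    response,
    groups,
    trials=None,
    n_quad: int = 25,
) -> GLMMFit:
    """Fit a random-intercept logistic model by adaptive quadrature.

    ``design`` is a design matrix (DataFrame or array), ``response``
    Bernoulli 0/1 or grouped successes with ``trials``, and ``groups``
    the per-row group labels.  Requires at least two groups (with one
    group the random intercept is not identified — fit a plain GLM).
    """
    from .glm import _as_matrix  # shared validation

    X, names = _as_matrix(design)
    y = np.asarray(response, dtype=float)
    n = np.ones_like(y) if trials is None else np.asarray(trials, dtype=float)
    groups = np.asarray(groups)
    if not (len(y) == len(n) == len(groups) == X.shape[0]):
        raise ValidationError("design, response, trials and groups lengths differ")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValidationError(
            "only one group: the random intercept is not estimable; "
            "use fit_binomial_glm instead"
        )
    if n_quad < 5:
        raise ValidationError("n_quad must be >= 5")

    cells = _aggregate(X, y, n, groups, names)
    blocks = []
    for g, Xg, s, ng, in cells:
        lchoose = float(np.sum(gammaln(ng + 1) - gammaln(s + 1) - gammaln(ng - s + 1)))
        blocks.append((g, Xg, s, ng, lchoose))
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    glm0 = fit_binomial_glm(pd.DataFrame(X, columns=names), y, n)
    x0 = np.append(glm0.params.to_numpy(), np.log(0.5))

    def negll(theta):
        ll, _ = _marginal_loglik(theta[:-1], theta[-1], blocks, nodes, weights)
        return -ll

    bounds = [(None, None)] * X.shape[1] + [(np.log(1e-5), np.log(50.0))]
    res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    if not res.success and res.status != 2:  # status 2: precision loss at optimum
        raise ConvergenceError(
            f"marginal likelihood maximisation failed: {res.message}"
        )
    beta_hat, log_sigma_hat = res.x[:-1], res.x[-1]
    sigma2_hat = float(np.exp(2 * log_sigma_hat))

    idx = pd.Index(names)
    group_names = [b[0] for b in blocks]
    # σ → 0 limit of the marginal likelihood, in the same (grouped,
    # binomial-coefficient-inclusive) convention as the quadrature
    beta0 = glm0.params.to_numpy()
    ll_limit = 0.0
    for _, Xg, s, ng, lchoose in blocks:
        eta = Xg @ beta0
        ll_limit += float(np.sum(s * eta - ng * np.logaddexp(0.0, eta))) + lchoose
    ll_hat, modes = _marginal_loglik(beta_hat, log_sigma_hat, blocks, nodes, weights)
    flat_boundary = ll_hat <= ll_limit + 1e-6
    if sigma2_hat < _SIGMA2_BOUNDARY or flat_boundary:
        # boundary collapse: the data carry no between-group variance
        return GLMMFit(
            params=glm0.params, vcov=glm0.vcov, sigma2=0.0,
            group_effects=pd.Series(0.0, index=group_names),
            loglik=float(ll_limit), n_obs=len(y), n_groups=len(uniq),
            n_quad=n_quad, converged=True, method="collapsed-glm",
            df_resid=glm0.df_resid,
        )

    H = _num_hessian(negll, res.x)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    cov_fixed = cov_all[: len(names), : len(names)]
    return GLMMFit(
        params=pd.Series(beta_hat, index=idx),
        vcov=pd.DataFrame(cov_fixed, index=idx, columns=idx),
        sigma2=sigma2_hat,
        group_effects=pd.Series(modes, index=group_names),
        loglik=float(ll_hat), n_obs=len(y), n_groups=len(uniq),
        n_quad=n_quad, converged=True, method="adaptive-gauss-hermite",
        df_resid=len(y) - len(names) - 1,
    )


def _num_hessian(fun, x, rel_step=1e-4):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H
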