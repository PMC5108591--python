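"""Factorial and dose–response regression models, fitted from first
principles.

The model family covers the designs used throughout the analysis:

* grouped/Bernoulli **binomial logistic** models (maximum likelihood by
  iteratively reweighted least squares), for ratios such as the fusion
  index or marker fractions — linear predictor
  y = µ + Σ β·δ (+ c·concentration), the log-odds of the outcome;
* **quasi-Poisson** log-link count models with Pearson-estimated
  dispersion φ and t-based p-values, for cell counts;
* ordinary **linear models** with t-based approximate p-values, for
  continuous responses such as per-frame eccentricity;
* Wald **effect reports** — odds/rate ratios with 95% intervals
  exp(β̂ ± 1.96·SE), and per-condition fitted ratios whose interval can
  optionally omit the error contribution of the baseline (intercept),
  a convention some summary tables use for treatment conditions.

Design matrices are treatment-coded (reference level absorbed by the
intercept) with a fixed, documented column order: intercept, main
effects, interactions, dose, batch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit, gammaln
from scipy.stats import norm, t as t_dist

from .errors import ConvergenceError, DesignError, SeparationError, ValidationError

_Z95 = 1.96  # Wald 95% multiplier, matching the ± SE reporting convention


# ---------------------------------------------------------------------------
# model specification and design construction

@dataclass
class ModelSpec:
    """Declarative description of one regression model.

    ``response`` is a column name, or a ``(successes, trials)`` pair of
    column names for grouped binomial data.  ``factors`` are treated as
    categorical with the reference level taken from ``references`` or
    the smallest observed level.  ``interactions`` are tuples of factor
    names.  ``dose_term`` enters linearly; ``batch_term`` is a
    categorical nuisance factor; ``random_intercept`` names a grouping
    column (handled by the mixed-model fitter, not here).
    """

    response_kind: str                      # binomial-grouped | binomial-bernoulli | count | continuous
    response: str | tuple[str, str]
    factors: list[str] = field(default_factory=list)
    interactions: list[tuple[str, ...]] = field(default_factory=list)
    dose_term: str | None = None
    batch_term: str | None = None
    random_intercept: str | None = None
    references: dict = field(default_factory=dict)

    _LINKS = {
        "binomial-grouped": "logit", "binomial-bernoulli": "logit",
        "count": "log", "continuous": "identity",
    }

    def __post_init__(self):
        if self.response_kind not in self._LINKS:
            raise ValidationError(
                f"unknown response_kind {self.response_kind!r}; "
                f"expected one of {sorted(self._LINKS)}"
            )
        if self.response_kind == "binomial-grouped" and not (
            isinstance(self.response, (tuple, list)) and len(self.response) == 2
        ):
            raise ValidationError(
                "binomial-grouped response must be a (successes, trials) pair"
            )
        for inter in self.interactions:
            for name in inter:
                if name not in self.factors:
                    raise ValidationError(
                        f"interaction member {name!r} is not a declared factor"
                    )

    @property
    def link(self) -> str:
        return self._LINKS[self.response_kind]


@dataclass
class DesignMatrices:
    """A built design: named matrix, response, and optional trials."""

    X: pd.DataFrame
    y: np.ndarray
    trials: np.ndarray | None
    spec: ModelSpec
    groups: np.ndarray | None = None

    def condition_contrasts(self) -> pd.DataFrame:
        """Unique design rows, labelled by their factor/dose values."""
        uniq = self.X.drop_duplicates().reset_index(drop=True)
        labels = []
        for _, row in uniq.iterrows():
            parts = [
                name if v == 1 else f"{name}={v:g}"
                for name, v in row.items()
                if name != "(Intercept)" and v != 0
            ]
            labels.append(" & ".join(parts) if parts else "baseline")
        uniq.index = pd.Index(labels, name="condition")
        return uniq


def _factor_columns(data: pd.DataFrame, factor: str, reference) -> dict[str, np.ndarray]:
    levels = pd.unique(data[factor])
    levels = sorted(levels, key=lambda v: (str(type(v)), v))
    if reference is None:
        reference = levels[0]
    elif reference not in levels:
        raise ValidationError(f"reference level {reference!r} not found in {factor!r}")
    cols = {}
    for lev in levels:
        if lev == reference:
            continue
        cols[f"{factor}[{lev}]"] = (data[factor] == lev).to_numpy(dtype=float)
    return cols


def build_design(spec: ModelSpec, data: pd.DataFrame) -> DesignMatrices:
    """Build a treatment-coded design matrix and extract the response.

    Column order: ``(Intercept)``, main effects (factor order as
    declared, levels sorted), interactions (as declared, products of
    the member columns), dose, batch dummies.  Raises
    :class:`DesignError` naming aliased columns when rank-deficient.
    """
    needed = list(spec.factors)
    needed += [spec.dose_term] if spec.dose_term else []
    needed += [spec.batch_term] if spec.batch_term else []
    resp_cols = list(spec.response) if isinstance(spec.response, (tuple, list)) else [spec.response]
    missing = [c for c in needed + resp_cols if c not in data.columns]
    if missing:
        raise ValidationError(f"data lacks required columns: {missing}")

    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(data))}
    per_factor: dict[str, dict[str, np.ndarray]] = {}
    for f in spec.factors:
        per_factor[f] = _factor_columns(data, f, spec.references.get(f))
        cols.update(per_factor[f])
    for inter in spec.interactions:
        members = [per_factor[f] for f in inter]
        for combo in itertools.product(*[m.items() for m in members]):
            name = ":".join(k for k, _ in combo)
            prod = np.ones(len(data))
            for _, v in combo:
                prod = prod * v
            cols[name] = prod
    if spec.dose_term:
        cols[spec.dose_term] = data[spec.dose_term].to_numpy(dtype=float)
    if spec.batch_term:
        cols.update(_factor_columns(data, spec.batch_term, spec.references.get(spec.batch_term)))

    X = pd.DataFrame(cols)
    _check_full_rank(X)

    if spec.response_kind == "binomial-grouped":
        succ = data[spec.response[0]].to_numpy(dtype=float)
        trials = data[spec.response[1]].to_numpy(dtype=float)
        if (trials <= 0).any():
            raise ValidationError("binomial-grouped data contains cells with trials = 0")
        if ((succ < 0) | (succ > trials)).any():
            raise ValidationError("successes must satisfy 0 <= successes <= trials")
        y = succ
    else:
        y = data[spec.response].to_numpy(dtype=float)
        trials = None
        if spec.response_kind == "binomial-bernoulli" and not np.isin(y, (0, 1)).all():
            raise ValidationError("bernoulli response must be 0/1")
        if spec.response_kind == "count" and ((y < 0) | (y != np.round(y))).any():
            raise ValidationError("count response must be non-negative integers")
    groups = (
        data[spec.random_intercept].to_numpy() if spec.random_intercept else None
    )
    return DesignMatrices(X=X, y=y, trials=trials, spec=spec, groups=groups)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    _, R, piv = linalg.qr(arr, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(arr.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        aliased = [X.columns[j] for j in piv[rank:]]
        raise DesignError(
            f"design matrix is rank deficient; aliased columns: {aliased}",
            aliased=aliased,
        )


# ---------------------------------------------------------------------------
# fits

@dataclass
class GLMFit:
    """A fitted generalized linear (or linear) model."""

    params: pd.Series
    vcov: pd.DataFrame
    dispersion: float
    loglik: float | None
    df_resid: int
    n_obs: int
    kind: str
    link: str
    converged: bool = True
    n_iter: int = 0
    use_t: bool = False
    fitted: np.ndarray | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = self.params / se
        if self.use_t:
            p = 2 * t_dist.sf(np.abs(stat), self.df_resid)
        else:
            p = 2 * norm.sf(np.abs(stat))
        return pd.DataFrame(
            {"estimate": self.params, "se": se, "stat": stat, "p": p}
        )


def _as_matrix(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, DesignMatrices):
        design = design.X
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    arr = np.asarray(design, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("design must be a 2-D matrix")
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _wls_solve(X, W, z):
    XtW = X.T * W
    return np.linalg.solve(XtW @ X, XtW @ z), XtW @ X


def fit_binomial_glm(design, successes, trials=None) -> GLMFit:
    """Maximum-likelihood logistic regression by IRLS.

    Accepts grouped data (``successes`` out of ``trials``) or Bernoulli
    0/1 outcomes (``trials`` omitted); both representations of the same
    data give identical coefficients.  Convergence at max |Δβ| < 1e-10
    within 100 iterations; diverging coefficients (|β| > 30 on the
    logit scale) raise :class:`SeparationError`.
    """
    X, names = _as_matrix(design)
    y = np.asarray(successes, dtype=float)
    n = np.ones_like(y) if trials is None else np.asarray(trials, dtype=float)
    if (n <= 0).any():
        raise ValidationError("all cells must have trials > 0")
    if ((y < 0) | (y > n)).any():
        raise ValidationError("successes must lie in [0, trials]")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("design and response lengths differ")

    beta = np.zeros(X.shape[1])
    info = None
    trace = []
    for it in range(1, 101):
        eta = X @ beta
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        W = n * p * (1 - p)
        z = eta + (y - n * p) / W
        beta_new, info = _wls_solve(X, W, z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        trace.append((it, step, beta.copy()))
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "coefficients diverged (|beta| > 30 on the logit scale); "
                "complete or quasi-complete separation"
            )
        if step < 1e-10:
            break
    else:
        raise ConvergenceError("IRLS did not converge in 100 iterations", trace=trace)

    eta = X @ beta
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + y * np.log(p) + (n - y) * np.log1p(-p)
    ))
    vcov = np.linalg.inv(info)
    idx = pd.Index(names)
    return GLMFit(
        params=pd.Series(beta, index=idx),
        vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        dispersion=1.0, loglik=ll, df_resid=len(y) - X.shape[1],
        n_obs=len(y), kind="binomial", link="logit",
        n_iter=it, fitted=p,
    )


def fit_quasipoisson_glm(design, counts) -> GLMFit:
    """Quasi-Poisson log-link regression by IRLS.

    Dispersion φ is the Pearson estimator X²/(n − p); standard errors
    are scaled by √φ and p-values use a t distribution on n − p
    degrees of freedom.
    """
    X, names = _as_matrix(design)
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise ValidationError("counts must be non-negative")
    if not y.any():
        raise ValidationError("all-zero count response cannot be fitted")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("design and response lengths differ")

    eta = np.log(y + 0.5)
    beta = np.zeros(X.shape[1])
    info = None
    trace = []
    for it in range(1, 101):
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / mu
        beta_new, info = _wls_solve(X, W, z)
        step = np.max(np.abs(beta_new - beta)) if it > 1 else np.inf
        beta = beta_new
        eta = X @ beta
        trace.append((it, step, beta.copy()))
        if step < 1e-10:
            break
    else:
        raise ConvergenceError("IRLS did not converge in 100 iterations", trace=trace)

    mu = np.exp(X @ beta)
    df_resid = len(y) - X.shape[1]
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / df_resid if df_resid > 0 else np.nan
    vcov = np.linalg.inv(info) * phi
    idx = pd.Index(names)
    return GLMFit(
        params=pd.Series(beta, index=idx),
        vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        dispersion=phi, loglik=None, df_resid=df_resid,
        n_obs=len(y), kind="quasipoisson", link="log",
        n_iter=it, use_t=True, fitted=mu,
    )


def fit_linear_model(design, response) -> GLMFit:
    """Ordinary least squares with t-based approximate p-values."""
    X, names = _as_matrix(design)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"need n > p observations (n={n}, p={p})")
    _check_full_rank(pd.DataFrame(X, columns=names))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    vcov = s2 * np.linalg.inv(X.T @ X)
    idx = pd.Index(names)
    return GLMFit(
        params=pd.Series(beta, index=idx),
        vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        dispersion=s2, loglik=None, df_resid=n - p, n_obs=n,
        kind="linear", link="identity", use_t=True, fitted=X @ beta,
    )


# ---------------------------------------------------------------------------
# reporting

_INVLINK = {"logit": expit, "log": np.exp, "identity": lambda x: x}
_RATIO_NAME = {"logit": "odds_ratio", "log": "rate_ratio"}


@dataclass
class EffectReport:
    """Wald effect table and per-condition fitted values for one fit."""

    terms: pd.DataFrame
    conditions: pd.DataFrame | None
    omit_intercept_error: bool
    link: str

    def to_frame(self) -> pd.DataFrame:
        return self.terms


def effect_report(
    fit: GLMFit,
    conditions: pd.DataFrame | None = None,
    omit_intercept_error: bool = False,
    ratios: bool = True,
) -> EffectReport:
    """Build the per-term and per-condition Wald report for a fit.

    Per term: estimate, SE, test statistic, p, and (for logit/log
    links) the exponentiated ratio with 95% interval
    exp(estimate ± 1.96·SE).  ``conditions`` is a matrix of contrast
    rows (e.g. :meth:`DesignMatrices.condition_contrasts`); each row's
    fitted value on the response scale is reported with its delta-
    method interval.  With ``omit_intercept_error`` the variance
    contribution of the intercept (and its covariances) is excluded for
    non-baseline conditions, reproducing the convention of summary
    tables that quote treatment intervals without the baseline error;
    the baseline row, whose only term is the intercept, keeps the full
    variance.
    """
    if ratios and fit.link == "identity":
        raise ValidationError(
            "ratios are undefined for an identity-link fit; pass ratios=False"
        )
    terms = fit.summary()
    if ratios:
        name = _RATIO_NAME[fit.link]
        terms[name] = np.exp(terms["estimate"])
        terms["ci_low"] = np.exp(terms["estimate"] - _Z95 * terms["se"])
        terms["ci_high"] = np.exp(terms["estimate"] + _Z95 * terms["se"])
    else:
        terms["ci_low"] = terms["estimate"] - _Z95 * terms["se"]
        terms["ci_high"] = terms["estimate"] + _Z95 * terms["se"]

    cond_table = None
    if conditions is not None:
        V = fit.vcov.to_numpy()
        names = list(fit.params.index)
        inv = _INVLINK[fit.link]
        try:
            i_int = names.index("(Intercept)")
        except ValueError:
            i_int = None
        rows = []
        for label, row in conditions.iterrows():
            x = row.reindex(names).to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValidationError(f"condition {label!r} misses design columns")
            eta = float(x @ fit.params.to_numpy())
            is_baseline = i_int is not None and np.all(
                (np.arange(len(x)) == i_int) | (x == 0)
            )
            if omit_intercept_error and i_int is not None and not is_baseline:
                x_var = x.copy()
                x_var[i_int] = 0.0
            else:
                x_var = x
            se_eta = float(np.sqrt(max(x_var @ V @ x_var, 0.0)))
            rows.append(
                {
                    "condition": label, "eta": eta, "se_eta": se_eta,
                    "fitted": float(inv(eta)),
                    "ci_low": float(inv(eta - _Z95 * se_eta)),
                    "ci_high": float(inv(eta + _Z95 * se_eta)),
                }
            )
        cond_table = pd.DataFrame(rows).set_index("condition")
    return EffectReport(
        terms=terms, conditions=cond_table,
        omit_intercept_error=omit_intercept_error, link=fit.link,
    )
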