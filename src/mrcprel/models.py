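"""Trend models for the epoch-selection analysis.

Two families of fits, both with a single random intercept grouped by dataset
(the repeated unit across raters and sessions):

* a Gaussian linear mixed model for cosine similarity across conditions
  (REML via statsmodels MixedLM), followed by Tukey-adjusted pairwise
  condition contrasts;
* a logistic mixed model for the probability of a matched epoch as a
  function of cosine similarity (and rater experience), fitted by maximising
  the marginal likelihood with adaptive Gauss-Hermite quadrature over the
  random intercept. A plain fixed-effects logistic fit by IRLS is provided
  both as the zero-variance limit of the GLMM and as the engine for fast
  likelihood-ratio calibration.

Condition factors use treatment coding with ``healthy_voluntary`` as the
reference; per-condition similarity trends are the simple slopes
(reference slope + interaction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "ContrastResult",
    "LRTResult",
    "SeparationError",
    "ConvergenceError",
    "fit_lmm_random_intercept",
    "pairwise_tukey",
    "fit_logistic_irls",
    "irls_logistic",
    "fit_glmm_logit_random_intercept",
    "lrt",
    "probability_curve",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge."""


@dataclass(frozen=True)
class ModelSpec:
    """Model description: response, fixed-effect terms (patsy syntax, may
    include interactions), one optional grouping variable for a random
    intercept, and the family."""

    response: str
    fixed_terms: Sequence[str]
    cluster: str | None = None
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        if not self.fixed_terms:
            raise ValueError("at least one fixed term (use '1' for intercept-only)")

    @property
    def formula(self) -> str:
        return f"{self.response} ~ " + " + ".join(self.fixed_terms)


@dataclass
class FitResult:
    """A fitted model: per-term coefficient table plus fit metadata.

    ``params`` has index = term names and columns estimate, se, stat, p.
    ``random_intercept_sd`` is on the response (gaussian) or logit
    (binomial) scale; None for purely fixed-effects fits.
    """

    params: pd.DataFrame
    loglike: float
    n_params: int
    n_obs: int
    family: str
    converged: bool
    n_iter: int
    random_intercept_sd: float | None = None
    n_groups: int | None = None
    boundary: bool = False
    df_contrast: float | None = None
    design_info: object | None = field(default=None, repr=False)
    data: pd.DataFrame | None = field(default=None, repr=False)
    cov: np.ndarray | None = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def wald_ci(self, term: str, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        est = self.params.loc[term, "estimate"]
        se = self.params.loc[term, "se"]
        return float(est - z * se), float(est + z * se)


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple[str, str]
    estimate: float
    se: float
    t_stat: float
    adjusted_p: float
    df: float


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float
    clamped: bool = False


# ---------------------------------------------------------------------------
# Gaussian linear mixed model (REML, statsmodels backend)
# ---------------------------------------------------------------------------

def fit_lmm_random_intercept(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """REML fit of a Gaussian model with one random intercept.

    Returns fixed effects with t statistics, the random-intercept SD (0 and
    flagged ``boundary`` when the variance estimate hits the boundary), and
    the REML criterion as ``loglike``. ``df_contrast`` is the between-cluster
    df (n_clusters - n_fixed) used for Tukey contrasts downstream.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm_random_intercept requires a gaussian spec")
    if spec.cluster is None:
        raise ValueError("spec.cluster must name the grouping variable")
    import statsmodels.formula.api as smf

    groups = data[spec.cluster]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    # lbfgs can park the variance exactly on the boundary, where the fixed-
    # effect covariance degenerates to NaN; powell approaches it smoothly
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            model = smf.mixedlm(spec.formula, data=data, groups=groups)
            res = model.fit(reml=True, method=method, maxiter=500)
            if res.converged and np.isfinite(res.bse_fe.values).all():
                break
    if res is None or not res.converged:
        raise ConvergenceError(
            f"MixedLM did not converge for {spec.formula!r}; "
            f"optimizer history: {getattr(res, 'hist', None)}"
        )
    fe = res.fe_params
    names = list(fe.index)
    params = pd.DataFrame(
        {
            "estimate": fe.values,
            "se": res.bse_fe.values,
            "stat": res.tvalues[names].values,
            "p": res.pvalues[names].values,
        },
        index=names,
    )
    re_var = float(np.asarray(res.cov_re)[0, 0])
    # boundary judged relative to the residual variance: a cluster variance
    # this many orders below it is indistinguishable from zero, and the fit
    # is reported with variance exactly 0, flagged
    boundary = re_var <= 1e-6 * float(res.scale)
    if boundary:
        re_var = 0.0
    cov = np.asarray(res.cov_params())[: len(names), : len(names)]
    return FitResult(
        params=params,
        loglike=float(res.llf),
        n_params=len(names) + 2,  # fixed effects + 2 variance components
        n_obs=int(res.nobs),
        family="gaussian",
        converged=True,
        n_iter=-1,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        n_groups=int(groups.nunique()),
        boundary=boundary,
        df_contrast=float(groups.nunique() - len(names)),
        design_info=model.data.design_info,
        data=data,
        cov=cov,
    )


def _reference_row(data: pd.DataFrame, overrides: Mapping[str, object]) -> pd.DataFrame:
    """One-row frame at covariate reference values: numeric columns at their
    mean, non-numeric at their first sorted level, with overrides applied."""
    row = {}
    for col in data.columns:
        if col in overrides:
            row[col] = overrides[col]
        elif pd.api.types.is_numeric_dtype(data[col]):
            row[col] = float(data[col].mean())
        else:
            row[col] = sorted(data[col].astype(str).unique())[0]
    return pd.DataFrame([row])


def pairwise_tukey(fit: FitResult, factor: str) -> list[ContrastResult]:
    """All pairwise contrasts of the levels of ``factor`` with Tukey
    (studentized-range) adjusted p-values.

    Level means are model-predicted at reference values of the remaining
    covariates; the contrast variance comes from the fixed-effect covariance.
    With two levels the adjusted p equals the unadjusted two-sided t p.
    """
    if fit.design_info is None or fit.data is None or fit.cov is None:
        raise ValueError("fit does not carry the design information needed")
    if factor not in fit.data.columns:
        raise ValueError(f"factor {factor!r} absent from the model data")
    levels = sorted(fit.data[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels")
    rows = {
        lv: patsy.build_design_matrices(
            [fit.design_info], _reference_row(fit.data, {factor: lv})
        )[0][0]
        for lv in levels
    }
    beta = fit.params["estimate"].values
    df = fit.df_contrast if fit.df_contrast and fit.df_contrast > 0 else max(
        fit.n_obs - len(beta), 1
    )
    out = []
    k = len(levels)
    for i in range(k):
        for j in range(i + 1, k):
            c = np.asarray(rows[levels[i]]) - np.asarray(rows[levels[j]])
            est = float(c @ beta)
            var = float(c @ fit.cov @ c)
            se = float(np.sqrt(max(var, 0.0)))
            t = est / se if se > 0 else np.inf
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
            out.append(
                ContrastResult(
                    pair=(levels[i], levels[j]),
                    estimate=est,
                    se=se,
                    t_stat=float(t),
                    adjusted_p=p_adj,
                    df=float(df),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Fixed-effects logistic regression (IRLS)
# ---------------------------------------------------------------------------

def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FitResult:
    """Maximum-likelihood logistic regression by IRLS on explicit matrices.

    Convergence on deviance change < ``tol``. Diverging coefficients
    (|beta| > 30) signal complete or quasi-complete separation and raise
    :class:`SeparationError` naming the offending term.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(p)
    dev_old = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, X.T @ (w * z))
        if np.max(np.abs(beta_new)) > 30.0:
            bad = names[int(np.argmax(np.abs(beta_new)))]
            raise SeparationError(
                f"separation detected: coefficient for {bad!r} is diverging"
            )
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta
        dev = -2.0 * float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        # under separation the deviance plateaus while the coefficients keep
        # drifting, so convergence requires both to settle
        if abs(dev_old - dev) < tol and step < 1e-6 * (1.0 + np.max(np.abs(beta))):
            break
        dev_old = dev
    else:
        if dev < 1e-6 * n:
            # a perfect fit the coefficients keep chasing: separation
            bad = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"separation detected: coefficient for {bad!r} is diverging"
            )
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    mu = special.expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    llf = float(np.sum(y * (X @ beta) - np.logaddexp(0.0, X @ beta)))
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "stat": zstat, "p": pvals}, index=list(names)
    )
    return FitResult(
        params=params,
        loglike=llf,
        n_params=p,
        n_obs=n,
        family="binomial",
        converged=True,
        n_iter=n_iter,
        cov=cov,
    )


def fit_logistic_irls(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Formula front-end to :func:`irls_logistic` (fixed effects only)."""
    if spec.family != "binomial":
        raise ValueError("fit_logistic_irls requires a binomial spec")
    ymat, X = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    fit = irls_logistic(X.values, ymat.values.ravel(), names=list(X.columns))
    fit.design_info = X.design_info
    fit.data = data
    return fit


# ---------------------------------------------------------------------------
# Logistic GLMM with one random intercept (adaptive Gauss-Hermite)
# ---------------------------------------------------------------------------

def _glmm_negll_factory(X, y, gidx, n_groups, quad_points):
    """Build the negative marginal log-likelihood for a random-intercept
    logistic model, with per-group posterior modes warm-started between
    evaluations (they move little along the optimizer path)."""
    nodes, weights = np.polynomial.hermite.hermgauss(quad_points)
    log_w = np.log(weights)
    state = {"u": np.zeros(n_groups)}

    def negll(theta: np.ndarray) -> float:
        beta, tau = theta[:-1], theta[-1]
        eta0 = X @ beta
        if tau < 1e-8:
            ll = float(np.sum(y * eta0 - np.logaddexp(0.0, eta0)))
            return -ll
        inv_t2 = 1.0 / (tau * tau)
        u = state["u"].copy()
        for _ in range(50):
            eta = eta0 + u[gidx]
            mu = special.expit(eta)
            grad = np.bincount(gidx, weights=y - mu, minlength=n_groups) - u * inv_t2
            hess = (
                np.bincount(gidx, weights=mu * (1.0 - mu), minlength=n_groups) + inv_t2
            )
            step = grad / hess
            u += np.clip(step, -4.0, 4.0)
            if np.max(np.abs(step)) < 1e-9:
                break
        state["u"] = u
        sd = 1.0 / np.sqrt(hess)
        # adaptive Gauss-Hermite: integral ~ sqrt(2)*sd * sum_k w_k e^{z_k^2}
        # * integrand(u_hat + sqrt(2)*sd*z_k)
        log_terms = np.empty((quad_points, n_groups))
        for kq, (z, lw) in enumerate(zip(nodes, log_w)):
            uk = u + np.sqrt(2.0) * sd * z
            eta = eta0 + uk[gidx]
            lp = np.bincount(
                gidx, weights=y * eta - np.logaddexp(0.0, eta), minlength=n_groups
            )
            lp += -0.5 * (uk * uk) * inv_t2 - 0.5 * np.log(2.0 * np.pi * tau * tau)
            log_terms[kq] = lw + z * z + lp
        ll_g = special.logsumexp(log_terms, axis=0) + 0.5 * np.log(2.0) + np.log(sd)
        return -float(ll_g.sum())

    return negll


def fit_glmm_logit_random_intercept(
    data: pd.DataFrame,
    spec: ModelSpec,
    quad_points: int = 25,
) -> FitResult:
    """Logistic mixed model with one random intercept.

    The marginal likelihood integrates the random intercept out by adaptive
    Gauss-Hermite quadrature (default 25 nodes) centred on each group's
    posterior mode; fixed effects and the random-intercept SD are then found
    by quasi-Newton maximisation. Wald SEs come from the numerical Hessian
    at the optimum. A variance estimate on the boundary (SD ~ 0) is returned
    converged and flagged; the fit then coincides with plain IRLS logistic
    regression.
    """
    if spec.family != "binomial":
        raise ValueError("fit_glmm_logit_random_intercept requires a binomial spec")
    if spec.cluster is None:
        raise ValueError("spec.cluster must name the grouping variable")
    if quad_points < 1:
        raise ValueError("quad_points must be >= 1")
    ymat, Xdf = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    X = Xdf.values
    y = ymat.values.ravel()
    names = list(Xdf.columns)
    codes, uniques = pd.factorize(data[spec.cluster])
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    try:
        start = irls_logistic(X, y, names=names)
        beta0 = start.params["estimate"].values
    except SeparationError:
        raise
    except ConvergenceError:
        beta0 = np.zeros(X.shape[1])
    theta0 = np.concatenate([beta0, [0.5]])

    negll = _glmm_negll_factory(X, y, codes, n_groups, quad_points)
    bounds = [(None, None)] * X.shape[1] + [(0.0, None)]
    res = optimize.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ConvergenceError(f"GLMM optimisation failed: {res.message}")
    theta = res.x
    tau = float(theta[-1])
    boundary = tau < 1e-4

    # numerical Hessian (central differences) for Wald SEs
    p = theta.size
    h = 1e-4 * (1.0 + np.abs(theta))
    if boundary:
        h[-1] = 1e-4  # one-sided region; keep the step inside tau >= 0
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            tpp = np.clip(theta + ei + ej, [b[0] if b[0] is not None else -np.inf for b in bounds], np.inf)
            tpm = np.clip(theta + ei - ej, [b[0] if b[0] is not None else -np.inf for b in bounds], np.inf)
            tmp = np.clip(theta - ei + ej, [b[0] if b[0] is not None else -np.inf for b in bounds], np.inf)
            tmm = np.clip(theta - ei - ej, [b[0] if b[0] is not None else -np.inf for b in bounds], np.inf)
            H[i, j] = H[j, i] = (
                negll(tpp) - negll(tpm) - negll(tmp) + negll(tmm)
            ) / (4.0 * h[i] * h[j])
    try:
        cov_all = np.linalg.pinv(H)
        se_all = np.sqrt(np.clip(np.diag(cov_all), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - pathological Hessian
        cov_all = np.full((p, p), np.nan)
        se_all = np.full(p, np.nan)

    beta = theta[:-1]
    se = se_all[:-1]
    zstat = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "stat": zstat, "p": pvals}, index=names
    )
    return FitResult(
        params=params,
        loglike=-float(res.fun),
        n_params=p,
        n_obs=len(y),
        family="binomial",
        converged=True,
        n_iter=int(res.nit),
        random_intercept_sd=tau,
        n_groups=n_groups,
        boundary=boundary,
        design_info=Xdf.design_info,
        data=data,
        cov=cov_all[: len(names), : len(names)],
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio test and probability curves
# ---------------------------------------------------------------------------

def lrt(full: FitResult, reduced: FitResult, tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test of nested fits on the same data.

    chi2 = 2 (llf_full - llf_reduced), df = parameter-count difference.
    A slightly negative chi2 (within ``tol``) is clamped to 0 and flagged;
    beyond tolerance it signals non-convergence and raises.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced fits must use the same data")
    chi2 = 2.0 * (full.loglike - reduced.loglike)
    clamped = False
    if chi2 < 0:
        if chi2 < -tol * max(1.0, abs(full.loglike)):
            raise ValueError(
                f"full model log-likelihood below reduced ({chi2/2:.6g}); "
                "a fit has not converged"
            )
        chi2 = 0.0
        clamped = True
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi2=float(chi2), df=int(df), p=p, clamped=clamped)


def probability_curve(
    fit: FitResult,
    predictor: str,
    grid: Sequence[float],
    at: Mapping[str, object] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predicted matched-epoch probability over a grid of one predictor.

    The linear predictor is evaluated at reference values of the remaining
    covariates (numeric at their mean, factors at their first level, both
    overridable via ``at``); for a mixed fit this is the curve of a typical
    cluster (random intercept at 0). The Wald CI is formed on the logit
    scale and transformed, so the interval respects [0, 1]. Grid points
    outside the observed predictor range are computed but flagged
    ``extrapolated``.
    """
    if fit.family != "binomial":
        raise ValueError("probability curves are defined for binomial fits")
    if fit.design_info is None or fit.data is None or fit.cov is None:
        raise ValueError("fit does not carry the design information needed")
    if predictor not in fit.data.columns:
        raise ValueError(f"predictor {predictor!r} absent from the model data")
    at = dict(at or {})
    beta = fit.params["estimate"].values
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    obs_lo = float(fit.data[predictor].min())
    obs_hi = float(fit.data[predictor].max())
    rows = []
    for g in grid:
        at[predictor] = g
        x = np.asarray(
            patsy.build_design_matrices([fit.design_info], _reference_row(fit.data, at))[0]
        )[0]
        eta = float(x @ beta)
        se = float(np.sqrt(max(x @ fit.cov @ x, 0.0)))
        rows.append(
            {
                predictor: float(g),
                "probability": float(special.expit(eta)),
                "ci_low": float(special.expit(eta - zcrit * se)),
                "ci_high": float(special.expit(eta + zcrit * se)),
                "extrapolated": not (obs_lo <= float(g) <= obs_hi),
            }
        )
    return pd.DataFrame(rows)
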