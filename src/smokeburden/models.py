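"""Two-level (country random-intercept) regression.

Respondents (level 1) are nested in countries (level 2) through a normally
distributed country intercept u_j ~ N(0, sigma_u^2):

* continuous burden indicators (never smokers included as zeros):
      y_ij = x_ij' beta + u_j + e_ij,          e_ij ~ N(0, sigma_e^2)
  estimated by REML.  The random-intercept structure admits a closed-form
  GLS fit for any variance ratio psi = sigma_u^2 / sigma_e^2 (group-wise
  partial centering), so REML reduces to a one-dimensional optimization
  over psi — exact and fast enough for simulation studies with hundreds of
  refits.

* binary indicators:
      logit P(y_ij = 1) = x_ij' beta + u_j
  estimated by maximum likelihood with the per-country integral evaluated
  by adaptive Gauss-Hermite quadrature (nodes centred and scaled at each
  country's conditional mode).

Confidence intervals are Wald-type on the link scale, exponentiated to
odds ratios for logistic models.  Fits are unweighted by default — design
weights belong to the descriptive estimates, models are fit on raw
observations — with a weighted pseudo-likelihood option behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

# reference level first; remaining levels get dummy columns, matching the
# conventional reporting order (reference rows marked "(Ref.)")
FACTOR_LEVELS: Mapping[str, tuple] = {
    "sex": ("male", "female"),
    "age_band": ("15_24", "25_34", "35_44", "45_54", "55_64", "65_74", "75_plus"),
    "education_end": ("le15", "16_19", "ge20", "still_studying"),
    "paying_bills": ("most_of_time", "time_to_time", "almost_never"),
    "residence": ("rural", "small_town", "large_town"),
    "occupation": ("employed", "unemployed", "not_working"),
    "marital": ("single_no_child", "single_child", "multi_no_child", "multi_child"),
    "tcs_category": ("low", "moderate", "high"),
}

DEFAULT_FIXED_EFFECTS = tuple(FACTOR_LEVELS)

_AGE_BAND_EDGES = (15, 25, 35, 45, 55, 65, 75)


class SeparationError(RuntimeError):
    """Quasi-complete separation: a term's estimate diverges."""


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, ordered fixed-effect factors, grouping and reporting scale."""

    outcome: str
    fixed_effects: Sequence[str] = DEFAULT_FIXED_EFFECTS
    grouping: str = "country"
    scale: str = "beta"  # "beta" | "odds_ratio"
    weighted: bool = False


@dataclass
class ModelFit:
    coefficients: dict[str, tuple[float, float, float]]  # term -> (est, lo, hi)
    random_intercept_sd: float
    n_obs: int
    n_groups: int
    converged: bool
    scale: str
    loglik: float = np.nan
    residual_sd: float = np.nan
    _se: dict[str, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = [
            {"term": term, "estimate": est, "ci_low": lo, "ci_high": hi}
            for term, (est, lo, hi) in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


def add_age_band(df: pd.DataFrame) -> pd.DataFrame:
    """Append the questionnaire age bands (15-24 ... >=75) derived from age."""
    out = df.copy()
    idx = np.searchsorted(_AGE_BAND_EDGES, out["age"].to_numpy(), side="right") - 1
    if (idx < 0).any():
        raise ValueError("age below 15 in model data")
    out["age_band"] = np.asarray(FACTOR_LEVELS["age_band"])[idx]
    return out


def build_design(df: pd.DataFrame, factors: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies with fixed reference levels.

    Levels absent from the data get no column (they would be identically
    zero and make the design singular).
    """
    columns = [np.ones(len(df))]
    names = ["intercept"]
    for factor in factors:
        if factor not in df.columns:
            raise ValueError(f"model factor {factor!r} missing from data")
        values = df[factor]
        if values.isna().any():
            raise ValueError(f"missing values in factor {factor!r}; exclude listwise first")
        levels = FACTOR_LEVELS[factor]
        present = set(values.unique())
        unknown = present - set(levels)
        if unknown:
            raise ValueError(f"unknown levels {sorted(unknown)} in factor {factor!r}")
        for level in levels[1:]:
            if level not in present:
                continue
            columns.append((values == level).to_numpy(dtype=float))
            names.append(f"{factor}[{level}]")
    return np.column_stack(columns), names


def _prepare(df: pd.DataFrame, spec: ModelSpec):
    data = df
    if "age_band" in spec.fixed_effects and "age_band" not in df.columns:
        data = add_age_band(df)
    data = data.sort_values(spec.grouping, kind="stable")
    X, names = build_design(data, spec.fixed_effects)
    y = data[spec.outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"missing values in outcome {spec.outcome!r}")
    codes, groups = pd.factorize(data[spec.grouping], sort=True)
    if len(groups) < 2:
        raise ValueError("two-level model needs at least 2 groups")
    w = data["weight"].to_numpy(dtype=float) if spec.weighted else None
    return X, y, codes, len(groups), names, w


# ---------------------------------------------------------------------------
# Linear model: profiled REML for the random-intercept structure
# ---------------------------------------------------------------------------


def _reml_profile(psi, X, y, codes, n_groups, counts, weights):
    """GLS fit and REML criterion for a fixed variance ratio psi."""
    if weights is not None:
        sw = np.sqrt(weights)
        X = X * sw[:, None]
        y = y * sw
    lam = 1.0 - 1.0 / np.sqrt(1.0 + psi * counts)  # partial-centering factor
    Xbar = np.empty((n_groups, X.shape[1]))
    ybar = np.empty(n_groups)
    for col in range(X.shape[1]):
        Xbar[:, col] = np.bincount(codes, weights=X[:, col], minlength=n_groups) / counts
    ybar = np.bincount(codes, weights=y, minlength=n_groups) / counts
    Xt = X - (lam[codes])[:, None] * Xbar[codes]
    yt = y - lam[codes] * ybar[codes]
    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    n, p = X.shape
    sign, logdet = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular design matrix")
    log_rss = np.log(max(rss, 1e-300))
    criterion = np.log1p(psi * counts).sum() + logdet + (n - p) * log_rss
    return criterion, beta, rss, XtX


def fit_two_level_linear(df: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML random-intercept linear regression (see module docstring)."""
    X, y, codes, n_groups, names, w = _prepare(df, spec)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    n, p = X.shape

    def objective(log_psi):
        return _reml_profile(np.exp(log_psi), X, y, codes, n_groups, counts, w)[0]

    # boundary (psi = 0, i.e. no between-country variance) vs interior optimum
    crit0 = _reml_profile(0.0, X, y, codes, n_groups, counts, w)[0]
    res = optimize.minimize_scalar(objective, bounds=(-15.0, 12.0), method="bounded")
    if res.fun < crit0:
        psi = float(np.exp(res.x))
        converged = bool(res.success)
    else:
        psi, converged = 0.0, True
    _, beta, rss, XtX = _reml_profile(psi, X, y, codes, n_groups, counts, w)

    dof = max(n - p, 1)
    sigma2 = rss / dof
    if sigma2 < 1e-12:  # outcome fits exactly (e.g. identically zero)
        sigma2 = 0.0
        psi = 0.0
    se = np.sqrt(np.maximum(np.diag(sigma2 * np.linalg.inv(XtX)), 0.0))
    z = stats.norm.ppf(0.975)
    coefficients = {
        name: (float(b), float(b - z * s), float(b + z * s))
        for name, b, s in zip(names, beta, se)
    }
    return ModelFit(
        coefficients=coefficients,
        random_intercept_sd=float(np.sqrt(psi * sigma2)),
        n_obs=n,
        n_groups=n_groups,
        converged=converged,
        scale="beta",
        residual_sd=float(np.sqrt(sigma2)),
        _se=dict(zip(names, se)),
    )


# ---------------------------------------------------------------------------
# Logistic model: adaptive Gauss-Hermite maximum likelihood
# ---------------------------------------------------------------------------

_GH_NODES = 13  # adaptive (mode-centred) rule: ample for cluster sizes >= 100
_LOG_SIGMA_BOUNDS = (-7.0, 3.0)


class _AGHProblem:
    """Marginal log-likelihood and gradient by adaptive Gauss-Hermite.

    Rows must be sorted by group.  The conditional modes found for one
    parameter value warm-start the next evaluation, so the Newton mode
    search typically needs only a few steps per call.  The quadrature rule
    (mode-centred, curvature-scaled nodes) is applied to both the
    likelihood integrand and its parameter derivatives.
    """

    def __init__(self, X, y, codes, n_groups, gh_x, gh_logw, weights):
        self.X, self.y, self.codes, self.n_groups = X, y, codes, n_groups
        self.gh_x, self.gh_logw = gh_x, gh_logw
        self.weights = weights
        self.starts = np.searchsorted(codes, np.arange(n_groups))
        self.u = np.zeros(n_groups)

    def _group_sum(self, values):
        return np.add.reduceat(values, self.starts, axis=0)

    def __call__(self, params):
        X, y, codes = self.X, self.y, self.codes
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        eta0 = X @ beta
        wobs = self.weights if self.weights is not None else None

        u = self.u  # warm start from the previous evaluation
        for _ in range(100):
            p = special.expit(eta0 + u[codes])
            resid = (y - p) if wobs is None else wobs * (y - p)
            curv = p * (1 - p) if wobs is None else wobs * p * (1 - p)
            score = self._group_sum(resid) - u / sigma**2
            info = self._group_sum(curv) + 1.0 / sigma**2
            step = score / info
            np.clip(step, -4.0, 4.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        tau = 1.0 / np.sqrt(info)

        # nodes u_{jk} = u_j + sqrt(2) tau_j x_k
        nodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * self.gh_x[None, :]  # (J, K)
        eta = eta0[:, None] + nodes[codes]  # (n, K)
        ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
        if wobs is not None:
            ll_obs = wobs[:, None] * ll_obs
        ll_group = self._group_sum(ll_obs)
        h = ll_group - nodes**2 / (2 * sigma**2) - log_sigma - 0.5 * np.log(2 * np.pi)
        a = self.gh_logw[None, :] + self.gh_x[None, :] ** 2 + h
        log_I = np.log(np.sqrt(2.0) * tau) + special.logsumexp(a, axis=1)
        loglik = float(log_I.sum())

        # gradient: posterior-weighted expectations over the same nodes
        W = np.exp(a - special.logsumexp(a, axis=1, keepdims=True))  # (J, K)
        resid = y[:, None] - special.expit(eta)  # (n, K)
        if wobs is not None:
            resid = resid * wobs[:, None]
        s = (resid * W[codes]).sum(axis=1)
        grad_beta = X.T @ s
        grad_log_sigma = float((W * (nodes**2 / sigma**2 - 1.0)).sum())
        return -loglik, -np.concatenate([grad_beta, [grad_log_sigma]])


def fit_two_level_logistic(df: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Random-intercept logistic regression by adaptive Gauss-Hermite ML.

    Fixed effects are reported as odds ratios with Wald 95% CIs computed on
    the log-odds scale when ``spec.scale == "odds_ratio"``.
    """
    X, y, codes, n_groups, names, w = _prepare(df, spec)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} is not binary")

    gh_x, gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
    gh_logw = np.log(gh_w)

    # single-level logistic start values
    import statsmodels.api as sm

    with np.errstate(all="ignore"):
        try:
            start = sm.Logit(y, X).fit(disp=0, maxiter=200).params
        except Exception:
            start = np.zeros(X.shape[1])
    x0 = np.concatenate([start, [np.log(0.3)]])

    problem = _AGHProblem(X, y, codes, n_groups, gh_x, gh_logw, w)
    bounds = [(None, None)] * X.shape[1] + [_LOG_SIGMA_BOUNDS]
    res = optimize.minimize(
        problem,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta, log_sigma = res.x[:-1], res.x[-1]

    diverged = np.abs(beta) > 15.0
    if diverged.any():
        term = names[int(np.argmax(np.abs(beta)))]
        raise SeparationError(f"estimate for {term!r} diverges; data are separated")

    # observed information via central differences of the analytic gradient
    k = len(res.x)
    hess = np.empty((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(res.x))
    for i in range(k):
        left, right = res.x.copy(), res.x.copy()
        left[i] -= h[i]
        right[i] += h[i]
        gl = problem(left)[1]
        gr = problem(right)[1]
        hess[:, i] = (gr - gl) / (2 * h[i])
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov)[: X.shape[1]], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)

    z = stats.norm.ppf(0.975)
    coefficients = {}
    for name, b, s in zip(names, beta, se):
        lo, hi = b - z * s, b + z * s
        if spec.scale == "odds_ratio":
            coefficients[name] = (float(np.exp(b)), float(np.exp(lo)), float(np.exp(hi)))
        else:
            coefficients[name] = (float(b), float(lo), float(hi))
    return ModelFit(
        coefficients=coefficients,
        random_intercept_sd=float(np.exp(log_sigma)),
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        scale=spec.scale,
        loglik=float(-res.fun),
        _se=dict(zip(names, se)),
    )


def fit(df: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Dispatch on reporting scale: odds ratios -> logistic, betas -> linear."""
    if spec.scale == "odds_ratio":
        return fit_two_level_logistic(df, spec)
    return fit_two_level_linear(df, spec)
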