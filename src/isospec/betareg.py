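"""Maximum-likelihood beta regression for proportion responses.

The response y ∈ (0,1) follows a beta density parameterised by mean μ and
precision φ,

    f(y; μ, φ) = Γ(φ)/(Γ(μφ)Γ((1−μ)φ)) · y^(μφ−1) (1−y)^((1−μ)φ−1),

with logit(μ_i) = x_iᵀβ and a single constant φ (log link internally).
Estimation is by maximum likelihood (statsmodels' BetaModel, quasi-Newton
from a least-squares start); standard errors come from the inverse observed
information, and Wald z = β̂/SE with two-sided normal p-values.

The module keeps its own log-likelihood and analytic score so the fitted
optimum can be verified independently of the optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConvergenceError, DomainError, SchemaError


@dataclass(frozen=True)
class RegressionFit:
    """ML beta-regression fit: coefficients on the logit scale plus φ."""

    names: tuple[str, ...]
    coefficients: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    phi: float
    loglik: float
    n: int
    converged: bool

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names, "estimate": self.coefficients,
            "se": self.se, "z": self.z, "p": self.p,
        })


def compress_boundary(y, n: int | None = None) -> np.ndarray:
    """Boundary compression y' = (y·(n−1) + 0.5)/n mapping [0,1] into (0,1)."""
    y = np.asarray(y, dtype=float)
    n = y.size if n is None else int(n)
    if n < 2:
        raise DomainError("compression needs n ≥ 2")
    return (y * (n - 1) + 0.5) / n


def beta_log_likelihood(y: np.ndarray, X: np.ndarray, beta: np.ndarray, phi: float) -> float:
    """Model log-likelihood at (β, φ); independent of the fitting route."""
    eta = X @ beta
    mu = special.expit(eta)
    a, b = mu * phi, (1.0 - mu) * phi
    return float(np.sum(
        special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
        + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
    ))


def beta_score(y: np.ndarray, X: np.ndarray, beta: np.ndarray, phi: float) -> np.ndarray:
    """Analytic gradient of the log-likelihood in (β, φ)."""
    mu = special.expit(X @ beta)
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
    g_beta = X.T @ (phi * (ystar - mustar) * mu * (1.0 - mu))
    g_phi = np.sum(
        special.digamma(phi)
        - mu * special.digamma(mu * phi)
        - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
        + mu * np.log(y) + (1.0 - mu) * np.log1p(-y)
    )
    return np.concatenate([g_beta, [g_phi]])


def fit_beta_regression(
    y,
    X,
    names: tuple[str, ...] | list[str] | None = None,
    compress: bool = False,
) -> RegressionFit:
    """Fit logit-link, constant-φ beta regression by maximum likelihood.

    Parameters
    ----------
    y:
        Proportions strictly inside (0, 1); boundary values are a domain
        error unless ``compress=True`` applies y' = (y(n−1)+0.5)/n first.
    X:
        Design matrix including the intercept column; must be full rank.
    names:
        Term names matching X's columns (defaults to x0..xk).
    """
    from statsmodels.genmod.families.links import Log
    from statsmodels.othermod.betareg import BetaModel

    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise SchemaError("X must be a 2-D design matrix aligned with y")
    n, k = X.shape
    if n <= k + 1:
        raise DomainError(f"need more observations ({n}) than parameters ({k + 1})")
    if compress:
        y = compress_boundary(y, n)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise DomainError(
            "response on the [0,1] boundary; enable compress=True to apply "
            "the standard (y(n−1)+0.5)/n compression"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        names_ = tuple(names) if names else tuple(f"x{i}" for i in range(k))
        _, r = np.linalg.qr(X)
        dependent = [names_[i] for i in range(min(k, r.shape[0])) if abs(r[i, i]) < 1e-10]
        raise SchemaError(f"design matrix is rank deficient (rank {rank} < {k}); "
                          f"aliased columns: {dependent or 'see design'}")

    names = tuple(names) if names is not None else tuple(f"x{i}" for i in range(k))
    if len(names) != k:
        raise SchemaError("names must match the number of design columns")

    model = BetaModel(y, X, exog_precision=np.ones((n, 1)), link_precision=Log())
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # the Newton polish below supersedes the optimizer's own stopping
        # flag, so its ConvergenceWarning would be misleading
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=1000, disp=False)
        params, converged = _polish(y, X, np.asarray(res.params, dtype=float))
    beta = params[:k]
    phi = float(np.exp(params[k]))
    # SEs from the inverse observed information at the polished optimum
    hess = model.hessian(params)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))[:k]
    if not np.all(np.isfinite(se)):
        raise ConvergenceError("standard errors not finite; fit did not converge")
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return RegressionFit(
        names=names, coefficients=beta, se=se, z=z, p=p,
        phi=phi, loglik=beta_log_likelihood(y, X, beta, phi), n=n,
        converged=converged,
    )


def _polish(y: np.ndarray, X: np.ndarray, start: np.ndarray) -> tuple[np.ndarray, bool]:
    """Drive the score to ~0 with a tightly-converged quasi-Newton pass.

    Works in the (β, log φ) parameterization; uses the package's own
    analytic score so the reported optimum satisfies the first-order
    conditions to high precision.
    """
    k = X.shape[1]

    def negll(theta):
        return -beta_log_likelihood(y, X, theta[:k], np.exp(theta[k]))

    def grad(theta):
        phi = np.exp(theta[k])
        g = beta_score(y, X, theta[:k], phi)
        g[k] *= phi  # chain rule for the log-φ coordinate
        return -g

    theta = np.asarray(start, dtype=float)
    with np.errstate(all="ignore"):
        # damped Newton: optimizer line searches stall near the machine
        # precision of the objective, but the score remains informative
        for _ in range(25):
            g = grad(theta)
            gnorm = np.max(np.abs(g))
            if gnorm < 1e-9:
                break
            H = _fd_hessian(grad, theta)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            f0, lam, accepted = negll(theta), 1.0, False
            while lam > 1e-4:
                cand = theta - lam * step
                fc = negll(cand)
                if fc <= f0 or np.max(np.abs(grad(cand))) < gnorm:
                    theta, accepted = cand, True
                    break
                lam *= 0.5
            if not accepted:
                break
    converged = bool(np.max(np.abs(grad(theta))) < 1e-5)
    return theta, converged


def _fd_hessian(grad, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
    k = theta.size
    H = np.empty((k, k))
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        H[:, i] = (grad(tp) - grad(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def build_design_matrix(
    df: pd.DataFrame, formula: str
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Minimal formula parser: ``response ~ term + term + ...``.

    Numeric columns enter raw; string/categorical columns expand to dummy
    indicators with the first (sorted) level as the reference.  An intercept
    is always included.
    """
    if "~" not in formula:
        raise SchemaError("formula must contain '~'")
    lhs, rhs = (s.strip() for s in formula.split("~", 1))
    if lhs not in df.columns:
        raise SchemaError(f"response column {lhs!r} not in data")
    y = pd.to_numeric(df[lhs], errors="raise").to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["Intercept"]
    for term in (t.strip() for t in rhs.split("+")):
        if term in ("", "1"):
            continue
        if term not in df.columns:
            raise SchemaError(f"term {term!r} not a column of the data")
        col = df[term]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                cols.append((col.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{term}[{level}]")
    X = np.column_stack(cols)
    return y, X, tuple(names)


def fit_beta_formula(df: pd.DataFrame, formula: str, compress: bool = False) -> RegressionFit:
    """Formula front-end to :func:`fit_beta_regression`."""
    y, X, names = build_design_matrix(df, formula)
    return fit_beta_regression(y, X, names=names, compress=compress)
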