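"""Robust M-estimation: Huber IRLS linear regression and robust logistic
regression of the Mallows/Huber quasi-likelihood type.

Formulas used
-------------
Linear (Huber IRLS):
    psi_c(u) = u for |u| <= c, c*sign(u) otherwise.
    Scale is re-estimated each iteration as MAD(residuals)/0.6745.
    Wald covariance: K * s^2 * [sum psi^2 / (n - p)] / mean(psi')^2 * (X'X)^-1
    with the Huber small-sample correction K = 1 + p/n * var(psi')/mean(psi')^2.
    RAIC = 2 * sum rho_c(r_i / s) + 2 * (p + 1), rho_c the Huber loss.

Logistic (binomial quasi-likelihood with Huberized Pearson residuals):
    r_i = (y_i - mu_i) / sqrt(V_i), V = mu(1 - mu).
    Estimating equation: sum_i [psi_c(r_i) - E psi_c(r_i)] sqrt(V_i) x_i = 0,
    where the expectation (the Fisher-consistency correction) is taken over
    y in {0, 1} at mu_i.  Sandwich covariance A^-1 B A^-T with A the Jacobian
    of the estimating function and B = sum Var[psi_c(r_i)] V_i x_i x_i'.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from geno2lnc.datatypes import DataError, RobustFit

_MAD_CONST = 0.6744897501960817  # Phi^-1(0.75): MAD -> sigma for Gaussians


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a collinear column: the first whose removal restores full rank
        for j in range(X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise DataError(f"design is rank deficient; column {names[j]!r} is collinear")
        raise DataError("design is rank deficient")


def huber_rho(u: np.ndarray, c: float) -> np.ndarray:
    au = np.abs(u)
    return np.where(au <= c, 0.5 * u * u, c * au - 0.5 * c * c)


def huber_psi(u: np.ndarray, c: float) -> np.ndarray:
    return np.clip(u, -c, c)


def mad_scale(residuals: np.ndarray) -> float:
    """MAD-about-zero residual scale, rescaled for Gaussian consistency."""
    return float(np.median(np.abs(residuals)) / _MAD_CONST)


def huber_rlm(
    y,
    X,
    huber_c: float = 1.345,
    max_iter: int = 200,
    tol: float = 1e-10,
    description: str = "",
) -> RobustFit:
    """Huber M-estimation by IRLS with concurrent MAD residual scale."""
    y = np.asarray(y, dtype=float)
    Xa, names = _as_design(X)
    n, p = Xa.shape
    if n <= p:
        raise DataError(f"need n > p (n={n}, p={p})")
    _check_rank(Xa, names)
    if huber_c <= 0:
        raise DataError("huber_c must be positive")

    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    converged = False
    scale = mad_scale(y - Xa @ beta)
    for _ in range(max_iter):
        resid = y - Xa @ beta
        scale = mad_scale(resid)
        if scale <= np.finfo(float).eps * max(1.0, np.abs(y).max()):
            # (near-)exact fit: IRLS has nothing left to reweight
            converged = True
            scale = max(scale, np.finfo(float).tiny)
            break
        u = resid / scale
        with np.errstate(divide="ignore"):
            w = np.where(np.abs(u) <= huber_c, 1.0, huber_c / np.abs(u))
        wX = Xa * w[:, None]
        beta_new = np.linalg.solve(wX.T @ Xa, wX.T @ y)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol * max(1.0, np.max(np.abs(beta))):
            converged = True
            break

    resid = y - Xa @ beta
    u = resid / scale
    psi = huber_psi(u, huber_c)
    psi_prime = (np.abs(u) <= huber_c).astype(float)
    m1 = psi_prime.mean()
    if m1 <= 0:
        raise DataError("all residuals outside the Huber band; fit degenerate")
    kappa = float((psi**2).sum()) / (n - p)
    correction = 1.0 + p / n * float(psi_prime.var()) / m1**2
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    cov = correction * scale**2 * kappa / m1**2 * xtx_inv
    bse = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bse > 0, beta / bse, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    raic = 2.0 * float(huber_rho(u, huber_c).sum()) + 2.0 * (p + 1)

    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float((resid**2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else np.nan

    idx = pd.Index(names)
    return RobustFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(bse, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        scale=scale,
        huber_c=huber_c,
        raic=raic,
        r2=r2,
        r2_adj=r2_adj,
        n=n,
        converged=converged,
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        description=description,
    )


def raic(fit: RobustFit) -> float:
    """Robust AIC of a converged Huber fit (lower is better)."""
    if not fit.converged:
        raise DataError("RAIC requires a converged fit")
    return fit.raic


def raic_at_scale(y, X, fit: RobustFit, scale: float) -> float:
    """RAIC of ``fit`` with the Huber loss evaluated at a common ``scale``.

    When comparing models of the same response, each fit's own MAD scale
    standardizes away the goodness of fit (sum rho(r/s_hat) is nearly
    constant), so subset selection must score all candidates against one
    shared residual scale.
    """
    if scale <= 0:
        raise DataError("common scale must be positive")
    y = np.asarray(y, dtype=float)
    Xa, _ = _as_design(X)
    resid = y - Xa @ fit.params.to_numpy()
    p = len(fit.params)
    return 2.0 * float(huber_rho(resid / scale, fit.huber_c).sum()) + 2.0 * (p + 1)


def wald_joint_test(fit: RobustFit, terms: list[str]) -> float:
    """Joint Wald chi-square p-value for a set of coefficients."""
    b = fit.params[terms].to_numpy()
    v = fit.cov.loc[terms, terms].to_numpy()
    stat = float(b @ np.linalg.solve(v, b))
    return float(stats.chi2.sf(stat, df=len(terms)))


# ---------------------------------------------------------------------------
# Robust logistic regression
# ---------------------------------------------------------------------------

def _ml_logistic(y: np.ndarray, X: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Plain Newton/IRLS maximum-likelihood logistic fit (starting values)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        g = X.T @ (y - mu)
        h = (X * w[:, None]).T @ X + 1e-10 * np.eye(X.shape[1])
        step = np.linalg.solve(h, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def robust_logistic(
    y,
    X,
    huber_c: float = 1.2,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> tuple[pd.Series, pd.Series, pd.Series, pd.DataFrame, bool]:
    """Robust quasi-likelihood logistic regression with Huberized residuals.

    Returns (coefficients, sandwich SEs, p-values, covariance, converged).
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("response must be binary 0/1")
    if y.min() == y.max():
        raise DataError("both classes must be present")
    Xa, names = _as_design(X)
    _check_rank(Xa, names)
    n, p = Xa.shape
    c = float(huber_c)

    def estfun(beta: np.ndarray) -> np.ndarray:
        eta = np.clip(Xa @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        sv = np.sqrt(mu * (1.0 - mu))
        r = (y - mu) / sv
        psi = np.clip(r, -c, c)
        r1 = (1.0 - mu) / sv
        r0 = -mu / sv
        e_psi = np.clip(r1, -c, c) * mu + np.clip(r0, -c, c) * (1.0 - mu)
        return Xa.T @ ((psi - e_psi) * sv)

    start = _ml_logistic(y, Xa)
    sol = optimize.root(estfun, start, method="hybr", tol=tol)
    beta = sol.x
    converged = bool(sol.success)

    eta = Xa @ beta
    if np.max(np.abs(eta)) > 30:
        worst = names[int(np.argmax(np.abs(beta)))]
        raise DataError(
            f"separation detected (diverging coefficients); check covariate {worst!r}"
        )

    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    v = mu * (1.0 - mu)
    sv = np.sqrt(v)
    r1 = (1.0 - mu) / sv
    r0 = -mu / sv
    psi1 = np.clip(r1, -c, c)
    psi0 = np.clip(r0, -c, c)
    e_psi = psi1 * mu + psi0 * (1.0 - mu)
    e_psi2 = psi1**2 * mu + psi0**2 * (1.0 - mu)
    var_psi = np.maximum(e_psi2 - e_psi**2, 0.0)

    B = (Xa * (var_psi * v)[:, None]).T @ Xa
    A = optimize.approx_fprime(beta, estfun, 1e-6 * np.maximum(np.abs(beta), 1.0))
    A = np.atleast_2d(A)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv.T
    bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bse > 0, beta / bse, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    idx = pd.Index(names)
    return (
        pd.Series(beta, index=idx),
        pd.Series(bse, index=idx),
        pd.Series(pvals, index=idx),
        pd.DataFrame(cov, index=idx, columns=idx),
        converged,
    )
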