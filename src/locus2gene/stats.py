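"""Closed-form regression primitives shared across modules.

Everything here is a thin, vectorized wrapper around the textbook simple /
multiple linear regression formulas; the heavy per-pair loops in eQTL mapping
and GWAS simulation reduce to matrix products on centered data.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def linear_assoc(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simple linear regression of ``y`` on each column of ``X`` separately.

    Returns (beta, se, p) arrays of length n_columns; columns with zero
    variance get beta = 0, se = inf, p = 1.  Two-sided t test with n - 2 df.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = y.shape[0]
    if n <= 3:
        raise ValueError("need more than 3 observations")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    ok = sxx > 0
    beta = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.inf)
    beta[ok] = sxy[ok] / sxx[ok]
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se[ok] = np.sqrt(sigma2[ok] / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.ones(X.shape[1])
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df=n - 2)
    # exact fit: rss == 0 with nonzero slope -> p underflows to 0; floor it
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    return beta, se, p


def simple_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, SE and two-sided p of ``y ~ 1 + x``."""
    beta, se, p = linear_assoc(np.asarray(x, float)[:, None], y)
    return float(beta[0]), float(se[0]), float(p[0])


def ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of ``y`` on ``X`` plus an intercept.

    Returns (coef, se, p, df) for the non-intercept columns.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough degrees of freedom")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    p = np.clip(2.0 * sps.t.sf(np.abs(t), df=df), np.finfo(float).tiny, 1.0)
    return coef[1:], se[1:], p[1:], df


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        return np.nan
    return float(xc @ yc) / denom


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors (LD r^2)."""
    r = pearson_r(x, y)
    return float(r * r) if np.isfinite(r) else np.nan


def residualize_matrix(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``values`` on [1, covariates]."""
    n = values.shape[0]
    design = np.column_stack([np.ones(n), np.asarray(covariates, float).reshape(n, -1)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef
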