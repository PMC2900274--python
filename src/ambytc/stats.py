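"""Shared statistical primitives: a vectorised OLS engine and BH FDR.

Per-gene regression screens fit the *same* design matrix to thousands of
response vectors, so the solver works on a response matrix in one shot
(normal equations via pinv, t/F tails from scipy).  Single-response
convenience wrappers are thin views over the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

# Residual mean squares below this are treated as an exact (noiseless) fit;
# coefficient inference then degenerates to |coef| > _COEF_TOL.
_NOISELESS_MSE = 1e-20
_COEF_TOL = 1e-8


@dataclass
class OLSResult:
    """Vectorised OLS output for ``g`` response vectors on a shared design.

    All arrays are indexed ``(n_params, g)`` or ``(g,)``.  The overall test
    is the F-test of all non-intercept terms against the intercept-only
    null.  Degenerate responses (zero variance) get ``p_overall = 1`` and
    ``r2 = 0``; exact fits get zero p-values on non-zero coefficients.
    """

    coef: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    p_coef: np.ndarray
    p_overall: np.ndarray
    r2: np.ndarray
    df_resid: int
    mse: np.ndarray
    degenerate: np.ndarray = field(default=None)  # zero-variance responses


def ols(X: np.ndarray, Y: np.ndarray) -> OLSResult:
    """Fit ``Y ~ X`` by ordinary least squares, one fit per column of ``Y``.

    ``X`` is ``(n, p)`` with an intercept in column 0; ``Y`` is ``(n,)`` or
    ``(n, g)``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y have incompatible shapes")
    df = n - p
    if df < 1:
        raise ValueError(f"residual df = {df} < 1 (n={n}, p={p})")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in design or response")

    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("singular (collinear) design matrix")
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ Y)  # (p, g)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    mse = rss / df
    tss = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))

    degenerate = tss <= _NOISELESS_MSE * n
    noiseless = (mse <= _NOISELESS_MSE) & ~degenerate

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(XtX_inv), mse))
        tstat = coef / se
        p_coef = 2.0 * sps.t.sf(np.abs(tstat), df)
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        fstat = ((tss - rss) / (p - 1)) / mse
        p_overall = sps.f.sf(fstat, p - 1, df)

    if noiseless.any():
        big = np.abs(coef[:, noiseless]) > _COEF_TOL
        p_coef[:, noiseless] = np.where(big, 0.0, 1.0)
        tstat[:, noiseless] = np.where(big, np.inf, 0.0)
        p_overall[noiseless] = 0.0
        r2[noiseless] = 1.0
    if degenerate.any():
        p_coef[:, degenerate] = 1.0
        p_coef[0, degenerate] = 0.0  # intercept is still estimated
        tstat[:, degenerate] = 0.0
        p_overall[degenerate] = 1.0
        r2[degenerate] = 0.0

    np.clip(r2, 0.0, 1.0, out=r2)
    if squeeze:
        return OLSResult(coef[:, 0], se[:, 0], tstat[:, 0], p_coef[:, 0],
                         float(p_overall[0]), float(r2[0]), df, float(mse[0]),
                         bool(degenerate[0]))
    return OLSResult(coef, se, tstat, p_coef, p_overall, r2, df, mse, degenerate)


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)`` aligned with the input order.  Rejects
    every ``p_(i)`` with ``i <= max{k : p_(k) <= k*q/m}``; adjusted p-values
    are the usual monotone ``min_{j>=i} m*p_(j)/j`` capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= thresholds)[0]
    reject = np.zeros(m, bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    adj_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj_sorted, 1.0)
    return reject, p_adj
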