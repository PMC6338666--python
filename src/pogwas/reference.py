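"""Brute-force dense-matrix mixed-model reference implementations.

These build the full covariance V = lambda*A + I explicitly and evaluate the
(restricted) likelihood and GLS estimates by dense inversion.  They are O(n^3)
per evaluation and exist as an independent validation route for the rotated
kernel in :mod:`pogwas.lmm`; they share no code with it.
"""

from __future__ import annotations

import numpy as np


def dense_loglik(lam: float, y: np.ndarray, Z: np.ndarray, A: np.ndarray, reml: bool):
    """Profile (restricted) log-likelihood at lambda via explicit V = lam*A + I.

    Returns (loglik, theta_hat, sigma_e2_hat).  The REML criterion includes the
    +0.5*log|Z'Z| term, matching the kernel's convention.
    """
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    A = np.asarray(A, float)
    n, c = Z.shape
    V = lam * A + np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVX = Z.T @ Vinv @ Z
    theta = np.linalg.solve(XtVX, Z.T @ Vinv @ y)
    resid = y - Z @ theta
    rss = float(resid @ Vinv @ resid)
    sign, logdet_V = np.linalg.slogdet(V)
    if reml:
        df = n - c
        sigma_e2 = rss / df
        _, logdet_XtVX = np.linalg.slogdet(XtVX)
        _, logdet_ZtZ = np.linalg.slogdet(Z.T @ Z)
        ll = -0.5 * (
            df * np.log(2.0 * np.pi * sigma_e2)
            + df
            + logdet_V
            + logdet_XtVX
            - logdet_ZtZ
        )
    else:
        sigma_e2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma_e2) + n + logdet_V)
    return float(ll), theta, sigma_e2


def dense_gls(y: np.ndarray, Z: np.ndarray, A: np.ndarray, lam: float):
    """GLS estimates and standard errors via explicit V^{-1}.

    Returns (theta_hat, se, sigma_e2_hat) with sigma_e2_hat = RSS_V / (n - c).
    """
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    n, c = Z.shape
    V = lam * np.asarray(A, float) + np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVX_inv = np.linalg.inv(Z.T @ Vinv @ Z)
    theta = XtVX_inv @ (Z.T @ Vinv @ y)
    resid = y - Z @ theta
    sigma_e2 = float(resid @ Vinv @ resid) / (n - c)
    se = np.sqrt(np.diag(sigma_e2 * XtVX_inv))
    return theta, se, sigma_e2


def grid_argmax_lambda(
    y: np.ndarray,
    Z: np.ndarray,
    A: np.ndarray,
    reml: bool = True,
    n_grid: int = 10_000,
    lo: float = 1e-5,
    hi: float = 1e5,
) -> float:
    """Dense-likelihood argmax of lambda over a fine log-spaced grid."""
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    vals = [dense_loglik(lam, y, Z, A, reml)[0] for lam in grid]
    return float(grid[int(np.argmax(vals))])
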