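"""Single-random-effect linear mixed model kernel.

The model is y = Z theta + g + e with g ~ N(0, A*sigma_g^2) and
e ~ N(0, I*sigma_e^2).  Writing lambda = sigma_g^2 / sigma_e^2 and
eigendecomposing the relatedness matrix A = U diag(s) U^T, the rotated model
U^T y = U^T Z theta + eps has independent errors with variances
sigma_e^2 * (lambda * s_i + 1), so for any lambda the fixed effects are a
weighted least-squares fit and sigma_e^2 profiles out in closed form.  The
one-dimensional profile (restricted) likelihood in lambda is maximised by a
log-spaced grid search followed by bounded refinement.

The restricted likelihood includes the +0.5*log|Z^T Z| constant, which makes
REML invariant to linear reparameterisations of the fixed-effect design —
in particular, the joint maternal+paternal parameterisation and its
difference/mean reparameterisation have identical restricted likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "RelatednessMatrix",
    "EigenRotation",
    "VarianceComponents",
    "FixedEffectFit",
    "compute_genotype_grm",
    "fit_variance_components",
    "gls_fit",
    "profile_log_likelihood",
    "wald_test",
]

_LAMBDA_LO = 1e-5
_LAMBDA_HI = 1e5
_WEIGHT_FLOOR = 1e-10


@dataclass
class RelatednessMatrix:
    """Symmetric PSD n x n additive relatedness (A) with sample ordering."""

    matrix: np.ndarray
    sample_ids: list[str]
    source: str = "pedigree"  # {"pedigree", "genotype"}

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("relatedness matrix must be square")
        if A.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix size")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("relatedness matrix is not symmetric (tol 1e-10)")
        A = 0.5 * (A + A.T)
        if A.shape[0] > 0:
            w = np.linalg.eigvalsh(A)
            if w.min() < -1e-8:
                raise ValueError(
                    f"relatedness matrix is not PSD (min eigenvalue {w.min():.3g})"
                )
            if self.source == "pedigree" and np.any(np.diag(A) < 1.0 - 1e-8):
                raise ValueError("pedigree relatedness diagonal must be >= 1")
        self.matrix = A

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def subset(self, indices) -> "RelatednessMatrix":
        idx = np.asarray(indices)
        return RelatednessMatrix(
            matrix=self.matrix[np.ix_(idx, idx)],
            sample_ids=[self.sample_ids[i] for i in idx],
            source=self.source,
        )


@dataclass
class EigenRotation:
    """Eigendecomposition A = U diag(s) U^T with eigenvalues clipped at 0."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @classmethod
    def from_relatedness(cls, A) -> "EigenRotation":
        mat = A.matrix if isinstance(A, RelatednessMatrix) else np.asarray(A, float)
        s, U = np.linalg.eigh(mat)
        return cls(eigenvalues=np.clip(s, 0.0, None), eigenvectors=U)

    def rotate(self, x: np.ndarray) -> np.ndarray:
        return self.eigenvectors.T @ x

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass
class VarianceComponents:
    lam: float  # sigma_g^2 / sigma_e^2
    sigma_g2: float
    sigma_e2: float
    log_likelihood: float
    method: str  # "REML" or "ML"
    at_boundary: bool = False


@dataclass
class FixedEffectFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    df: int
    p_values: np.ndarray
    sigma_e2: float
    column_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# relatedness from genotypes


def compute_genotype_grm(G) -> RelatednessMatrix:
    """Centered genotype relationship matrix A = C C^T / m, with C columns
    x_pm - 2*p_hat; missing genotypes are mean-imputed for this computation
    only.  An alternative A when no pedigree is available."""
    xpm = G.xpm()  # (m, n)
    called = ~np.isnan(xpm)
    n_called = called.sum(axis=1)
    if G.n_variants < 2:
        raise ValueError("need at least 2 variants to compute a genotype GRM")
    with np.errstate(invalid="ignore"):
        mean = np.nansum(xpm, axis=1) / np.maximum(n_called, 1)
    poly = np.zeros(G.n_variants, dtype=bool)
    for j in range(G.n_variants):
        vals = xpm[j, called[j]]
        poly[j] = vals.size > 0 and np.ptp(vals) > 0
    if not poly.any():
        raise ValueError("all variants monomorphic; GRM undefined")
    C = np.where(called, xpm, mean[:, None]) - mean[:, None]
    C = C[poly]
    A = C.T @ C / C.shape[0]
    return RelatednessMatrix(matrix=A, sample_ids=list(G.samples), source="genotype")


# ---------------------------------------------------------------------------
# likelihood machinery (rotated space)


def _profile_loglik(
    lam: float,
    s: np.ndarray,
    yt: np.ndarray,
    Zt: np.ndarray,
    reml: bool,
    logdet_ZtZ: float,
):
    """Profile (restricted) log-likelihood at lambda, with theta and sigma_e^2
    profiled out.  Returns (loglik, theta, rss_weighted, XtWX)."""
    n, c = Zt.shape
    w = 1.0 / np.maximum(lam * s + 1.0, _WEIGHT_FLOOR)
    ZtW = Zt * w[:, None]
    XtWX = Zt.T @ ZtW
    XtWy = ZtW.T @ yt
    theta = np.linalg.solve(XtWX, XtWy)
    resid = yt - Zt @ theta
    rss = float(np.sum(w * resid * resid))
    logdet_V = float(np.sum(np.log(np.maximum(lam * s + 1.0, _WEIGHT_FLOOR))))
    if reml:
        df = n - c
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            df * np.log(2.0 * np.pi * rss / df)
            + df
            + logdet_V
            + logdet_XtWX
            - logdet_ZtZ
        )
    else:
        ll = -0.5 * (n * np.log(2.0 * np.pi * rss / n) + n + logdet_V)
    return ll, theta, rss, XtWX


def _check_design(Z: np.ndarray, column_names=None) -> None:
    n, c = Z.shape
    if n <= c:
        raise ValueError(f"need n > number of design columns ({n} <= {c})")
    rank = np.linalg.matrix_rank(Z)
    if rank < c:
        from scipy.linalg import qr

        names = column_names or [f"col{i}" for i in range(c)]
        # identify offending columns via pivoted QR
        _, R, piv = qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < diag[0] * 1e-10] or [
            names[p] for p in piv[rank:]
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {c}); "
            f"collinear columns: {sorted(set(bad))}"
        )


def fit_variance_components(
    y: np.ndarray,
    Z: np.ndarray,
    rot: EigenRotation,
    method: str = "REML",
    grid_points: int = 60,
    rel_tol: float = 1e-6,
    column_names=None,
) -> VarianceComponents:
    """Estimate lambda = sigma_g^2/sigma_e^2 by maximising the profile
    (restricted) likelihood of the eigen-rotated model.

    Optimisation: log-spaced grid over lambda in [1e-5, 1e5] followed by
    bounded scalar refinement in the best grid bracket to relative tolerance
    ``rel_tol``.  sigma_e^2 is profiled in closed form.  An optimum at the grid
    boundary is returned with ``at_boundary=True``.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    if np.isnan(y).any() or np.isnan(Z).any():
        raise ValueError("y and Z must not contain missing values; subset first")
    _check_design(Z, column_names)
    reml = method == "REML"
    yt = rot.rotate(y)
    Zt = rot.rotate(Z)
    return _fit_rotated(yt, Zt, rot.eigenvalues, reml, grid_points, rel_tol, method)


def _fit_rotated(yt, Zt, s, reml, grid_points, rel_tol, method) -> VarianceComponents:
    n, c = Zt.shape
    sign, logdet_ZtZ = np.linalg.slogdet(Zt.T @ Zt)

    def nll(loglam: float) -> float:
        return -_profile_loglik(float(np.exp(loglam)), s, yt, Zt, reml, logdet_ZtZ)[0]

    grid = np.log(np.logspace(np.log10(_LAMBDA_LO), np.log10(_LAMBDA_HI), grid_points))
    vals = np.array([nll(g) for g in grid])
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": rel_tol}
    )
    loglam = float(res.x) if res.fun <= vals[best] else float(grid[best])
    lam = float(np.exp(loglam))
    at_boundary = best in (0, len(grid) - 1)
    if at_boundary:
        log.warning("lambda optimum at grid boundary (lambda=%.3g)", lam)
    ll, theta, rss, _ = _profile_loglik(lam, s, yt, Zt, reml, logdet_ZtZ)
    denom = (n - c) if reml else n
    sigma_e2 = rss / denom
    return VarianceComponents(
        lam=lam,
        sigma_g2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        log_likelihood=float(ll),
        method=method,
        at_boundary=at_boundary,
    )


def gls_fit(
    y: np.ndarray,
    Z: np.ndarray,
    rot: EigenRotation,
    lam: float,
    column_names=None,
) -> FixedEffectFit:
    """Generalised least squares at fixed lambda.

    theta_hat = (Z'WZ)^-1 Z'Wy in the rotated space with W = diag(1/(lam*s+1));
    standard errors from sigma_e^2_hat * (Z'WZ)^-1 with
    sigma_e^2_hat = RSS_w / (n - c); Wald p-values from the t distribution on
    n - c degrees of freedom.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    if np.isnan(y).any() or np.isnan(Z).any():
        raise ValueError("y and Z must not contain missing values; subset first")
    _check_design(Z, column_names)
    yt = rot.rotate(y)
    Zt = rot.rotate(Z)
    return _gls_rotated(yt, Zt, rot.eigenvalues, lam, column_names)


def _gls_rotated(yt, Zt, s, lam, column_names=None) -> FixedEffectFit:
    n, c = Zt.shape
    w = 1.0 / np.maximum(lam * s + 1.0, _WEIGHT_FLOOR)
    ZtW = Zt * w[:, None]
    XtWX = Zt.T @ ZtW
    try:
        XtWX_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular normal equations: {exc}") from exc
    theta = XtWX_inv @ (ZtW.T @ yt)
    resid = yt - Zt @ theta
    rss = float(np.sum(w * resid * resid))
    df = n - c
    sigma_e2 = rss / df
    cov = sigma_e2 * XtWX_inv
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, theta / se, np.inf)
    p = np.array([wald_test(b, e, df) if e > 0 else np.nan for b, e in zip(theta, se)])
    return FixedEffectFit(
        coefficients=theta,
        standard_errors=se,
        covariance=cov,
        df=df,
        p_values=p,
        sigma_e2=sigma_e2,
        column_names=list(column_names) if column_names else [f"col{i}" for i in range(c)],
    )


def profile_log_likelihood(
    y: np.ndarray, Z: np.ndarray, rot: EigenRotation, lam: float, method: str = "REML"
) -> float:
    """Profile (restricted) log-likelihood at a fixed lambda, with theta and
    sigma_e^2 profiled out.  Useful for likelihood-ratio tests and for checking
    that reparameterisations of the design leave the criterion unchanged."""
    if method not in ("REML", "ML"):
        raise ValueError(f"unknown method {method!r}")
    yt = rot.rotate(np.asarray(y, float))
    Zt = rot.rotate(np.asarray(Z, float))
    _, logdet_ZtZ = np.linalg.slogdet(Zt.T @ Zt)
    ll, *_ = _profile_loglik(lam, rot.eigenvalues, yt, Zt, method == "REML", logdet_ZtZ)
    return float(ll)


def wald_test(coef: float, se: float, df: int) -> float:
    """Two-sided Wald p-value from the t distribution on df degrees of freedom."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    if df < 1:
        raise ValueError("need at least 1 residual degree of freedom")
    t = coef / se
    return float(min(1.0, 2.0 * stats.t.sf(abs(t), df)))
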