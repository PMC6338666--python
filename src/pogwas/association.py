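"""The four per-variant association models and parent-of-origin classification.

For each variant, with y the trait, W covariates (intercept included), g the
polygenic random effect with covariance A*sigma_g^2, and e ~ N(0, I*sigma_e^2):

* standard:     y = W a + X_PM * b_PM + g + e          (alleles pooled)
* maternal:     y = W a + X_M * b_M + g + e            (maternal allele only)
* paternal:     y = W a + X_P * b_P + g + e
* differential: y = W a + d * (b_M - b_P) + X_PM * (b_M + b_P)/2 + g + e
                 with d = (X_M - X_P)/2

The differential model is an exact reparameterisation of the joint model
y = W a + X_M b_M + X_P b_P + g + e: the coefficient on d is b_M - b_P, the
quantity of interest for parent-of-origin effects that are different or
opposite in direction — effects that cancel in the pooled X_PM regressor and
are therefore invisible to a standard GWAS.

A variant is classified as having a single-parent effect when exactly one
parental test reaches genome-wide significance while the standard GWAS does
not; a differential effect is called from the d-coefficient's p-value and may
co-occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotypes import PhasedGenotypeMatrix, Variant, derive_design_vectors
from .lmm import (
    EigenRotation,
    RelatednessMatrix,
    _fit_rotated,
    _gls_rotated,
)
from .phenotype import PhenotypeFrame

log = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8

MODELS = ("standard", "maternal", "paternal", "differential")

__all__ = [
    "AssociationResult",
    "PoeCall",
    "run_standard_gwas",
    "run_parental_gwas",
    "run_differential_gwas",
    "run_differential_lrt",
    "run_all_models",
    "classify_poe",
    "significance_filter",
    "top_hits",
    "GENOME_WIDE_ALPHA",
]


@dataclass
class AssociationResult:
    """One variant under one model; ``beta`` is b_PM, b_M, b_P, or b_M - b_P."""

    variant: Variant
    model: str
    n_analyzed: int
    maf: float
    beta: float
    se: float
    p: float
    mean_effect: Optional[float] = None  # (b_M + b_P)/2, differential model only
    lam: Optional[float] = None
    log_likelihood: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class PoeCall:
    variant: Variant
    classification: str  # {"maternal_only", "paternal_only", "differential", "none"}
    differential: bool
    p_values: dict


# ---------------------------------------------------------------------------
# sample reconciliation and per-mask caching


class _ScanContext:
    """Reconciled y/W/A/genotypes plus a cache of per-missingness-pattern
    eigendecompositions and rotated designs.

    ``eigen_cache`` may be shared across scans that use the same relatedness
    matrix and sample reconciliation (e.g. the four models of one study, or
    repeated scans on one pedigree); it holds only (eigenvalues, eigenvectors)
    per missingness pattern, never trait-dependent quantities.
    """

    def __init__(
        self,
        G: PhasedGenotypeMatrix,
        pheno: PhenotypeFrame,
        A: RelatednessMatrix,
        eigen_cache: Optional[dict] = None,
    ):
        common = [
            s
            for s in pheno.sample_ids
            if s in set(G.samples) and s in set(A.sample_ids)
        ]
        if not common:
            raise ValueError("no samples shared between genotypes, phenotype and A")
        p_idx = {s: i for i, s in enumerate(pheno.sample_ids)}
        g_idx = {s: i for i, s in enumerate(G.samples)}
        a_idx = {s: i for i, s in enumerate(A.sample_ids)}
        self.samples = common
        self.y = pheno.y[[p_idx[s] for s in common]]
        self.W = pheno.W[[p_idx[s] for s in common], :]
        self.cov_names = list(pheno.covariate_names)
        self.G = G
        self.g_cols = np.array([g_idx[s] for s in common])
        self.A = A.matrix[np.ix_([a_idx[s] for s in common], [a_idx[s] for s in common])]
        self._eigen = eigen_cache if eigen_cache is not None else {}
        self._rotated: dict[bytes, tuple] = {}

    def rotated(self, mask: np.ndarray):
        """(s, U, yt, Wt) for the complete-case submatrix selected by mask."""
        key = np.packbits(mask).tobytes()
        hit = self._rotated.get(key)
        if hit is None:
            eig = self._eigen.get(key)
            if eig is None:
                sub = self.A[np.ix_(mask, mask)]
                s, U = np.linalg.eigh(sub)
                eig = (np.clip(s, 0.0, None), U)
                self._eigen[key] = eig
            s, U = eig
            yt = U.T @ self.y[mask]
            Wt = U.T @ self.W[mask, :]
            hit = (s, U, yt, Wt)
            self._rotated[key] = hit
        return hit


def _scan(
    G: PhasedGenotypeMatrix,
    pheno: PhenotypeFrame,
    A: RelatednessMatrix,
    model: str,
    lambda_strategy: str = "per-variant",
    min_n: int = 10,
    reml: bool = True,
    eigen_cache: Optional[dict] = None,
) -> list[AssociationResult]:
    if lambda_strategy not in ("per-variant", "once"):
        raise ValueError(f"unknown lambda strategy {lambda_strategy!r}")
    ctx = _ScanContext(G, pheno, A, eigen_cache=eigen_cache)
    once_cache: dict[bytes, float] = {}
    results: list[AssociationResult] = []
    for j, variant in enumerate(G.variants):
        res = _fit_variant(ctx, j, model, lambda_strategy, min_n, reml, once_cache)
        if res is not None:
            results.append(res)
    return results


def _fit_variant(
    ctx: _ScanContext,
    j: int,
    model: str,
    lambda_strategy: str,
    min_n: int,
    reml: bool,
    once_cache: dict,
) -> Optional[AssociationResult]:
    variant = ctx.G.variants[j]
    dv = derive_design_vectors(ctx.G, j)
    mask = dv.mask[ctx.g_cols]
    n_an = int(mask.sum())
    if n_an < min_n:
        log.debug("skipping %s under %s: only %d analyzed samples", variant.id, model, n_an)
        return None

    xm = ctx.G.maternal[j, ctx.g_cols][mask]
    xp = ctx.G.paternal[j, ctx.g_cols][mask]
    xpm = xm + xp
    d = (xm - xp) / 2.0
    af = xpm.mean() / 2.0
    maf = float(min(af, 1.0 - af))

    if model == "standard":
        cols, names, test = [xpm], ["x_pm"], "x_pm"
    elif model == "maternal":
        cols, names, test = [xm], ["x_m"], "x_m"
    elif model == "paternal":
        cols, names, test = [xp], ["x_p"], "x_p"
    elif model == "differential":
        if np.ptp(d) == 0:
            log.debug("skipping %s: no informative transmissions", variant.id)
            return None
        cols, names, test = [d], ["d"], "d"
        if np.ptp(xpm) > 0:  # constant x_pm is absorbed by the intercept
            cols.append(xpm)
            names.append("x_pm")
        else:
            log.debug("%s: x_pm constant on analyzed subset; dropped as covariate", variant.id)
    else:
        raise ValueError(f"unknown model {model!r}")

    if np.ptp(cols[0]) == 0:
        log.debug("skipping %s under %s: tested regressor is constant", variant.id, model)
        return None

    s, U, yt, Wt = ctx.rotated(mask)
    Zt = np.column_stack([Wt] + [U.T @ c for c in cols])
    all_names = ctx.cov_names + names
    n, c = Zt.shape
    if n <= c or np.linalg.matrix_rank(Zt) < c:
        log.debug("skipping %s under %s: rank-deficient design", variant.id, model)
        return None

    if lambda_strategy == "per-variant":
        vc = _fit_rotated(yt, Zt, s, reml, grid_points=60, rel_tol=1e-6,
                          method="REML" if reml else "ML")
    else:
        key = np.packbits(mask).tobytes()
        if key not in once_cache:
            vc0 = _fit_rotated(yt, Wt, s, reml, grid_points=60, rel_tol=1e-6,
                               method="REML" if reml else "ML")
            once_cache[key] = vc0.lam
        vc = None
    lam = vc.lam if vc is not None else once_cache[np.packbits(mask).tobytes()]

    fit = _gls_rotated(yt, Zt, s, lam, all_names)
    k = all_names.index(test)
    mean_effect = None
    if model == "differential" and "x_pm" in names:
        mean_effect = float(fit.coefficients[all_names.index("x_pm")])
    return AssociationResult(
        variant=variant,
        model=model,
        n_analyzed=n_an,
        maf=maf,
        beta=float(fit.coefficients[k]),
        se=float(fit.standard_errors[k]),
        p=float(fit.p_values[k]),
        mean_effect=mean_effect,
        lam=float(lam),
        log_likelihood=vc.log_likelihood if vc is not None else None,
    )


# ---------------------------------------------------------------------------
# public scans


def run_standard_gwas(G, pheno, A, **kw) -> list[AssociationResult]:
    """Standard additive GWAS on the pooled genotype X_PM (null model of the
    differential test; parent-of-origin is ignored)."""
    return _scan(G, pheno, A, "standard", **kw)


def run_parental_gwas(G, pheno, A, parent: str, **kw) -> list[AssociationResult]:
    """Single-parent GWAS: the trait regressed on the maternal (or paternal)
    allele alone; the other parent's allele is not in the model."""
    if parent not in ("maternal", "paternal"):
        raise ValueError(f"parent must be 'maternal' or 'paternal', got {parent!r}")
    return _scan(G, pheno, A, parent, **kw)


def run_differential_gwas(G, pheno, A, **kw) -> list[AssociationResult]:
    """Differential (opposite-effect) GWAS: tests b_M - b_P via the coefficient
    on d = (X_M - X_P)/2 with the total genotype X_PM as a covariate."""
    return _scan(G, pheno, A, "differential", **kw)


def run_differential_lrt(
    G, pheno, A, min_n: int = 10, eigen_cache: Optional[dict] = None
) -> list[AssociationResult]:
    """Differential test via a likelihood-ratio statistic (optional alternative
    to the default Wald test).

    Compares the full-likelihood (ML) fit of the parent-aware model
    (covariates + d + X_PM) against the pooled null (covariates + X_PM), each
    at its own ML lambda; 2*(ll_alt - ll_null) is referred to chi-square with
    one degree of freedom.  ML rather than REML likelihoods are used because
    restricted likelihoods are not comparable across fixed-effect designs.
    The reported beta/se are the GLS estimates at the alternative's lambda.
    """
    from scipy.stats import chi2

    ctx = _ScanContext(G, pheno, A, eigen_cache=eigen_cache)
    results: list[AssociationResult] = []
    for j, variant in enumerate(G.variants):
        dv = derive_design_vectors(ctx.G, j)
        mask = dv.mask[ctx.g_cols]
        n_an = int(mask.sum())
        if n_an < min_n:
            continue
        xm = ctx.G.maternal[j, ctx.g_cols][mask]
        xp = ctx.G.paternal[j, ctx.g_cols][mask]
        xpm = xm + xp
        d = (xm - xp) / 2.0
        if np.ptp(d) == 0 or np.ptp(xpm) == 0:
            continue
        af = xpm.mean() / 2.0
        s, U, yt, Wt = ctx.rotated(mask)
        dt, xt = U.T @ d, U.T @ xpm
        Z_null = np.column_stack([Wt, xt])
        Z_alt = np.column_stack([Wt, dt, xt])
        if np.linalg.matrix_rank(Z_alt) < Z_alt.shape[1]:
            continue
        vc_null = _fit_rotated(yt, Z_null, s, False, 60, 1e-6, "ML")
        vc_alt = _fit_rotated(yt, Z_alt, s, False, 60, 1e-6, "ML")
        stat = max(0.0, 2.0 * (vc_alt.log_likelihood - vc_null.log_likelihood))
        p = float(chi2.sf(stat, 1))
        fit = _gls_rotated(yt, Z_alt, s, vc_alt.lam)
        k = Wt.shape[1]
        results.append(
            AssociationResult(
                variant=variant,
                model="differential",
                n_analyzed=n_an,
                maf=float(min(af, 1.0 - af)),
                beta=float(fit.coefficients[k]),
                se=float(fit.standard_errors[k]),
                p=max(p, np.finfo(float).tiny),
                mean_effect=float(fit.coefficients[k + 1]),
                lam=float(vc_alt.lam),
                log_likelihood=vc_alt.log_likelihood,
            )
        )
    return results


def run_all_models(G, pheno, A, **kw) -> dict[str, list[AssociationResult]]:
    kw.setdefault("eigen_cache", {})  # share eigendecompositions across models
    return {
        "standard": run_standard_gwas(G, pheno, A, **kw),
        "maternal": run_parental_gwas(G, pheno, A, "maternal", **kw),
        "paternal": run_parental_gwas(G, pheno, A, "paternal", **kw),
        "differential": run_differential_gwas(G, pheno, A, **kw),
    }


# ---------------------------------------------------------------------------
# classification and filtering


def classify_poe(
    variant: Variant,
    p_standard: float,
    p_maternal: float,
    p_paternal: float,
    p_differential: float,
    genomewide_alpha: float = GENOME_WIDE_ALPHA,
) -> PoeCall:
    """Single-parent POE call: significant in exactly one parent and not in the
    standard GWAS, all at the same genome-wide alpha.  A differential effect
    (p of b_M - b_P below alpha) is reported separately and may co-occur."""
    a = genomewide_alpha
    for name, p in (
        ("standard", p_standard),
        ("maternal", p_maternal),
        ("paternal", p_paternal),
        ("differential", p_differential),
    ):
        if p is None or not np.isfinite(p):
            raise ValueError(f"missing {name} p-value for {variant.id}")
    maternal_only = p_maternal < a and p_paternal >= a and p_standard >= a
    paternal_only = p_paternal < a and p_maternal >= a and p_standard >= a
    differential = p_differential < a
    if maternal_only:
        classification = "maternal_only"
    elif paternal_only:
        classification = "paternal_only"
    elif differential:
        classification = "differential"
    else:
        classification = "none"
    return PoeCall(
        variant=variant,
        classification=classification,
        differential=differential,
        p_values={
            "standard": p_standard,
            "maternal": p_maternal,
            "paternal": p_paternal,
            "differential": p_differential,
        },
    )


def significance_filter(
    results: Sequence[AssociationResult], alpha: float = GENOME_WIDE_ALPHA
):
    """Rows with p strictly below alpha, in stable input order."""
    return [r for r in results if r.p < alpha]


def top_hits(
    results: Sequence[AssociationResult], window: int = 1_000_000
) -> list[AssociationResult]:
    """Greedy distance-based top-hit reporting: repeatedly take the most
    significant remaining variant and suppress others within ``window`` bp on
    the same chromosome.  A convenience reporter, not an LD-aware clumping."""
    remaining = sorted(results, key=lambda r: r.p)
    out: list[AssociationResult] = []
    for r in remaining:
        if all(
            r.variant.chrom != h.variant.chrom
            or abs(r.variant.pos - h.variant.pos) > window
            for h in out
        ):
            out.append(r)
    return out
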