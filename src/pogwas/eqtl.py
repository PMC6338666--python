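"""Parent-of-origin cis-eQTL testing.

For each query SNP, genes whose transcription start site (TSS) lies within a
fixed window (default 1 Mb, closed interval) on the same chromosome are tested
with the same mixed-model machinery as the phenotype scans, using each gene's
normalised expression vector as the trait.  The expression matrix is expected
to be already normalised (e.g. log-CPM with technical covariates handled
upstream); a small detection-filter helper is provided for users starting from
counts.  Multiple testing over all (SNP, gene) pairs is handled by Bonferroni.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import AssociationResult, _scan
from .genotypes import PhasedGenotypeMatrix, Variant
from .lmm import RelatednessMatrix
from .phenotype import PhenotypeFrame

log = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "EqtlResult",
    "read_gene_table",
    "select_cis_genes",
    "run_po_eqtl",
    "bonferroni_threshold",
    "cpm_detection_filter",
]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 1")


@dataclass
class EqtlResult:
    snp: Variant
    gene: GeneRecord
    model: str
    n_analyzed: int
    maf: float
    beta: float
    se: float
    p: float
    mean_effect: Optional[float] = None


def read_gene_table(path) -> list[GeneRecord]:
    """BED-like TSV with columns chrom, tss, gene_id, strand (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if list(df.columns[:3]) != ["chrom", "tss", "gene_id"]:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "tss", "gene_id", "strand"],
            dtype={0: str},
            comment="#",
        )
    if "strand" not in df.columns:
        df["strand"] = "+"
    return [
        GeneRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def select_cis_genes(
    snp: Variant, genes: Sequence[GeneRecord], window: int = 1_000_000
) -> list[GeneRecord]:
    """Genes on the SNP's chromosome with |TSS - pos| <= window (closed
    interval, strand-agnostic), in stable order by TSS position."""
    if window < 0:
        raise ValueError("window must be >= 0")
    hits = [
        g
        for g in genes
        if str(g.chrom) == str(snp.chrom) and abs(g.tss - snp.pos) <= window
    ]
    return sorted(hits, key=lambda g: (g.tss, g.gene_id))


def run_po_eqtl(
    snps: PhasedGenotypeMatrix,
    expression: pd.DataFrame,
    genes: Sequence[GeneRecord],
    A: RelatednessMatrix,
    mode: str,
    window: int = 1_000_000,
    covariates: Optional[PhenotypeFrame] = None,
    **scan_kw,
) -> list[EqtlResult]:
    """Test every (SNP, cis gene) pair under one model.

    ``expression`` is a genes x samples DataFrame (index = gene IDs, columns =
    sample IDs) of normalised values.  ``mode`` is one of "maternal",
    "paternal", "differential" or "standard".  Genes absent from the expression
    matrix are skipped with a log record.
    """
    if mode not in ("maternal", "paternal", "differential", "standard"):
        raise ValueError(f"unknown eQTL mode {mode!r}")
    expr_samples = [str(c) for c in expression.columns]
    results: list[EqtlResult] = []
    for j, snp in enumerate(snps.variants):
        cis = select_cis_genes(snp, genes, window)
        if not cis:
            continue
        sub = snps.subset_variants([j])
        for gene in cis:
            if gene.gene_id not in expression.index:
                log.info("gene %s not in expression matrix; skipped", gene.gene_id)
                continue
            yvec = expression.loc[gene.gene_id].to_numpy(dtype=float)
            keep = ~np.isnan(yvec)
            pheno = PhenotypeFrame(
                sample_ids=[s for s, k in zip(expr_samples, keep) if k],
                y=yvec[keep],
                W=np.ones((int(keep.sum()), 1)),
                covariate_names=["intercept"],
                phenotype_name=gene.gene_id,
            )
            if covariates is not None:
                pheno = _merge_covariates(pheno, covariates)
            rows = _scan(sub, pheno, A, mode, **scan_kw)
            for r in rows:
                results.append(
                    EqtlResult(
                        snp=snp,
                        gene=gene,
                        model=r.model,
                        n_analyzed=r.n_analyzed,
                        maf=r.maf,
                        beta=r.beta,
                        se=r.se,
                        p=r.p,
                        mean_effect=r.mean_effect,
                    )
                )
    return results


def _merge_covariates(pheno: PhenotypeFrame, cov: PhenotypeFrame) -> PhenotypeFrame:
    idx = {s: i for i, s in enumerate(cov.sample_ids)}
    keep = [i for i, s in enumerate(pheno.sample_ids) if s in idx]
    rows = [idx[pheno.sample_ids[i]] for i in keep]
    return PhenotypeFrame(
        sample_ids=[pheno.sample_ids[i] for i in keep],
        y=pheno.y[keep],
        W=cov.W[rows, :],
        covariate_names=list(cov.covariate_names),
        phenotype_name=pheno.phenotype_name,
    )


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold family_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def cpm_detection_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0
) -> pd.DataFrame:
    """Drop genes whose counts-per-million never exceed ``min_cpm`` in any
    sample.  A convenience for users starting from raw counts; the eQTL
    contract itself expects an already-normalised matrix."""
    lib = counts.sum(axis=0).astype(float)
    cpm = counts.div(lib, axis=1) * 1e6
    keep = (cpm > min_cpm).any(axis=1)
    return counts.loc[keep]
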