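"""Results and matrix serialisation.

The results TSV schema mirrors standard per-variant association reporting:
phenotype, rsid, chr, pos, effect_allele, other_allele, maf, n, model, beta,
se, p — one row per (variant, model).  p-values are written in scientific
notation with seven significant digits; betas and standard errors with six.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .association import AssociationResult
from .eqtl import EqtlResult
from .genotypes import Variant
from .lmm import RelatednessMatrix

log = logging.getLogger(__name__)

__all__ = [
    "RESULT_COLUMNS",
    "write_results",
    "read_results",
    "results_to_frame",
    "write_kinship",
    "read_kinship",
    "write_manifest",
]

RESULT_COLUMNS = [
    "phenotype",
    "rsid",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "maf",
    "n",
    "model",
    "beta",
    "se",
    "p",
]


def _fmt_p(p: float) -> str:
    return format(p, ".6E")


def _fmt_num(x) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else format(x, ".6g")


def results_to_frame(
    results: Sequence[Union[AssociationResult, EqtlResult]],
    phenotype: str = "trait",
) -> pd.DataFrame:
    rows = []
    for r in results:
        if isinstance(r, EqtlResult):
            v, pheno_name = r.snp, r.gene.gene_id
        else:
            v, pheno_name = r.variant, phenotype
        rows.append(
            {
                "phenotype": pheno_name,
                "rsid": v.id,
                "chr": v.chrom,
                "pos": v.pos,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "maf": r.maf,
                "n": r.n_analyzed,
                "model": r.model,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(
    results: Sequence[Union[AssociationResult, EqtlResult]],
    path,
    phenotype: str = "trait",
) -> None:
    """Write results as TSV (header always present, even for empty lists)."""
    df = results_to_frame(results, phenotype)
    lines = ["\t".join(RESULT_COLUMNS)]
    for row in df.itertuples(index=False):
        lines.append(
            "\t".join(
                [
                    str(row.phenotype),
                    str(row.rsid),
                    str(row.chr),
                    str(row.pos),
                    str(row.effect_allele),
                    str(row.other_allele),
                    _fmt_num(row.maf),
                    str(int(row.n)),
                    str(row.model),
                    _fmt_num(row.beta),
                    _fmt_num(row.se),
                    _fmt_p(row.p),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read a results TSV back into a typed DataFrame."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chr": str, "rsid": str, "phenotype": str, "model": str},
        na_values=["NA"],
    )
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results file {path} lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# kinship / GRM text format: square whitespace-delimited matrix + sidecar IDs


def write_kinship(A: RelatednessMatrix, matrix_path, ids_path) -> None:
    np.savetxt(matrix_path, A.matrix, fmt="%.10g", delimiter="\t")
    Path(ids_path).write_text("\n".join(A.sample_ids) + "\n")


def read_kinship(matrix_path, ids_path, source: str = "pedigree") -> RelatednessMatrix:
    M = np.loadtxt(matrix_path)
    if M.ndim == 0:
        M = M.reshape(1, 1)
    ids = Path(ids_path).read_text().split()
    return RelatednessMatrix(matrix=M, sample_ids=ids, source=source)


def write_manifest(path, config: dict, extra: Optional[dict] = None) -> None:
    """JSON run manifest: package version, full config echo, seed, counts.
    Deterministic (no timestamps) so identical runs are byte-identical."""
    from . import __version__

    manifest = {"pogwas_version": __version__, "config": config}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
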