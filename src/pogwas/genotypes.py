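"""Phased parent-of-origin genotypes: containers, readers/writers, QC filters, encodings.

A variant's genotype is represented as two haploid allele-count vectors, one per
parental origin: ``maternal`` (X_M) and ``paternal`` (X_P), each in {0, 1} with
NaN for missing.  The total genotype is X_PM = X_M + X_P in {0, 1, 2} and the
parent-of-origin contrast is d = (X_M - X_P) / 2 in {-0.5, 0, +0.5}; d is
non-zero only for heterozygotes whose parental origin is assigned, which are the
only observations that carry parent-of-origin information.

Phasing/parental-origin assignment itself (e.g. pedigree-based IBD phasing) is
upstream of this package; these readers consume its output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_SEX_CHROM = re.compile(r"^(chr)?(x|y|mt?|m)$", re.IGNORECASE)

__all__ = [
    "Variant",
    "PhasedGenotypeMatrix",
    "FilterReport",
    "DesignVectors",
    "GenotypeParseError",
    "UnsupportedPloidyError",
    "load_phased_genotypes",
    "apply_variant_filters",
    "derive_design_vectors",
    "write_phased_vcf",
    "write_two_matrix",
    "write_bimbam",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class UnsupportedPloidyError(GenotypeParseError):
    """Raised for non-diploid GT fields (triploid, hemizygous)."""


@dataclass(frozen=True)
class Variant:
    """A biallelic autosomal SNP; ``effect_allele`` is the counted allele."""

    chrom: str
    pos: int
    id: str
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"variant {self.id}: effect and other allele are identical")
        if _SEX_CHROM.match(str(self.chrom)):
            raise ValueError(
                f"variant {self.id}: chromosome {self.chrom} is not autosomal; "
                "only autosomes are supported"
            )


@dataclass
class PhasedGenotypeMatrix:
    """Per-variant maternal/paternal haploid allele counts for an ordered sample set.

    ``maternal`` and ``paternal`` are float arrays of shape (n_variants, n_samples)
    with values in {0.0, 1.0} and NaN for missing parental-origin calls.
    Missingness may differ between the two parental vectors of a sample.
    """

    variants: list[Variant]
    samples: list[str]
    maternal: np.ndarray
    paternal: np.ndarray

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=float)
        self.paternal = np.asarray(self.paternal, dtype=float)
        shape = (len(self.variants), len(self.samples))
        if self.maternal.shape != shape or self.paternal.shape != shape:
            raise ValueError(
                f"genotype arrays must have shape {shape}; got "
                f"{self.maternal.shape} / {self.paternal.shape}"
            )
        for name, arr in (("maternal", self.maternal), ("paternal", self.paternal)):
            ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
            if not ok.all():
                raise ValueError(f"{name} allele counts must be 0, 1 or NaN")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs in genotype matrix")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def xpm(self) -> np.ndarray:
        """Total allele count X_PM = X_M + X_P (NaN where either parent missing)."""
        return self.maternal + self.paternal

    def subset_variants(self, indices: Sequence[int]) -> "PhasedGenotypeMatrix":
        idx = list(indices)
        return PhasedGenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            maternal=self.maternal[idx, :].copy(),
            paternal=self.paternal[idx, :].copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "PhasedGenotypeMatrix":
        idx = list(indices)
        return PhasedGenotypeMatrix(
            variants=list(self.variants),
            samples=[self.samples[i] for i in idx],
            maternal=self.maternal[:, idx].copy(),
            paternal=self.paternal[:, idx].copy(),
        )


@dataclass
class FilterReport:
    """Accounting of a variant-QC pass; MAF is checked before call rate, so a
    variant failing both is attributed to ``n_fail_maf``."""

    n_input: int
    n_pass: int
    n_fail_maf: int
    n_fail_callrate: int
    maf_min: float
    call_rate_min: float

    def __post_init__(self) -> None:
        if self.n_input != self.n_pass + self.n_fail_maf + self.n_fail_callrate:
            raise ValueError("filter report counts do not sum to n_input")

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass": self.n_pass,
            "n_fail_maf": self.n_fail_maf,
            "n_fail_callrate": self.n_fail_callrate,
            "maf_min": self.maf_min,
            "call_rate_min": self.call_rate_min,
        }


class DesignVectors(NamedTuple):
    """Per-variant model inputs; arrays are full-length with NaN off-mask."""

    x_m: np.ndarray
    x_p: np.ndarray
    x_pm: np.ndarray
    d: np.ndarray
    mask: np.ndarray


# ---------------------------------------------------------------------------
# readers


def load_phased_genotypes(
    path,
    format: str = "phased-vcf",
    po_convention: str = "maternal-first",
) -> PhasedGenotypeMatrix:
    """Load phased genotypes with parental-origin assignment.

    Parameters
    ----------
    path
        For ``phased-vcf``: path to a VCF whose GT fields are phased with ``|``.
        For ``two-matrix-tsv``: a ``(maternal_path, paternal_path)`` pair.
    format
        ``"phased-vcf"`` or ``"two-matrix-tsv"``.
    po_convention
        Which haplotype of a phased GT is the maternal one: ``"maternal-first"``
        (left of ``|``) or ``"paternal-first"``.  There is no community standard
        for haplotype order in phased VCFs, so the convention is always explicit
        and echoed to the log.

    Unphased (``/``) and half-missing genotypes carry no parental-origin
    information and are recorded as missing in both parental vectors.
    """
    if po_convention not in ("maternal-first", "paternal-first"):
        raise ValueError(f"unknown po_convention {po_convention!r}")
    log.info("loading %s with parental-order convention: %s", format, po_convention)
    if format == "phased-vcf":
        return _load_vcf(path, po_convention)
    if format == "two-matrix-tsv":
        try:
            maternal_path, paternal_path = path
        except (TypeError, ValueError) as exc:
            raise ValueError(
                "two-matrix-tsv format requires a (maternal_path, paternal_path) pair"
            ) from exc
        return _load_two_matrix(maternal_path, paternal_path)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_vcf(path, po_convention: str) -> PhasedGenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on malformed input
        raise GenotypeParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    variants: list[Variant] = []
    mat_rows: list[np.ndarray] = []
    pat_rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            log.warning(
                "skipping multi-allelic site %s:%d (%s)", rec.CHROM, rec.POS, rec.ID
            )
            continue
        if _SEX_CHROM.match(str(rec.CHROM)):
            log.warning("skipping non-autosomal site %s:%d", rec.CHROM, rec.POS)
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variant = Variant(
            chrom=str(rec.CHROM),
            pos=int(rec.POS),
            id=vid,
            effect_allele=rec.ALT[0],
            other_allele=rec.REF,
        )
        mat = np.full(len(samples), np.nan)
        pat = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            # cyvcf2 genotype entry: [allele_0, ..., phased_flag]
            if len(gt) != 3:
                raise UnsupportedPloidyError(
                    f"{variant.id}: sample {samples[i]} has ploidy {len(gt) - 1}; "
                    "only diploid genotypes are supported"
                )
            a1, a2, phased = gt
            if a1 < 0 or a2 < 0 or not phased:
                continue  # missing, half-missing, or unphased: no PO assignable
            first, second = float(a1), float(a2)
            if po_convention == "maternal-first":
                mat[i], pat[i] = first, second
            else:
                mat[i], pat[i] = second, first
        variants.append(variant)
        mat_rows.append(mat)
        pat_rows.append(pat)
    if not variants:
        return PhasedGenotypeMatrix(
            [], samples, np.empty((0, len(samples))), np.empty((0, len(samples)))
        )
    return PhasedGenotypeMatrix(
        variants, samples, np.vstack(mat_rows), np.vstack(pat_rows)
    )


_META_COLS = ["chrom", "pos", "id", "effect_allele", "other_allele"]


def _load_two_matrix(maternal_path, paternal_path) -> PhasedGenotypeMatrix:
    def read_one(p):
        try:
            df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
        except Exception as exc:
            raise GenotypeParseError(f"cannot parse {p}: {exc}") from exc
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise GenotypeParseError(f"{p}: missing metadata columns {missing}")
        return df

    dm = read_one(maternal_path)
    dp = read_one(paternal_path)
    if list(dm.columns) != list(dp.columns):
        raise GenotypeParseError("maternal/paternal matrices have different columns")
    if not dm[_META_COLS].equals(dp[_META_COLS]):
        raise GenotypeParseError("maternal/paternal matrices disagree on variant metadata")
    samples = [c for c in dm.columns if c not in _META_COLS]
    variants = [
        Variant(str(r.chrom), int(r.pos), str(r.id), str(r.effect_allele), str(r.other_allele))
        for r in dm[_META_COLS].itertuples(index=False)
    ]
    maternal = dm[samples].to_numpy(dtype=float)
    paternal = dp[samples].to_numpy(dtype=float)
    return PhasedGenotypeMatrix(variants, samples, maternal, paternal)


# ---------------------------------------------------------------------------
# QC filters


def apply_variant_filters(
    G: PhasedGenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.85,
) -> tuple[PhasedGenotypeMatrix, FilterReport]:
    """Retain variants with MAF strictly above ``maf_min`` and call rate strictly
    above ``call_rate_min``.

    MAF is computed on the total genotype over samples with both parental calls;
    call rate is the fraction of samples with both parental calls.  The defaults
    (MAF > 1%, call rate > 85%) are the QC thresholds of a one-time genotype
    pass over all loaded samples.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= call_rate_min <= 1.0:
        raise ValueError("call_rate_min must be in [0, 1]")
    if G.n_variants == 0 or G.n_samples == 0:
        raise ValueError("cannot filter an empty genotype matrix")

    xpm = G.xpm()
    called = ~np.isnan(xpm)
    n_called = called.sum(axis=1)
    call_rate = n_called / G.n_samples
    with np.errstate(invalid="ignore"):
        af = np.nansum(xpm, axis=1) / np.maximum(2.0 * n_called, 1.0)
    maf = np.minimum(af, 1.0 - af)
    maf = np.where(n_called == 0, 0.0, maf)

    fail_maf = ~(maf > maf_min)
    fail_cr = ~(call_rate > call_rate_min) & ~fail_maf  # MAF attributed first
    keep = ~fail_maf & ~fail_cr
    report = FilterReport(
        n_input=G.n_variants,
        n_pass=int(keep.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_callrate=int(fail_cr.sum()),
        maf_min=maf_min,
        call_rate_min=call_rate_min,
    )
    if report.n_pass == 0:
        log.warning("all %d variants removed by QC filters", G.n_variants)
    return G.subset_variants(np.flatnonzero(keep)), report


def derive_design_vectors(G: PhasedGenotypeMatrix, variant_index: int) -> DesignVectors:
    """Model inputs for one variant: (x_m, x_p, x_pm, d, mask).

    ``mask`` marks samples with both parental calls; d = (x_m - x_p)/2 takes
    values in {-0.5, 0, +0.5} on the mask (homozygotes carry no parent-of-origin
    information, so d = 0 for them).
    """
    if not 0 <= variant_index < G.n_variants:
        raise IndexError(f"variant index {variant_index} out of range")
    x_m = G.maternal[variant_index].copy()
    x_p = G.paternal[variant_index].copy()
    mask = ~np.isnan(x_m) & ~np.isnan(x_p)
    x_m[~mask] = np.nan
    x_p[~mask] = np.nan
    x_pm = x_m + x_p
    d = (x_m - x_p) / 2.0
    return DesignVectors(x_m, x_p, x_pm, d, mask)


# ---------------------------------------------------------------------------
# writers


def write_phased_vcf(
    G: PhasedGenotypeMatrix, path, po_convention: str = "maternal-first"
) -> None:
    """Write a minimal phased VCF (v4.2).  A sample missing either parental call
    is written as ``./.`` — this format cannot represent one-sided missingness."""
    if po_convention not in ("maternal-first", "paternal-first"):
        raise ValueError(f"unknown po_convention {po_convention!r}")
    contigs = list(dict.fromkeys(v.chrom for v in G.variants))
    lines = (
        ["##fileformat=VCFv4.2"]
        + [f"##contig=<ID={c}>" for c in contigs]
        + [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype; '
            f'haplotype order: {po_convention}">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples),
        ]
    )
    for j, v in enumerate(G.variants):
        gts = []
        for i in range(G.n_samples):
            m, p = G.maternal[j, i], G.paternal[j, i]
            if np.isnan(m) or np.isnan(p):
                gts.append("./.")
            elif po_convention == "maternal-first":
                gts.append(f"{int(m)}|{int(p)}")
            else:
                gts.append(f"{int(p)}|{int(m)}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t{v.effect_allele}"
            "\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _format_counts(row: np.ndarray) -> list[str]:
    return ["NA" if np.isnan(x) else str(int(x)) for x in row]


def write_two_matrix(G: PhasedGenotypeMatrix, maternal_path, paternal_path) -> None:
    """Write the two-matrix TSV pair (maternal and paternal haploid counts)."""
    header = "\t".join(_META_COLS + list(G.samples))
    for path, arr in ((maternal_path, G.maternal), (paternal_path, G.paternal)):
        lines = [header]
        for j, v in enumerate(G.variants):
            meta = [v.chrom, str(v.pos), v.id, v.effect_allele, v.other_allele]
            lines.append("\t".join(meta + _format_counts(arr[j])))
        Path(path).write_text("\n".join(lines) + "\n")


def write_bimbam(G: PhasedGenotypeMatrix, path, encoding: str = "mean") -> None:
    """Write BIMBAM mean-genotype rows: id, effect allele, other allele, values.

    ``encoding="mean"`` writes the total genotype X_PM (the "average genotype"
    covariate of the differential model); ``encoding="differential"`` writes
    d = (X_M - X_P)/2, the tested regressor of the differential model.
    """
    if encoding == "mean":
        values = G.xpm()
    elif encoding == "differential":
        values = (G.maternal - G.paternal) / 2.0
    else:
        raise ValueError(f"unknown BIMBAM encoding {encoding!r}")
    lines = []
    for j, v in enumerate(G.variants):
        vals = ["NA" if np.isnan(x) else format(x, "g") for x in values[j]]
        lines.append(", ".join([v.id, v.effect_allele, v.other_allele] + vals))
    Path(path).write_text("\n".join(lines) + "\n")
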