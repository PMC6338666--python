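"""Seeded synthetic-data generator: pedigrees, gene-dropped phased genotypes
with known parental origin, and phenotypes/expression with configurable
maternal, paternal, opposite and polygenic effects.

The generator emulates a founder-population study design: a closed pedigree of
a few non-overlapping generations, genotypes produced by Mendelian
gene-dropping (one draw per meiosis, parental origin tracked by construction),
and traits built from the generative model

    Y = W a + sum_causal (X_M b_M + X_P b_P) + g + e,
    g ~ N(0, A*sigma_g^2),  e ~ N(0, I*sigma_e^2).

Variants are independent (no linkage disequilibrium) — sufficient to exercise
single-SNP tests.  All randomness flows from ``SimulationConfig.seed``; every
dataset retains its ground truth for downstream recovery assertions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import PhasedGenotypeMatrix, Variant, write_phased_vcf, write_two_matrix
from .lmm import RelatednessMatrix
from .pedigree import Individual, Pedigree, compute_pedigree_relationship, write_fam
from .phenotype import PhenotypeFrame
from .eqtl import GeneRecord

log = logging.getLogger(__name__)

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "simulate_pedigree",
    "gene_drop_genotypes",
    "mask_parent_of_origin",
    "simulate_phenotype",
    "simulate_expression",
    "write_dataset",
]


@dataclass(frozen=True)
class EffectSpec:
    """Per-causal-variant parental effect sizes; an opposite-effect scenario is
    beta_m = -beta_p != 0."""

    variant_index: int
    beta_m: float
    beta_p: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta_m) and np.isfinite(self.beta_p)):
            raise ValueError("effect sizes must be finite")


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    ``n_founders`` individuals form generation 0; each later generation is
    produced by random within-generation mating (parent-offspring and full-sib
    matings disallowed) with ``round(n_couples * mean_offspring)`` children, so
    ``mean_offspring = 2.0`` keeps generation sizes constant.  Founder allele
    frequencies are drawn uniformly from ``maf_range``; ``causal_maf`` pins the
    frequency of planted causal variants (0.3 by default, a common variant well
    above typical QC cutoffs).  Variance components default to
    sigma_g2 = sigma_e2 = 0.5.  ``missing_po_rate`` masks parental origin
    i.i.d. per sample x variant.
    """

    n_founders: int = 100
    n_generations: int = 3
    mean_offspring: float = 2.0
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf: float = 0.3
    sigma_g2: float = 0.5
    sigma_e2: float = 0.5
    covariate_effects: dict = field(default_factory=dict)  # name -> alpha
    missing_po_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need n_founders >= 2 and n_generations >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")
        if not 0.0 <= self.missing_po_rate < 1.0:
            raise ValueError("missing_po_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Multi-generation pedigree by random within-generation mating.

    Deterministic under the config seed.  Couples are male-female pairs from
    the current generation avoiding full sibs (parent-offspring pairs cannot
    arise since mating is within-generation); children are distributed
    cyclically over couples so generation sizes are exact.
    """
    rng = np.random.default_rng(config.seed)
    inds: list[Individual] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    current: list[Individual] = []
    for _ in range(config.n_founders):
        sex = "M" if len(current) % 2 == 0 else "F"
        ind = Individual(new_id(), None, None, sex, generation=0)
        current.append(ind)
        inds.append(ind)

    parents_of = {i.iid: (None, None) for i in current}
    for gen in range(1, config.n_generations):
        males = [i for i in current if i.sex == "M"]
        females = [i for i in current if i.sex == "F"]
        couples = _pair_avoiding_sibs(males, females, parents_of, rng)
        if not couples:
            raise ValueError(f"no valid couples in generation {gen}")
        n_children = int(round(len(couples) * config.mean_offspring))
        children: list[Individual] = []
        for k in range(n_children):
            father, mother = couples[k % len(couples)]
            sex = "M" if k % 2 == 0 else "F"
            child = Individual(new_id(), father.iid, mother.iid, sex, generation=gen)
            parents_of[child.iid] = (father.iid, mother.iid)
            children.append(child)
            inds.append(child)
        current = children
    return Pedigree(inds)


def _pair_avoiding_sibs(males, females, parents_of, rng):
    males = list(males)
    females = list(females)
    rng.shuffle(males)
    rng.shuffle(females)
    couples = []
    used = set()
    for m in males:
        pm = parents_of[m.iid]
        for f in females:
            if f.iid in used:
                continue
            pf = parents_of[f.iid]
            full_sibs = pm != (None, None) and pm == pf
            if not full_sibs:
                couples.append((m, f))
                used.add(f.iid)
                break
    return couples


# ---------------------------------------------------------------------------
# genotypes


def gene_drop_genotypes(
    ped: Pedigree,
    config: SimulationConfig,
    allele_freqs: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PhasedGenotypeMatrix, np.ndarray]:
    """Phased genotypes with true parental origin by gene-dropping.

    Founders receive two independent Bernoulli(p) alleles (the first recorded
    as maternal — founders have no assigned origin and the two draws are
    exchangeable); each offspring receives one uniformly chosen allele from
    each parent's pair, recorded as maternal/paternal by construction.
    Variants are independent.  Returns ``(G, allele_freqs)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    m = config.n_variants
    n = len(ped)
    if allele_freqs is None:
        lo, hi = config.maf_range
        allele_freqs = rng.uniform(lo, hi, size=m)
    else:
        allele_freqs = np.asarray(allele_freqs, float)
        m = allele_freqs.shape[0]

    fa, mo = ped.parent_indices()
    order = ped.topological_order()
    hap_m = np.empty((m, n))
    hap_p = np.empty((m, n))
    for i in order:
        f, mth = fa[i], mo[i]
        if mth >= 0:
            pick = rng.integers(0, 2, size=m)
            hap_m[:, i] = np.where(pick == 0, hap_m[:, mth], hap_p[:, mth])
        else:
            hap_m[:, i] = rng.random(m) < allele_freqs
        if f >= 0:
            pick = rng.integers(0, 2, size=m)
            hap_p[:, i] = np.where(pick == 0, hap_m[:, f], hap_p[:, f])
        else:
            hap_p[:, i] = rng.random(m) < allele_freqs

    variants = [
        Variant(chrom="1", pos=(j + 1) * 100_000, id=f"snp{j:05d}",
                effect_allele="A", other_allele="G")
        for j in range(m)
    ]
    G = PhasedGenotypeMatrix(variants, ped.ids, hap_m, hap_p)
    return G, allele_freqs


def mask_parent_of_origin(
    G: PhasedGenotypeMatrix, rate: float, rng: np.random.Generator
) -> PhasedGenotypeMatrix:
    """Observed-data copy with parental origin masked i.i.d. at ``rate`` per
    sample x variant (both parental calls set missing)."""
    mat = G.maternal.copy()
    pat = G.paternal.copy()
    drop = rng.random(mat.shape) < rate
    mat[drop] = np.nan
    pat[drop] = np.nan
    return PhasedGenotypeMatrix(list(G.variants), list(G.samples), mat, pat)


# ---------------------------------------------------------------------------
# phenotypes / expression


def simulate_phenotype(
    G_true: PhasedGenotypeMatrix,
    ped: Pedigree,
    effects: Sequence[EffectSpec],
    config: SimulationConfig,
    A: Optional[RelatednessMatrix] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PhenotypeFrame, dict]:
    """Y = W a + sum (X_M b_M + X_P b_P) + g + e from true parental alleles.

    g is drawn through the Cholesky factor of A*sigma_g2 (A from the pedigree
    unless supplied).  Covariates named in ``config.covariate_effects`` are
    standard normal draws, except ``sex`` which is the pedigree sex coded
    0 (M) / 1 (F).  Returns ``(PhenotypeFrame, truth)`` with all generative
    components retained.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(ped)
    if A is None:
        A = compute_pedigree_relationship(ped)
    for spec in effects:
        if not 0 <= spec.variant_index < G_true.n_variants:
            raise ValueError(f"causal variant index {spec.variant_index} out of range")

    cov_names = ["intercept"]
    W_cols = [np.ones(n)]
    alphas = [0.0]
    for name, alpha in config.covariate_effects.items():
        if name == "sex":
            col = np.array([1.0 if ind.sex == "F" else 0.0 for ind in ped.individuals])
        else:
            col = rng.standard_normal(n)
        W_cols.append(col)
        cov_names.append(name)
        alphas.append(float(alpha))
    W = np.column_stack(W_cols)
    alphas = np.array(alphas)

    genetic = np.zeros(n)
    for spec in effects:
        xm = G_true.maternal[spec.variant_index]
        xp = G_true.paternal[spec.variant_index]
        if np.isnan(xm).any() or np.isnan(xp).any():
            raise ValueError("simulate_phenotype requires complete true genotypes")
        genetic += spec.beta_m * xm + spec.beta_p * xp

    if config.sigma_g2 > 0:
        try:
            L = np.linalg.cholesky(A.matrix + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("relatedness matrix is not PSD within tolerance") from exc
        g = np.sqrt(config.sigma_g2) * (L @ rng.standard_normal(n))
    else:
        g = np.zeros(n)
    eps = (
        np.sqrt(config.sigma_e2) * rng.standard_normal(n)
        if config.sigma_e2 > 0
        else np.zeros(n)
    )
    y = W @ alphas + genetic + g + eps

    pheno = PhenotypeFrame(
        sample_ids=ped.ids, y=y, W=W, covariate_names=cov_names,
        phenotype_name="sim_trait",
    )
    truth = {
        "effects": [dataclasses.asdict(e) for e in effects],
        "alphas": alphas.tolist(),
        "covariate_names": cov_names,
        "sigma_g2": config.sigma_g2,
        "sigma_e2": config.sigma_e2,
        "g": g,
        "epsilon": eps,
        "fixed_genetic": genetic,
    }
    return pheno, truth


def simulate_expression(
    G_true: PhasedGenotypeMatrix,
    ped: Pedigree,
    cis_effects: Sequence[tuple[str, EffectSpec]],
    config: SimulationConfig,
    A: Optional[RelatednessMatrix] = None,
    rng: Optional[np.random.Generator] = None,
    tss_offset: int = 50_000,
) -> tuple[pd.DataFrame, list[GeneRecord], dict]:
    """Expression matrix (genes x samples) with per-gene cis effects.

    Each ``(gene_id, EffectSpec)`` pair places the gene's TSS ``tss_offset`` bp
    from its designated SNP and generates its expression vector via
    :func:`simulate_phenotype` with that single effect.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if A is None:
        A = compute_pedigree_relationship(ped)
    rows, records, truth = [], [], {}
    for gene_id, spec in cis_effects:
        pheno, t = simulate_phenotype(G_true, ped, [spec], config, A=A, rng=rng)
        rows.append(pheno.y)
        snp = G_true.variants[spec.variant_index]
        records.append(
            GeneRecord(gene_id=gene_id, chrom=snp.chrom, tss=snp.pos + tss_offset)
        )
        truth[gene_id] = t
    expr = pd.DataFrame(np.vstack(rows), index=[g.gene_id for g in records],
                        columns=ped.ids)
    return expr, records, truth


# ---------------------------------------------------------------------------
# round-trip fixture writer


def write_dataset(
    out_dir,
    ped: Pedigree,
    G: PhasedGenotypeMatrix,
    pheno: PhenotypeFrame,
    truth: dict,
    A: Optional[RelatednessMatrix] = None,
    genes: Optional[Sequence[GeneRecord]] = None,
    expression: Optional[pd.DataFrame] = None,
) -> dict:
    """Write every format the readers consume; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fam": out / "pedigree.fam",
        "vcf": out / "genotypes.vcf",
        "maternal": out / "genotypes.maternal.tsv",
        "paternal": out / "genotypes.paternal.tsv",
        "kinship": out / "kinship.txt",
        "kinship_ids": out / "kinship.ids.txt",
        "phenotype": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    write_fam(ped, paths["fam"])
    write_phased_vcf(G, paths["vcf"])
    write_two_matrix(G, paths["maternal"], paths["paternal"])
    if A is None:
        A = compute_pedigree_relationship(ped)
    from .io import write_kinship

    write_kinship(A, paths["kinship"], paths["kinship_ids"])

    cols = {"sample_id": pheno.sample_ids, pheno.phenotype_name: pheno.y}
    for j, name in enumerate(pheno.covariate_names):
        if name != "intercept":
            cols[name] = pheno.W[:, j]
    pd.DataFrame(cols).to_csv(paths["phenotype"], sep="\t", index=False, na_rep="NA")

    serializable = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()
    }
    paths["truth"].write_text(json.dumps(serializable, indent=1))

    if genes is not None:
        paths["genes"] = out / "genes.bed"
        lines = [f"{g.chrom}\t{g.tss}\t{g.gene_id}\t{g.strand}" for g in genes]
        paths["genes"].write_text("\n".join(lines) + "\n")
    if expression is not None:
        paths["expression"] = out / "expression.tsv"
        expression.to_csv(paths["expression"], sep="\t", na_rep="NA")
    # names relative to out_dir so manifests stay location-independent
    return {k: v.name for k, v in paths.items()}
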