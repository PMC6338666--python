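import numpy as np
import pytest

from pogwas import (
    Individual,
    Pedigree,
    SimulationConfig,
    compute_pedigree_relationship,
    gene_drop_genotypes,
    simulate_pedigree,
    simulate_phenotype,
)


@pytest.fixture
def nuclear_ped() -> Pedigree:
    """Two unrelated founders with two full-sib offspring."""
    return Pedigree(
        [
            Individual("dad", None, None, "M"),
            Individual("mom", None, None, "F"),
            Individual("kid1", "dad", "mom", "M"),
            Individual("kid2", "dad", "mom", "F"),
        ]
    )


@pytest.fixture
def inbred_ped() -> Pedigree:
    """Offspring of half sibs: F = 1/8, so its diagonal A entry is 1.125."""
    return Pedigree(
        [
            Individual("gdad", None, None, "M"),
            Individual("gmom1", None, None, "F"),
            Individual("gmom2", None, None, "F"),
            Individual("halfsib1", "gdad", "gmom1", "M"),
            Individual("halfsib2", "gdad", "gmom2", "F"),
            Individual("inbred", "halfsib1", "halfsib2", "M"),
        ]
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """A modest seeded pedigree study: ~180 related individuals, 40 variants,
    polygenic-only (null) trait.  Shared by read-only tests."""
    cfg = SimulationConfig(
        n_founders=60, n_generations=3, mean_offspring=2.0, n_variants=40, seed=7
    )
    ped = simulate_pedigree(cfg)
    G, freqs = gene_drop_genotypes(ped, cfg)
    A = compute_pedigree_relationship(ped)
    pheno, truth = simulate_phenotype(G, ped, [], cfg, A=A)
    return {"cfg": cfg, "ped": ped, "G": G, "A": A, "pheno": pheno, "truth": truth}
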