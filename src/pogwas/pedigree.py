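"""Pedigrees and additive relationship matrices.

The additive relationship matrix A (twice the kinship matrix) encodes the
expected additive genetic covariance between individuals: parent-offspring and
full-sib pairs have A = 0.5, an outbred individual has A_ii = 1, and inbreeding
raises the diagonal to 1 + F.  A enters the mixed model through the polygenic
random effect g ~ N(0, A*sigma_g^2).

Two routes are provided: the exact recursive (tabular) algorithm, and a
Monte-Carlo gene-dropping estimator of identity-by-descent that serves as an
independent cross-check of the recursion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "read_fam",
    "write_fam",
    "compute_pedigree_relationship",
    "monte_carlo_relationship",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown parents...)."""


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str]  # None = unknown
    mother: Optional[str]
    sex: str = "U"  # "M", "F", or "U"
    generation: Optional[int] = None


@dataclass
class Pedigree:
    """An ordered set of individuals with parent links.

    Founders have both parents unknown; an individual with exactly one known
    parent is a half-founder and is treated as if the missing parent were an
    unrelated founder (logged).
    """

    individuals: list[Individual]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [ind.iid for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual IDs in pedigree")
        self._index = {iid: i for i, iid in enumerate(ids)}
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._index:
                    raise PedigreeError(
                        f"{ind.iid}: parent {parent} not present in pedigree"
                    )
            if (ind.father is None) != (ind.mother is None):
                log.info(
                    "%s has one known parent; treating as half-founder with an "
                    "unrelated missing parent",
                    ind.iid,
                )
        self.topological_order()  # validates acyclicity eagerly

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    def __len__(self) -> int:
        return len(self.individuals)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(father_idx, mother_idx) arrays with -1 for unknown."""
        fa = np.full(len(self), -1, dtype=int)
        mo = np.full(len(self), -1, dtype=int)
        for i, ind in enumerate(self.individuals):
            if ind.father is not None:
                fa[i] = self._index[ind.father]
            if ind.mother is not None:
                mo[i] = self._index[ind.mother]
        return fa, mo

    def topological_order(self) -> list[int]:
        """Indices ordered so every parent precedes its offspring; raises on cycles."""
        fa, mo = (
            np.full(len(self), -1, dtype=int),
            np.full(len(self), -1, dtype=int),
        )
        fa, mo = self.parent_indices()
        order: list[int] = []
        state = np.zeros(len(self), dtype=int)  # 0 unvisited, 1 active, 2 done

        def visit(i: int, stack: list[int]) -> None:
            if state[i] == 2:
                return
            if state[i] == 1:
                cyc = " -> ".join(self.individuals[j].iid for j in stack + [i])
                raise PedigreeError(f"pedigree cycle: {cyc} (individual is its own ancestor)")
            state[i] = 1
            for p in (fa[i], mo[i]):
                if p >= 0:
                    visit(p, stack + [i])
            state[i] = 2
            order.append(i)

        import sys

        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 10 * len(self) + 100))
        try:
            for i in range(len(self)):
                visit(i, [])
        finally:
            sys.setrecursionlimit(old_limit)
        return order


# ---------------------------------------------------------------------------
# I/O: PLINK-style .fam-like TSV (id, father, mother, sex), "0" = unknown


def read_fam(path) -> Pedigree:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["iid", "father", "mother", "sex"], dtype=str
    )
    inds = [
        Individual(
            iid=r.iid,
            father=None if r.father in ("0", None) else r.father,
            mother=None if r.mother in ("0", None) else r.mother,
            sex={"1": "M", "2": "F"}.get(str(r.sex), str(r.sex)),
        )
        for r in df.itertuples(index=False)
    ]
    return Pedigree(inds)


def write_fam(ped: Pedigree, path) -> None:
    lines = [
        "\t".join(
            [
                ind.iid,
                ind.father or "0",
                ind.mother or "0",
                {"M": "1", "F": "2"}.get(ind.sex, "0"),
            ]
        )
        for ind in ped.individuals
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# relationship matrices


def compute_pedigree_relationship(ped: Pedigree):
    """Additive relationship matrix A = 2*Phi by the recursive tabular method.

    Processing individuals with parents before offspring:
    A_ij = (A_{j,father(i)} + A_{j,mother(i)}) / 2 for previously processed j,
    and A_ii = 1 + A_{father(i),mother(i)} / 2.  An unknown parent contributes 0
    (unrelated founder).
    """
    from .lmm import RelatednessMatrix

    n = len(ped)
    fa, mo = ped.parent_indices()
    order = ped.topological_order()
    A = np.zeros((n, n))
    for i in order:
        f, m = fa[i], mo[i]
        row = np.zeros(n)
        if f >= 0:
            row += 0.5 * A[f]
        if m >= 0:
            row += 0.5 * A[m]
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[f, m] if (f >= 0 and m >= 0) else 0.0)
    return RelatednessMatrix(matrix=A, sample_ids=ped.ids, source="pedigree")


def monte_carlo_relationship(
    ped: Pedigree, n_replicates: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate A by gene-dropping unique founder alleles and scoring IBD.

    Each replicate drops labelled founder alleles down the pedigree (one
    Mendelian draw per meiosis).  Kinship phi_ij is the probability that a
    random allele of i is identical by descent to a random allele of j;
    A_ij = 2*phi_ij off-diagonal and A_ii = 1 + F_i with F_i the probability
    that i's two alleles are IBD.

    Returns ``(A_hat, se)`` where ``se`` is the per-entry Monte-Carlo standard
    error.  Independent of :func:`compute_pedigree_relationship` by
    construction; intended for validation on small pedigrees.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    fa, mo = ped.parent_indices()
    order = ped.topological_order()
    R = n_replicates

    # allele labels per individual: pat[i], mat[i] are (R,) int arrays
    pat = np.empty((n, R), dtype=np.int64)
    mat = np.empty((n, R), dtype=np.int64)
    next_label = 0
    for i in order:
        f, m = fa[i], mo[i]
        if f >= 0:
            pick = rng.integers(0, 2, size=R, dtype=np.int8)
            pat[i] = np.where(pick == 0, pat[f], mat[f])
        else:
            pat[i] = next_label
            next_label += 1
        if m >= 0:
            pick = rng.integers(0, 2, size=R, dtype=np.int8)
            mat[i] = np.where(pick == 0, pat[m], mat[m])
        else:
            mat[i] = next_label
            next_label += 1

    A_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                stat = (pat[i] == mat[i]).astype(float)  # per-replicate F indicator
                vals = 1.0 + stat
            else:
                shared = (
                    (pat[i] == pat[j]).astype(float)
                    + (pat[i] == mat[j])
                    + (mat[i] == pat[j])
                    + (mat[i] == mat[j])
                )
                vals = 0.5 * shared  # 2 * phi per replicate
            A_hat[i, j] = A_hat[j, i] = vals.mean()
            se[i, j] = se[j, i] = vals.std(ddof=1) / np.sqrt(R)
    return A_hat, se
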