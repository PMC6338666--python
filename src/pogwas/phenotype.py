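"""Phenotype/covariate design assembly, residualisation, and the rank-based
inverse-normal transform.

Covariates enter the mixed model as fixed effects (the primary mode).  A
pre-residualisation path — regress the trait on covariates by OLS, then
inverse-normal-transform the residuals — replicates the replication-cohort
procedure and is approximate relative to joint fitting; it is provided for
that use and labelled as such in its log records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "PhenotypeFrame",
    "read_phenotype_table",
    "build_design",
    "residualize",
    "inverse_normal_transform",
    "load_phenotype_config",
]


@dataclass
class PhenotypeFrame:
    """Trait vector y, covariate matrix W (intercept first), aligned sample IDs."""

    sample_ids: list[str]
    y: np.ndarray
    W: np.ndarray
    covariate_names: list[str] = field(default_factory=lambda: ["intercept"])
    transform_log: list[str] = field(default_factory=list)
    phenotype_name: str = "trait"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.W = np.asarray(self.W, float)
        if self.W.ndim != 2 or self.W.shape[0] != self.y.shape[0]:
            raise ValueError("W rows must align with y")
        if len(self.sample_ids) != self.y.shape[0]:
            raise ValueError("sample_ids must align with y")
        if self.W.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names must match W columns")
        is_const = [np.ptp(self.W[:, j]) == 0 and np.any(self.W[:, j] != 0)
                    for j in range(self.W.shape[1])]
        if sum(is_const) != 1:
            raise ValueError("W must contain exactly one intercept (constant) column")
        for j, const in enumerate(is_const):
            if const and self.covariate_names[j] != "intercept":
                raise ValueError(
                    f"constant non-intercept covariate: {self.covariate_names[j]}"
                )

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def subset(self, indices) -> "PhenotypeFrame":
        idx = np.asarray(indices)
        return PhenotypeFrame(
            sample_ids=[self.sample_ids[i] for i in idx],
            y=self.y[idx],
            W=self.W[idx, :],
            covariate_names=list(self.covariate_names),
            transform_log=list(self.transform_log),
            phenotype_name=self.phenotype_name,
        )


def read_phenotype_table(path) -> pd.DataFrame:
    """Phenotype/covariate TSV: first column sample ID, header row, 'NA' missing."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str})
    df = df.rename(columns={df.columns[0]: "sample_id"})
    return df


def _resolve_covariate(table: pd.DataFrame, name: str) -> tuple[pd.Series, str]:
    """Resolve a covariate name, supporting squared terms 'x^2' / 'x**2'."""
    if name in table.columns:
        return table[name], name
    for suffix in ("^2", "**2"):
        if name.endswith(suffix):
            base = name[: -len(suffix)]
            if base in table.columns:
                return table[base].astype(float) ** 2, f"{base}^2"
    raise KeyError(f"covariate {name!r} not found in phenotype table")


def build_design(
    pheno_table: pd.DataFrame,
    phenotype: str,
    covariate_names: Sequence[str] = (),
    exclusions: Optional[Sequence[str]] = None,
    transform: Optional[str] = None,
) -> PhenotypeFrame:
    """Assemble a PhenotypeFrame from a phenotype table.

    Categorical covariates are expanded to indicator columns dropping one
    level; squared terms may be requested as ``"age^2"``.  Samples missing the
    trait or any covariate are dropped (recorded in ``transform_log``).
    ``transform`` may be ``"inverse-normal"`` to apply the rank-based transform
    to the trait after exclusions.
    """
    table = pheno_table.copy()
    if "sample_id" not in table.columns:
        table = table.rename(columns={table.columns[0]: "sample_id"})
    table["sample_id"] = table["sample_id"].astype(str)
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in phenotype table: {dups}")
    if phenotype not in table.columns:
        raise KeyError(f"phenotype {phenotype!r} not found in table")

    tlog: list[str] = []
    if exclusions:
        before = len(table)
        table = table[~table["sample_id"].isin(set(map(str, exclusions)))]
        tlog.append(f"excluded {before - len(table)} samples by ID")

    cols: list[pd.Series] = []
    names: list[str] = []
    for raw in covariate_names:
        series, resolved = _resolve_covariate(table, raw)
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series, prefix=resolved, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].astype(float))
                names.append(str(c))
            # propagate missingness of the original categorical
            na = series.isna()
            if na.any():
                for c in cols[-dummies.shape[1]:]:
                    c[na] = np.nan
        else:
            cols.append(series.astype(float))
            names.append(resolved)

    y = table[phenotype].astype(float)
    keep = ~y.isna()
    for c in cols:
        keep &= ~c.isna()
    dropped = int((~keep).sum())
    if dropped:
        tlog.append(f"dropped {dropped} samples with missing trait or covariates")
    if keep.sum() == 0:
        raise ValueError("no usable samples after removing missing values")
    table = table[keep]
    yv = y[keep].to_numpy()
    W = np.column_stack(
        [np.ones(keep.sum())] + [c[keep].to_numpy() for c in cols]
    )
    all_names = ["intercept"] + names
    for j in range(1, W.shape[1]):
        if np.ptp(W[:, j]) == 0:
            raise ValueError(f"covariate {all_names[j]!r} is constant after exclusions")
    if np.linalg.matrix_rank(W) < W.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(W, mode="economic", pivoting=True)
        rank = np.linalg.matrix_rank(W)
        bad = sorted(all_names[p] for p in piv[rank:])
        raise ValueError(f"collinear covariates: {bad}")

    if transform in ("inverse-normal", "int"):
        yv = inverse_normal_transform(yv)
        tlog.append("inverse-normal transform applied to trait")
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform {transform!r}")

    return PhenotypeFrame(
        sample_ids=table["sample_id"].tolist(),
        y=yv,
        W=W,
        covariate_names=all_names,
        transform_log=tlog,
        phenotype_name=phenotype,
    )


def residualize(y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """OLS residuals y - W (W'W)^-1 W'y; orthogonal to every column of W."""
    y = np.asarray(y, float)
    W = np.asarray(W, float)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariate matrix W is rank deficient")
    coef, *_ = np.linalg.lstsq(W, y, rcond=None)
    return y - W @ coef


def inverse_normal_transform(values: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse-normal (quantile) transform.

    z_i = Phi^-1((r_i - offset) / (n + 1 - 2*offset)) with average ranks for
    ties; the default offset 0.375 is the Blom convention, giving denominator
    n + 0.25.  Missing values pass through as NaN.  Strictly monotone in the
    input over distinct values.
    """
    values = np.asarray(values, float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    v = values[mask]
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(v) == 0:
        raise ValueError("all values identical; ranks are undefined for inference")
    ranks = stats.rankdata(v, method="average")
    out[mask] = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return out


def load_phenotype_config(path) -> dict:
    """Per-phenotype recipe file (YAML or JSON):
    ``{phenotype: {transform, covariates, exclusions}}``."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError("phenotype config must map phenotype -> recipe")
    return cfg
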