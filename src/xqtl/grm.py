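"""Genomic relationship matrices from SNP dosages.

For a SNP subset of size m with ALT frequencies p_i estimated from the
analyzed cohort itself, the relationship between individuals j and k is

    G_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

i.e. the VanRaden estimator applied uniformly to diagonals and
off-diagonals.  Using the same estimator on the diagonal keeps G = W W'/m
positive semi-definite by construction (the alternative diagonal estimator
some tools use differs by O(1/m) and can break PSD-ness).

Because the analyzed cohorts are all-female, X-linked SNPs need no dosage
compensation treatment and are standardized exactly like autosomal ones.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes_io import DosageMatrix

__all__ = ["GRMatrix", "compute_grm", "write_grm", "read_grm"]


@dataclass
class GRMatrix:
    sample_ids: list[str]
    values: np.ndarray
    n_snps: int
    snp_set_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape inconsistent with sample list")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids: Sequence[str]) -> "GRMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in ids])
        return GRMatrix(
            sample_ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            n_snps=self.n_snps,
            snp_set_label=self.snp_set_label,
        )


def compute_grm(
    dm: DosageMatrix,
    subset: Sequence[str] | Sequence[int] | np.ndarray | None = None,
    chroms: Sequence[str] | None = None,
    exclude_chroms: Sequence[str] | None = None,
    label: str = "",
) -> GRMatrix:
    """Build a GRM over a SNP subset (ids, indices, a boolean mask, or chroms).

    ``exclude_chroms`` supports leave-one-chromosome-out construction.
    All subset SNPs must be polymorphic in the cohort; a monomorphic SNP is
    a hard error (its standardization would divide by zero) — filtering
    belongs to upstream QC, not here.
    """
    if sum(x is not None for x in (subset, chroms, exclude_chroms)) > 1:
        raise ValueError("give at most one of subset, chroms, exclude_chroms")
    if chroms is not None:
        idx = np.flatnonzero(np.isin(dm.chroms(), list(chroms)))
    elif exclude_chroms is not None:
        idx = np.flatnonzero(~np.isin(dm.chroms(), list(exclude_chroms)))
    elif subset is None:
        idx = np.arange(dm.n_variants)
    else:
        arr = np.asarray(subset)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        elif np.issubdtype(arr.dtype, np.integer):
            idx = arr
        else:  # variant ids
            lookup = {v: i for i, v in enumerate(dm.variant_ids())}
            missing = [v for v in arr if v not in lookup]
            if missing:
                raise KeyError(f"variant ids not in DosageMatrix: {missing[:5]}")
            idx = np.array([lookup[v] for v in arr])
    if idx.size == 0:
        raise ValueError("empty SNP subset")

    x = dm.dosages[:, idx]
    p = x.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = [dm.variants[idx[j]].id for j in np.flatnonzero(mono)[:5]]
        raise ValueError(f"monomorphic SNP(s) in GRM subset: {bad}")
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = idx.size
    g = (w @ w.T) / m
    g = 0.5 * (g + g.T)  # remove float asymmetry
    return GRMatrix(
        sample_ids=list(dm.samples), values=g, n_snps=int(m), snp_set_label=label
    )


def write_grm(grm: GRMatrix, prefix: str | os.PathLike) -> None:
    """Text GRM: '<prefix>.grm.ids' + lower-triangle '<prefix>.grm.tsv'."""
    prefix = str(prefix)
    with open(prefix + ".grm.ids", "w") as fh:
        for s in grm.sample_ids:
            fh.write(s + "\n")
    with open(prefix + ".grm.tsv", "w") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t{grm.values[i, j]:.17g}\n")


def read_grm(prefix: str | os.PathLike, label: str = "") -> GRMatrix:
    prefix = str(prefix)
    with open(prefix + ".grm.ids") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    n = len(ids)
    values = np.zeros((n, n))
    n_snps = 1
    with open(prefix + ".grm.tsv") as fh:
        for line in fh:
            i, j, m, v = line.split("\t")
            i, j = int(i) - 1, int(j) - 1
            n_snps = int(m)
            values[i, j] = values[j, i] = float(v)
    return GRMatrix(sample_ids=ids, values=values, n_snps=n_snps, snp_set_label=label)
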