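"""Mixed-linear-model association scan on allele dosages.

Per variant the model is

    y = 1 mu + x b + g_A + e,     g_A ~ N(0, G_A sigma2_A),

with the polygenic term controlled through an *autosomal* GRM — scanning
the X chromosome with an autosomal GRM is leave-one-chromosome-out by
construction.  Variance components are estimated once under the no-marker
null and then held fixed for every variant (the EMMAX approximation):
after rotating into the GRM eigenbasis the covariance is diagonal and each
variant costs a weighted two-parameter least squares.  p-values are
two-sided standard normal on the Wald ratio b / se, appropriate for the
cohort sizes this model targets (thousands); small-n test oracles must use
the same reference distribution.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import neglog10p_two_sided, p_two_sided
from .genotypes_io import DosageMatrix, PhenotypeTable
from .grm import GRMatrix
from .reml import SingleComponentFit, fit_reml_single_component

__all__ = ["AssocStat", "ScanResult", "run_scan", "write_scan", "read_scan"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssocStat:
    """Per-variant association record (the unit of scans and meta-analyses)."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    freq: float
    b: float
    se: float
    p: float
    neglog10p: float
    n: int


@dataclass
class ScanResult:
    trait: str
    population: str
    table: pd.DataFrame  # one row per analyzed variant, sorted by (chrom, pos)
    null_components: dict  # {"sigma2_a": ..., "sigma2_e": ...}

    def stat(self, variant_id: str) -> AssocStat:
        row = self.table.loc[self.table["id"] == variant_id]
        if row.empty:
            raise KeyError(f"variant {variant_id!r} not in scan")
        return _row_to_stat(row.iloc[0])


def _row_to_stat(row: pd.Series) -> AssocStat:
    return AssocStat(
        id=str(row["id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        effect_allele=str(row["effect_allele"]),
        freq=float(row["freq"]),
        b=float(row["b"]),
        se=float(row["se"]),
        p=float(row["p"]),
        neglog10p=float(row["neglog10p"]),
        n=int(row["n"]),
    )


def run_scan(
    dm: DosageMatrix,
    y: PhenotypeTable | np.ndarray,
    G_A: GRMatrix,
    trait: str = "YD",
    population: str = "",
    null_fit: SingleComponentFit | None = None,
) -> ScanResult:
    """Scan every variant in `dm` against one trait.

    `y` may be a PhenotypeTable (samples are intersected with the genotyped
    cohort, silently but with a logged count) or an array already aligned
    to `dm.samples`.  `null_fit` lets callers reuse a fitted null model
    (e.g. across several variant subsets of the same cohort).
    """
    if isinstance(y, PhenotypeTable):
        pheno_samples = set(y.samples(trait))
        keep = [i for i, s in enumerate(dm.samples) if s in pheno_samples]
        if len(keep) < dm.n_samples:
            logger.info(
                "scan %s/%s: intersecting %d genotyped with %d phenotyped -> %d",
                population, trait, dm.n_samples, len(pheno_samples), len(keep),
            )
        if len(keep) < dm.n_samples:
            dm = dm.subset_samples(np.array(keep))
        yvec = y.vector(trait, dm.samples)
    else:
        yvec = np.asarray(y, dtype=float)
        if yvec.size != dm.n_samples:
            raise ValueError("phenotype vector length differs from cohort size")
    if G_A.sample_ids != dm.samples:
        G_A = G_A.subset(dm.samples)

    if null_fit is None:
        null_fit = fit_reml_single_component(yvec, G_A)
    n = dm.n_samples
    d = null_fit.sigma2_g * null_fit.eigvals + null_fit.sigma2_e
    w = 1.0 / d
    ut = null_fit.eigvecs.T
    ys = ut @ yvec
    ones = ut @ np.ones(n)

    x = dm.dosages
    var_x = x.var(axis=0)
    usable = var_x > 0.0
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning(
            "scan %s/%s: skipping %d variant(s) with zero dosage variance",
            population, trait, n_skipped,
        )
    xs = ut @ x[:, usable]

    s11 = float((w * ones**2).sum())
    s1y = float((w * ones * ys).sum())
    s1x = (w * ones) @ xs
    sxx = w @ xs**2
    sxy = (w * ys) @ xs
    det = s11 * sxx - s1x**2
    b = (s11 * sxy - s1x * s1y) / det
    se = np.sqrt(s11 / det)
    z = b / se

    vt = dm.variant_table().loc[usable].reset_index(drop=True)
    table = pd.DataFrame(
        {
            "id": vt["id"],
            "chrom": vt["chrom"],
            "pos": vt["pos"],
            "effect_allele": vt["alt"],
            "other_allele": vt["ref"],
            "freq": dm.alt_freq()[usable],
            "b": b,
            "se": se,
            "p": p_two_sided(z),
            "neglog10p": neglog10p_two_sided(z),
            "n": n,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return ScanResult(
        trait=trait,
        population=population,
        table=table,
        null_components={
            "sigma2_a": float(null_fit.sigma2_g),
            "sigma2_e": float(null_fit.sigma2_e),
        },
    )


_SUMMARY_COLS = ["chr", "snp", "bp", "a1", "a2", "freq", "b", "se", "p", "n"]


def write_scan(scan: ScanResult, path: str | os.PathLike) -> None:
    """Summary-statistic TSV (column layout shared with GCTA .mlma output)."""
    t = scan.table
    out = pd.DataFrame(
        {
            "chr": t["chrom"],
            "snp": t["id"],
            "bp": t["pos"],
            "a1": t["effect_allele"],
            "a2": t["other_allele"],
            "freq": t["freq"],
            "b": t["b"],
            "se": t["se"],
            "p": t["p"],
            "n": t["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(
    path: str | os.PathLike, trait: str = "", population: str = ""
) -> ScanResult:
    raw = pd.read_csv(path, sep="\t", dtype={"chr": str, "snp": str})
    missing = set(_SUMMARY_COLS) - set(raw.columns)
    if missing:
        raise ValueError(f"summary-stat file {path} lacks columns {sorted(missing)}")
    z = raw["b"] / raw["se"]
    table = pd.DataFrame(
        {
            "id": raw["snp"],
            "chrom": raw["chr"],
            "pos": raw["bp"].astype(int),
            "effect_allele": raw["a1"],
            "other_allele": raw["a2"],
            "freq": raw["freq"],
            "b": raw["b"],
            "se": raw["se"],
            "p": raw["p"],
            "neglog10p": neglog10p_two_sided(z.to_numpy()),
            "n": raw["n"].astype(int),
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return ScanResult(trait=trait, population=population, table=table, null_components={})
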