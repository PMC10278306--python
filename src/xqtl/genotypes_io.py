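"""Dosage, variant and phenotype I/O, plus variant-level quality control.

Genotypes are carried as ALT-allele dosages in [0, 2] (imputed expected
allele counts).  The in-memory container, :class:`DosageMatrix`, is the
substrate for relationship matrices, association scans and LD computation.
Coordinates are 1-based (VCF convention) and the tested/effect allele is
ALT throughout.

Two file dialects are supported:

* a plain dosage TSV (``sample_id`` + one column per variant) with a
  ``<stem>.variants.tsv`` sidecar holding variant metadata, and
* VCF 4.2 with a per-genotype ``DS`` field (``GT`` fallback, converted to
  hard 0/1/2 counts), read through cyvcf2.

Missing dosages are a hard error everywhere: the analysis cohorts this
package models are fully imputed, so silent imputation here would mask
upstream problems.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "DosageMatrix",
    "PhenotypeTable",
    "QCThresholds",
    "QCReport",
    "read_dosages",
    "write_dosages",
    "read_phenotypes",
    "write_phenotypes",
    "apply_variant_qc",
    "hwe_pvalues",
]


@dataclass(frozen=True)
class VariantRecord:
    """Metadata for one variant: position, alleles, MAF and imputation quality."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float
    imputation_r2: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")
        if self.imputation_r2 is not None and not (
            0.0 <= self.imputation_r2 <= 1.0
        ):
            raise ValueError(
                f"variant {self.id}: imputation_r2 {self.imputation_r2} outside [0,1]"
            )


def _fold(p: np.ndarray) -> np.ndarray:
    return np.minimum(p, 1.0 - p)


@dataclass
class DosageMatrix:
    """Samples x variants ALT-dosage matrix with aligned metadata.

    ``sample_info`` is an optional frame indexed like ``samples`` for
    auxiliary per-sample columns (population label, sire id, ...); it is
    carried through subsetting but never interpreted by core algorithms.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray
    sex: np.ndarray | None = None  # per-sample code, 'F' in analysis cohorts
    sample_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if np.isnan(self.dosages).any():
            raise ValueError("missing dosages are not supported")
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2.0 + 1e-9
        ):
            raise ValueError("dosage outside [0, 2]")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(
                f"duplicate variant id(s): {list(dup[dup > 1].index[:5])}"
            )
        if self.sex is None:
            self.sex = np.full(len(self.samples), "F")
        # metadata MAF must agree with the data (folded, 1e-6)
        if self.n_variants:
            meta = np.array([v.maf for v in self.variants])
            data = self.maf()
            bad = np.abs(meta - data) > 1e-6
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"variant {ids[j]}: metadata maf {meta[j]:.6g} does not match "
                    f"maf recomputed from dosages {data[j]:.6g}"
                )

    # -- shape ------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # -- derived arrays ---------------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """ALT allele frequency per variant (mean dosage / 2)."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        return _fold(self.alt_freq())

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.variant_ids(),
                "chrom": self.chroms(),
                "pos": self.positions(),
                "ref": [v.ref_allele for v in self.variants],
                "alt": [v.alt_allele for v in self.variants],
                "maf": [v.maf for v in self.variants],
                "imputation_r2": [
                    np.nan if v.imputation_r2 is None else v.imputation_r2
                    for v in self.variants
                ],
            }
        )

    # -- subsetting -------------------------------------------------------
    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "DosageMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return DosageMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in index],
            dosages=self.dosages[:, index],
            sex=None if self.sex is None else self.sex.copy(),
            sample_info=None if self.sample_info is None else self.sample_info.copy(),
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "DosageMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        sub = self.dosages[index, :]
        # allele frequencies shift with the sample subset: refresh metadata MAF
        maf = _fold(sub.mean(axis=0) / 2.0) if len(index) else np.array([])
        variants = [replace(v, maf=float(maf[j])) for j, v in enumerate(self.variants)]
        return DosageMatrix(
            samples=[self.samples[i] for i in index],
            variants=variants,
            dosages=sub,
            sex=None if self.sex is None else self.sex[index],
            sample_info=None
            if self.sample_info is None
            else self.sample_info.iloc[index],
        )

    def select_chrom(self, chrom: str) -> "DosageMatrix":
        return self.subset_variants(self.chroms() == chrom)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in DosageMatrix") from None


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Long-format phenotype store: one yield deviation per (sample, trait)."""

    table: pd.DataFrame  # columns: sample_id, trait, value

    def __post_init__(self) -> None:
        required = {"sample_id", "trait", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"phenotype table must have columns {sorted(required)}")
        if self.table.duplicated(subset=["sample_id", "trait"]).any():
            raise ValueError("more than one value per (sample, trait)")
        if self.table["value"].isna().any():
            raise ValueError("missing phenotype values are not supported")

    def traits(self) -> list[str]:
        return sorted(self.table["trait"].unique())

    def samples(self, trait: str | None = None) -> list[str]:
        t = self.table
        if trait is not None:
            t = t[t["trait"] == trait]
        return list(t["sample_id"].unique())

    def vector(self, trait: str, sample_order: Sequence[str]) -> np.ndarray:
        """Phenotype values for `trait`, aligned to `sample_order`."""
        sub = self.table[self.table["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not in phenotype table")
        m = dict(zip(sub["sample_id"], sub["value"]))
        try:
            return np.array([m[s] for s in sample_order], dtype=float)
        except KeyError as e:
            raise KeyError(
                f"sample {e.args[0]!r} has no phenotype for trait {trait!r}"
            ) from None


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_phenotypes(pheno: PhenotypeTable, path: str | os.PathLike) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dosage I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: str) -> str:
    stem, ext = os.path.splitext(str(path))
    return (stem if ext == ".tsv" else str(path)) + ".variants.tsv"


def read_dosages(path: str | os.PathLike, format: str = "tsv") -> DosageMatrix:
    """Read a dosage matrix from TSV (with sidecar) or VCF (DS field).

    MAF is recomputed from the dosages whenever the metadata leaves it
    blank; a metadata MAF inconsistent with the data is an error.
    """
    if format == "tsv":
        return _read_tsv(str(path))
    if format == "vcf":
        return _read_vcf(str(path))
    raise ValueError(f"unknown dosage format {format!r} (expected 'tsv' or 'vcf')")


def _read_tsv(path: str) -> DosageMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)][0]
        raise ValueError(f"missing dosage in row for sample {bad!r} of {path}")
    meta = pd.read_csv(
        _sidecar_path(path), sep="\t", dtype={"id": str, "chrom": str},
        float_precision="round_trip",
    )
    if list(meta["id"]) != list(frame.columns):
        raise ValueError(
            f"variant ids in {path} do not match sidecar {_sidecar_path(path)}"
        )
    dosages = frame.to_numpy(dtype=float)
    if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
        raise ValueError(f"dosage outside [0,2] in {path}")
    data_maf = _fold(dosages.mean(axis=0) / 2.0)
    variants = []
    for j, row in enumerate(meta.itertuples(index=False)):
        maf = row.maf
        if maf is None or (isinstance(maf, float) and math.isnan(maf)):
            maf = float(data_maf[j])
        r2 = row.imputation_r2
        if isinstance(r2, float) and math.isnan(r2):
            r2 = None
        variants.append(
            VariantRecord(
                id=str(row.id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                maf=float(maf),
                imputation_r2=r2,
            )
        )
    return DosageMatrix(
        samples=[str(s) for s in frame.index], variants=variants, dosages=dosages
    )


def write_dosages(dm: DosageMatrix, path: str | os.PathLike, format: str = "tsv") -> None:
    if format == "tsv":
        _write_tsv(dm, str(path))
    elif format == "vcf":
        _write_vcf(dm, str(path))
    else:
        raise ValueError(f"unknown dosage format {format!r}")


def _write_tsv(dm: DosageMatrix, path: str) -> None:
    frame = pd.DataFrame(dm.dosages, index=dm.samples, columns=dm.variant_ids())
    frame.index.name = "sample_id"
    # default float formatting is the shortest round-trip repr: exact I/O
    frame.to_csv(path, sep="\t")
    dm.variant_table().to_csv(_sidecar_path(path), sep="\t", index=False)


def _read_vcf(path: str) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        try:
            ds = v.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # GT fallback: cyvcf2 gt_types -> 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = v.gt_types
            if (gt == 2).any():
                raise ValueError(
                    f"missing genotype at {v.CHROM}:{v.POS}; "
                    "missingness is not supported"
                )
            col = np.where(gt == 3, 2.0, gt.astype(float))
        if np.isnan(col).any():
            raise ValueError(f"missing dosage at {v.CHROM}:{v.POS}")
        if col.min() < 0 or col.max() > 2:
            raise ValueError(f"dosage outside [0,2] at {v.CHROM}:{v.POS}")
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}_{v.REF}_{v.ALT[0]}"
        r2 = v.INFO.get("R2")
        maf = float(_fold(np.array([col.mean() / 2.0]))[0])
        variants.append(
            VariantRecord(
                id=vid,
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref_allele=str(v.REF),
                alt_allele=str(v.ALT[0]) if v.ALT else ".",
                maf=maf,
                imputation_r2=None if r2 is None else float(r2),
            )
        )
        columns.append(col)
    ids = [rec.id for rec in variants]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant id in VCF")
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return DosageMatrix(samples=samples, variants=variants, dosages=dosages)


def _write_vcf(dm: DosageMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R2">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT allele dosage">\n'
        )
        for chrom in dict.fromkeys(v.chrom for v in dm.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dm.samples)
            + "\n"
        )
        order = np.lexsort((dm.positions(), dm.chroms()))
        for j in order:
            v = dm.variants[j]
            info = "." if v.imputation_r2 is None else f"R2={v.imputation_r2:.6g}"
            ds = "\t".join(f"{d:.6g}" for d in dm.dosages[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t{info}\tDS\t{ds}\n"
            )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCThresholds:
    """Variant QC thresholds for the two filtering stages.

    ``chip_qc`` mimics array-level QC (MAF > chip_min_maf, Hardy-Weinberg
    chi-square p > hwe_p_floor on hard-called genotypes); ``sequence_filter``
    is the imputed-sequence filter (MAF >= min_maf, imputation R² >= min_r2).
    """

    min_maf: float = 0.005
    min_imputation_r2: float = 0.20
    chip_min_maf: float = 0.01
    hwe_p_floor: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_imputation_r2", "chip_min_maf", "hwe_p_floor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QCReport:
    stage: str
    n_input: int
    n_pass: int
    removed_by: dict[str, int] = field(default_factory=dict)


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg chi-square (1 df) p-values on hard-called genotypes.

    Dosages are rounded to the nearest genotype class; this is only
    meaningful for array-quality calls, which is why it is confined to the
    chip QC stage.
    """
    g = np.clip(np.rint(dosages), 0, 2).astype(int)
    n = g.shape[0]
    n2 = (g == 2).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    p = (2 * n2 + n1) / (2.0 * n)
    exp = np.stack(
        [n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2], axis=0
    )
    obs = np.stack([(g == 0).sum(axis=0), n1, n2], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    # monomorphic columns carry no HWE information
    chi2 = np.where((p <= 0) | (p >= 1), 0.0, chi2)
    return stats.chi2.sf(chi2, df=1)


def apply_variant_qc(
    dm: DosageMatrix, thresholds: QCThresholds, stage: str
) -> tuple[DosageMatrix, QCReport]:
    """Filter variants for one QC stage, preserving order.

    Returns the surviving matrix plus a report counting removals per
    criterion (a variant failing several criteria is counted under each).
    """
    maf = np.array([v.maf for v in dm.variants])
    if stage == "chip_qc":
        fail_maf = maf <= thresholds.chip_min_maf
        hwe_p = hwe_pvalues(dm.dosages) if dm.n_variants else np.array([])
        fail_hwe = hwe_p <= thresholds.hwe_p_floor
        keep = ~(fail_maf | fail_hwe)
        removed = {"maf": int(fail_maf.sum()), "hwe": int(fail_hwe.sum())}
    elif stage == "sequence_filter":
        fail_maf = maf < thresholds.min_maf
        r2 = np.array(
            [
                np.nan if v.imputation_r2 is None else v.imputation_r2
                for v in dm.variants
            ]
        )
        # a variant with no quality score cannot pass a quality filter
        fail_r2 = ~(r2 >= thresholds.min_imputation_r2)
        keep = ~(fail_maf | fail_r2)
        removed = {"maf": int(fail_maf.sum()), "imputation_r2": int(fail_r2.sum())}
    else:
        raise ValueError(
            f"unknown QC stage {stage!r} (expected 'chip_qc' or 'sequence_filter')"
        )
    out = dm.subset_variants(np.flatnonzero(keep)) if dm.n_variants else dm
    return out, QCReport(
        stage=stage, n_input=dm.n_variants, n_pass=int(keep.sum()) if dm.n_variants else 0,
        removed_by=removed,
    )
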