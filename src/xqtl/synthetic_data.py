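"""Synthetic multi-population all-female cohorts with autosomal and X genotypes.

The generator emulates the data structure of a dairy-cattle genomic
evaluation cohort: several populations (breeds) of females genotyped on one
representative autosome (labelled "2") and the non-pseudoautosomal X
(labelled "X"), with linkage disequilibrium, a polygenic architecture split
between autosomes and X, and optional planted major QTL.

LD model
--------
Haplotypes are two-level founder mosaics.  A small *ancestral* pool (shared
by all populations) carries independent alleles at frequencies drawn per
variant; each population's *founder* pool is a set of mosaics over the
ancestral pool, and every sampled haplotype is a mosaic over its
population's founders, switching template between adjacent variants with
probability ``1 - exp(-rate * gap_bp)``.  The switch rate plays the role
of an *effective* ancestral per-bp recombination rate (per-meiosis rate
times the number of generations back to the founders).  The small
ancestral pool gives realistic short-range r² (of order 1 / pool size);
the mosaic scales set the decay with distance; populations are distinct
but related, as breeds drawn from one ancestral species should be.

The X chromosome is special-cased to mirror its transmission in mammals:

* X mosaics are built with a switch rate of 2/3 of the autosomal/female
  rate, because the X recombines only in females (two of the three X
  copies in a sire-dam pair pass through a female meiosis);
* every daughter receives one maternal X (a fresh recombined mosaic) and
  one paternal X copied *intact* from her sire's single X, and each sire
  transmits that same X to all of his daughters.

Both effects raise X-chromosome LD above autosomal LD at matched distance,
the qualitative signature this generator must reproduce.

Genetic architecture
--------------------
Every variant is causal.  Effects on the standardized dosage scale
w = (x - 2p) / sqrt(2 p (1-p)) are drawn i.i.d. N(0, h2/m) per chromosome
set, so the expected variance explained equals the target and, crucially,
the implied covariance of genetic values is exactly h2 times the
VanRaden-style relationship matrix built from the same variants — the REML
model is then correctly specified and recovery tests are unbiased.
Planted major QTL are added on top (effect stated in phenotypic SD units on
the standardized dosage) and counted inside the realized autosomal or
X-linked variance.  Residuals are Gaussian with variance
1 - target_h2_aut - target_h2_x, so the phenotype ("yield deviation") has
unit variance in expectation.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes_io import DosageMatrix, PhenotypeTable, VariantRecord

__all__ = ["SimConfig", "SimTruth", "simulate_population", "table2_fixture"]


@dataclass
class SimConfig:
    """Study-design knobs for one simulated cohort.

    Defaults describe a desk-scale version of a dairy-cattle evaluation:
    one population of 1000 cows, ~1000 autosomal and ~400 X variants on
    130-Mbp chromosomes, a 0.30/0.02 autosomal/X heritability split, and
    sires with ~40 daughters each.
    """

    n_populations: int = 1
    n_females_per_pop: int = 1000
    n_founder_haplotypes: int = 60
    n_autosomal_variants: int = 1000
    n_x_variants: int = 400
    chrom_length_bp: int = 130_000_000
    target_h2_aut: float = 0.30
    target_h2_x: float = 0.02
    planted_qtl: list[tuple[str, int, float]] = field(default_factory=list)
    recomb_rate_female: float = 1.2e-6  # effective ancestral switch rate per bp
    seed: int = 0
    n_ancestral_haplotypes: int = 6  # sets the short-range r2 plateau (~1/K)
    n_sires_per_pop: int | None = None  # default: ~40 daughters per sire
    trait_name: str = "YD"

    def __post_init__(self) -> None:
        if self.target_h2_aut < 0 or self.target_h2_x < 0:
            raise ValueError("heritability targets must be non-negative")
        if self.target_h2_aut + self.target_h2_x >= 1.0:
            raise ValueError(
                "target_h2_aut + target_h2_x must be < 1 "
                f"(got {self.target_h2_aut + self.target_h2_x})"
            )
        for name in (
            "n_populations",
            "n_females_per_pop",
            "n_founder_haplotypes",
            "n_autosomal_variants",
            "n_x_variants",
            "chrom_length_bp",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for chrom, pos, _ in self.planted_qtl:
            if chrom not in ("2", "X"):
                raise ValueError(f"planted QTL chromosome must be '2' or 'X', got {chrom!r}")
            if not (1 <= pos <= self.chrom_length_bp):
                raise ValueError(f"planted QTL position {pos} outside chromosome")

    @property
    def sires_per_pop(self) -> int:
        if self.n_sires_per_pop is not None:
            return self.n_sires_per_pop
        return max(2, self.n_females_per_pop // 40)


@dataclass
class SimTruth:
    """Ground truth emitted next to a simulated cohort."""

    beta_dosage: np.ndarray  # per-variant true effect per ALT dose, dm order
    sigma2_a: float  # realized autosomal genetic variance (incl. planted QTL)
    sigma2_x: float
    sigma2_e: float
    h2_aut_realized: float
    h2_x_realized: float
    planted_qtl: list[tuple[str, int, float]]
    populations: np.ndarray  # per-sample population label

    def to_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_x": self.sigma2_x,
            "sigma2_e": self.sigma2_e,
            "h2_aut_realized": self.h2_aut_realized,
            "h2_x_realized": self.h2_x_realized,
            "planted_qtl": [list(q) for q in self.planted_qtl],
            "beta_dosage": self.beta_dosage.tolist(),
        }


def _positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted 1-based positions; rejection-samples collisions."""
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=2 * (n - pos.size) + 8)
        pos = np.unique(np.concatenate([pos, extra]))
    if pos.size > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos.astype(np.int64)


def _mosaic(
    rng: np.random.Generator,
    founders: np.ndarray,  # (K, m) 0/1 alleles
    positions: np.ndarray,
    rate: float,
    n_hap: int,
) -> np.ndarray:
    """Sample `n_hap` mosaic haplotypes from a founder pool."""
    K, m = founders.shape
    gaps = np.diff(positions, prepend=positions[0])
    p_sw = 1.0 - np.exp(-rate * gaps)
    p_sw[0] = 1.0  # always draw an initial founder
    sw = rng.random((n_hap, m)) < p_sw
    cols = np.broadcast_to(np.arange(m), (n_hap, m))
    last_sw = np.maximum.accumulate(np.where(sw, cols, 0), axis=1)
    fid = rng.integers(0, K, size=(n_hap, m))
    chosen = fid[np.arange(n_hap)[:, None], last_sw]
    return founders[chosen, cols]


def _ancestral_pool(
    rng: np.random.Generator, freqs: np.ndarray, k: int, forced: np.ndarray
) -> np.ndarray:
    """Draw K ancestral haplotypes with independent alleles at `freqs`.

    `forced` marks columns (planted QTL) that must stay polymorphic.
    """
    pool = (rng.random((k, freqs.size)) < freqs).astype(np.int8)
    for j in np.flatnonzero(forced):
        tries = 0
        while pool[:, j].min() == pool[:, j].max():
            pool[:, j] = rng.random(k) < freqs[j]
            tries += 1
            if tries > 100:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not keep planted QTL polymorphic")
    return pool


def _founder_pool(
    rng: np.random.Generator,
    ancestral: np.ndarray,
    positions: np.ndarray,
    rate: float,
    k: int,
    forced: np.ndarray,
) -> np.ndarray:
    """One population's founders: mosaics over the ancestral pool.

    Founder-level segments are longer than within-population ones (half
    the switch rate), and forced (planted-QTL) columns are re-seeded from
    the ancestral alleles until polymorphic among the founders.
    """
    pool = _mosaic(rng, ancestral, positions, 0.5 * rate, k)
    k0 = ancestral.shape[0]
    for j in np.flatnonzero(forced):
        tries = 0
        while pool[:, j].min() == pool[:, j].max():
            pool[:, j] = ancestral[rng.integers(0, k0, size=k), j]
            tries += 1
            if tries > 100:  # pragma: no cover
                raise RuntimeError("could not keep planted QTL polymorphic")
    return pool


def simulate_population(
    cfg: SimConfig,
) -> tuple[DosageMatrix, PhenotypeTable, SimTruth]:
    """Generate a cohort: genotypes, one phenotype, and ground truth.

    Deterministic given ``cfg.seed``: all randomness flows through a single
    PCG64 generator.
    """
    rng = np.random.default_rng(cfg.seed)

    # -- variant maps (shared across populations) -------------------------
    pos_a = _positions(rng, cfg.n_autosomal_variants, cfg.chrom_length_bp)
    pos_x = _positions(rng, cfg.n_x_variants, cfg.chrom_length_bp)
    # plant QTL positions exactly: replace the nearest simulated variant
    forced_a = np.zeros(pos_a.size, dtype=bool)
    forced_x = np.zeros(pos_x.size, dtype=bool)
    for chrom, qpos, _ in cfg.planted_qtl:
        pos, forced = (pos_a, forced_a) if chrom == "2" else (pos_x, forced_x)
        j = int(np.argmin(np.abs(pos - qpos)))
        pos[j] = qpos
        forced[j] = True
    pos_a = np.sort(pos_a)
    pos_x = np.sort(pos_x)
    # (forced flags follow positions only through the QTL lookup below)
    forced_a = np.isin(pos_a, [q[1] for q in cfg.planted_qtl if q[0] == "2"])
    forced_x = np.isin(pos_x, [q[1] for q in cfg.planted_qtl if q[0] == "X"])

    freq_a = rng.uniform(0.05, 0.95, size=pos_a.size)
    freq_x = rng.uniform(0.05, 0.95, size=pos_x.size)
    # keep planted QTL at workable frequencies
    freq_a[forced_a] = rng.uniform(0.25, 0.75, size=int(forced_a.sum()))
    freq_x[forced_x] = rng.uniform(0.25, 0.75, size=int(forced_x.sum()))

    rate_a = cfg.recomb_rate_female
    rate_x = (2.0 / 3.0) * cfg.recomb_rate_female  # X recombines only in females

    anc_a = _ancestral_pool(rng, freq_a, cfg.n_ancestral_haplotypes, forced_a)
    anc_x = _ancestral_pool(rng, freq_x, cfg.n_ancestral_haplotypes, forced_x)

    n = cfg.n_females_per_pop
    pops: list[str] = []
    sires: list[str] = []
    dos_a_blocks, dos_x_blocks = [], []
    for p in range(cfg.n_populations):
        label = f"POP{p + 1}"
        fa = _founder_pool(
            rng, anc_a, pos_a, rate_a, cfg.n_founder_haplotypes, forced_a
        )
        fx = _founder_pool(
            rng, anc_x, pos_x, rate_x, cfg.n_founder_haplotypes, forced_x
        )
        # autosome: two recombined mosaics per cow
        hap1 = _mosaic(rng, fa, pos_a, rate_a, n)
        hap2 = _mosaic(rng, fa, pos_a, rate_a, n)
        dos_a_blocks.append((hap1 + hap2).astype(float))
        # X: maternal mosaic + paternal copy of the sire's single X
        mat = _mosaic(rng, fx, pos_x, rate_x, n)
        sire_x = _mosaic(rng, fx, pos_x, rate_x, cfg.sires_per_pop)
        sire_of = rng.integers(0, cfg.sires_per_pop, size=n)
        dos_x_blocks.append((mat + sire_x[sire_of]).astype(float))
        pops.extend([label] * n)
        sires.extend(f"{label}_S{j + 1:03d}" for j in sire_of)

    dos_a = np.vstack(dos_a_blocks)
    dos_x = np.vstack(dos_x_blocks)
    n_total = dos_a.shape[0]

    # -- drop variants monomorphic in the pooled cohort -------------------
    def _poly(d: np.ndarray, forced: np.ndarray, chrom: str) -> np.ndarray:
        f = d.mean(axis=0) / 2.0
        keep = (f > 0.0) & (f < 1.0)
        if (~keep & forced).any():
            raise RuntimeError(f"planted QTL on {chrom} became monomorphic")
        return keep

    keep_a = _poly(dos_a, forced_a, "2")
    keep_x = _poly(dos_x, forced_x, "X")
    dos_a, pos_a, forced_a = dos_a[:, keep_a], pos_a[keep_a], forced_a[keep_a]
    dos_x, pos_x, forced_x = dos_x[:, keep_x], pos_x[keep_x], forced_x[keep_x]

    # -- genetic values ----------------------------------------------------
    def _standardize(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p_hat = d.mean(axis=0) / 2.0
        scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
        return (d - 2.0 * p_hat) / scale, scale

    w_a, scale_a = _standardize(dos_a)
    w_x, scale_x = _standardize(dos_x)
    m_a, m_x = w_a.shape[1], w_x.shape[1]

    beta_std_a = (
        rng.normal(0.0, 1.0, m_a) * np.sqrt(cfg.target_h2_aut / m_a)
        if cfg.target_h2_aut > 0
        else np.zeros(m_a)
    )
    beta_std_x = (
        rng.normal(0.0, 1.0, m_x) * np.sqrt(cfg.target_h2_x / m_x)
        if cfg.target_h2_x > 0
        else np.zeros(m_x)
    )
    for chrom, qpos, eff in cfg.planted_qtl:
        if chrom == "2":
            beta_std_a[np.flatnonzero(pos_a == qpos)[0]] += eff
        else:
            beta_std_x[np.flatnonzero(pos_x == qpos)[0]] += eff

    g_a = w_a @ beta_std_a
    g_x = w_x @ beta_std_x
    sigma_e = np.sqrt(1.0 - cfg.target_h2_aut - cfg.target_h2_x)
    e = rng.normal(0.0, sigma_e, n_total)
    y = g_a + g_x + e

    # -- assemble containers ----------------------------------------------
    samples = [f"{pops[i]}_{i + 1:06d}" for i in range(n_total)]
    r2_a = np.clip(rng.beta(8, 2, m_a), 0.05, 1.0)
    r2_x = np.clip(rng.beta(8, 2, m_x), 0.05, 1.0)

    def _records(
        chrom: str, pos: np.ndarray, d: np.ndarray, r2: np.ndarray
    ) -> list[VariantRecord]:
        f = d.mean(axis=0) / 2.0
        maf = np.minimum(f, 1 - f)
        return [
            VariantRecord(
                id=f"{chrom}:{pos[j]}",
                chrom=chrom,
                pos=int(pos[j]),
                ref_allele="A",
                alt_allele="G",
                maf=float(maf[j]),
                imputation_r2=float(r2[j]),
            )
            for j in range(pos.size)
        ]

    variants = _records("2", pos_a, dos_a, r2_a) + _records("X", pos_x, dos_x, r2_x)
    dm = DosageMatrix(
        samples=samples,
        variants=variants,
        dosages=np.hstack([dos_a, dos_x]),
        sample_info=pd.DataFrame(
            {"population": pops, "sire": sires}, index=samples
        ),
    )
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"sample_id": samples, "trait": cfg.trait_name, "value": y}
        )
    )
    var = lambda v: float(np.var(v, ddof=1))
    vp = var(y)
    truth = SimTruth(
        beta_dosage=np.concatenate([beta_std_a / scale_a, beta_std_x / scale_x]),
        sigma2_a=var(g_a),
        sigma2_x=var(g_x),
        sigma2_e=var(e),
        h2_aut_realized=var(g_a) / vp,
        h2_x_realized=var(g_x) / vp,
        planted_qtl=list(cfg.planted_qtl),
        populations=np.array(pops),
    )
    return dm, pheno, truth


# ---------------------------------------------------------------------------
# published heritability-partition table (dairy cattle, 6 breeds x 11 traits)
# ---------------------------------------------------------------------------

# Values exactly as printed in the source publication's heritability table;
# clinical mastitis (MAST) was not recorded in Vosgienne, hence 65 rows.
_TABLE2_TSV = """\
breed	trait	h2	h2_aut	h2_x
Abondance	MY	0.324	0.315	0.009
Tarentaise	MY	0.354	0.340	0.015
Vosgienne	MY	0.398	0.371	0.027
Montbeliarde	MY	0.345	0.338	0.007
Normande	MY	0.260	0.253	0.007
Holstein	MY	0.340	0.330	0.006
Abondance	PY	0.260	0.251	0.009
Tarentaise	PY	0.316	0.304	0.012
Vosgienne	PY	0.345	0.325	0.020
Montbeliarde	PY	0.285	0.279	0.006
Normande	PY	0.224	0.217	0.007
Holstein	PY	0.256	0.249	0.007
Abondance	FY	0.299	0.289	0.010
Tarentaise	FY	0.384	0.365	0.019
Vosgienne	FY	0.356	0.333	0.023
Montbeliarde	FY	0.324	0.317	0.007
Normande	FY	0.228	0.222	0.006
Holstein	FY	0.306	0.299	0.007
Abondance	PC	0.707	0.678	0.029
Tarentaise	PC	0.728	0.687	0.041
Vosgienne	PC	0.747	0.738	0.009
Montbeliarde	PC	0.652	0.636	0.016
Normande	PC	0.522	0.515	0.007
Holstein	PC	0.660	0.650	0.014
Abondance	FC	0.677	0.668	0.010
Tarentaise	FC	0.719	0.698	0.020
Vosgienne	FC	0.723	0.712	0.011
Montbeliarde	FC	0.630	0.619	0.011
Normande	FC	0.522	0.513	0.009
Holstein	FC	0.660	0.644	0.012
Abondance	SCS	0.223	0.218	0.005
Tarentaise	SCS	0.209	0.185	0.024
Vosgienne	SCS	0.219	0.218	0.001
Montbeliarde	SCS	0.227	0.223	0.004
Normande	SCS	0.180	0.175	0.005
Holstein	SCS	0.240	0.235	0.008
Abondance	MAST	0.024	0.023	0.001
Tarentaise	MAST	0.021	0.021	0.000
Montbeliarde	MAST	0.027	0.027	0.000
Normande	MAST	0.033	0.033	0.000
Holstein	MAST	0.035	0.034	0.001
Abondance	ICFI	0.049	0.048	0.001
Tarentaise	ICFI	0.055	0.054	0.002
Vosgienne	ICFI	0.019	0.008	0.011
Montbeliarde	ICFI	0.080	0.077	0.004
Normande	ICFI	0.070	0.064	0.005
Holstein	ICFI	0.094	0.093	0.002
Abondance	HCR	0.035	0.033	0.002
Tarentaise	HCR	0.023	0.019	0.004
Vosgienne	HCR	0.043	0.043	0.000
Montbeliarde	HCR	0.018	0.016	0.001
Normande	HCR	0.020	0.019	0.000
Holstein	HCR	0.010	0.012	0.000
Abondance	CCR	0.038	0.038	0.000
Tarentaise	CCR	0.051	0.025	0.027
Vosgienne	CCR	0.043	0.043	0.000
Montbeliarde	CCR	0.041	0.041	0.001
Normande	CCR	0.049	0.048	0.001
Holstein	CCR	0.070	0.068	0.001
Abondance	STAT	0.641	0.639	0.002
Tarentaise	STAT	0.704	0.704	0.000
Vosgienne	STAT	0.715	0.706	0.010
Montbeliarde	STAT	0.564	0.554	0.010
Normande	STAT	0.559	0.543	0.015
Holstein	STAT	0.420	0.414	0.008
"""


def table2_fixture() -> pd.DataFrame:
    """The published breed x trait heritability partition (65 rows).

    Columns: breed, trait, h2, h2_aut, h2_x — values as printed in the
    source table (three decimals).
    """
    return pd.read_csv(io.StringIO(_TABLE2_TSV), sep="\t")
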