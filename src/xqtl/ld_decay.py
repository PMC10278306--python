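"""Pairwise r² and distance-binned LD-decay curves.

r² is the squared Pearson correlation of allele dosages within a
chromosome, restricted to pairs closer than a maximum distance, after
excluding low-MAF variants (default MAF < 0.01, whose r² estimates are
dominated by sampling noise).  Binned curves average r² per distance bin,
unweighted; the canonical use is comparing the X chromosome against an
autosome of similar length at matched distances.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .genotypes_io import DosageMatrix

__all__ = ["LDBin", "pairwise_r2", "bin_decay", "default_bin_edges", "one_daughter_per_sire"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDBin:
    distance_lo_bp: int  # half-open bin [lo, hi)
    distance_hi_bp: int
    mean_r2: float  # nan when the bin is empty
    n_pairs: int


def one_daughter_per_sire(dm: DosageMatrix, rng: np.random.Generator) -> DosageMatrix:
    """Keep one random daughter per sire (requires a 'sire' sample-info column).

    When no sire information is present the cohort is returned unchanged,
    with a logged notice — pedigree is optional input.
    """
    if dm.sample_info is None or "sire" not in dm.sample_info.columns:
        logger.info("no sire information: using all %d samples for LD", dm.n_samples)
        return dm
    sires = dm.sample_info["sire"].to_numpy()
    keep = []
    for s in pd_unique(sires):
        members = np.flatnonzero(sires == s)
        keep.append(int(rng.choice(members)))
    return dm.subset_samples(np.sort(np.array(keep)))


def pd_unique(values: np.ndarray) -> np.ndarray:
    # order-preserving unique (np.unique sorts)
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def pairwise_r2(
    dm: DosageMatrix,
    chrom: str,
    max_dist_bp: int,
    min_maf: float = 0.01,
) -> Iterator[tuple[int, int, float]]:
    """Yield (pos_i, pos_j, r²) for intra-chromosome pairs within max_dist_bp."""
    sub = dm.select_chrom(chrom)
    keep = sub.maf() >= min_maf
    # constant columns would make the correlation undefined
    keep &= sub.dosages.var(axis=0) > 0
    sub = sub.subset_variants(keep)
    if sub.n_variants == 0:
        logger.warning("no variants on %s after MAF >= %g filter", chrom, min_maf)
        return
    order = np.argsort(sub.positions(), kind="mergesort")
    sub = sub.subset_variants(order)
    pos = sub.positions()
    corr = np.corrcoef(sub.dosages.T)
    for i in range(sub.n_variants):
        jmax = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
        for j in range(i + 1, jmax):
            yield int(pos[i]), int(pos[j]), float(corr[i, j] ** 2)


def default_bin_edges(max_dist_bp: int, n_log_bins: int = 12) -> np.ndarray:
    """0–10 kb, then log-spaced up to max_dist_bp."""
    if max_dist_bp <= 10_000:
        return np.array([0, max_dist_bp + 1])
    log_edges = np.logspace(4, np.log10(max_dist_bp), n_log_bins + 1)[1:]
    return np.unique(np.concatenate([[0, 10_000], np.round(log_edges)])).astype(np.int64)


def bin_decay(
    pairs: Iterable[tuple[int, int, float]], bin_edges: np.ndarray
) -> list[LDBin]:
    """Unweighted mean r² per half-open distance bin [lo, hi)."""
    edges = np.asarray(bin_edges)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    sums = np.zeros(edges.size - 1)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    for pos_i, pos_j, r2 in pairs:
        d = abs(pos_j - pos_i)
        k = int(np.searchsorted(edges, d, side="right")) - 1
        if 0 <= k < sums.size and d < edges[k + 1]:
            sums[k] += r2
            counts[k] += 1
    out = []
    for k in range(sums.size):
        out.append(
            LDBin(
                distance_lo_bp=int(edges[k]),
                distance_hi_bp=int(edges[k + 1]),
                mean_r2=float(sums[k] / counts[k]) if counts[k] else float("nan"),
                n_pairs=int(counts[k]),
            )
        )
    return out
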