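"""Fixed-effects inverse-variance meta-analysis of association scans.

The default scheme is the classical inverse-variance ("STDERR") estimator:
with per-study effects b_i and standard errors se_i,

    w_i = 1 / se_i**2,
    b_meta = sum(w_i b_i) / sum(w_i),   se_meta = sum(w_i) ** -0.5,
    z = b_meta / se_meta,               p = two-sided normal.

A sample-size-weighted z-score scheme (the other classical flavour) is
available behind ``scheme="samplesize"`` for comparison; it combines only
z-scores and reports no pooled effect size.

Variants are matched across studies by (chrom, pos, allele pair), never by
id string; a study whose REF/ALT is swapped relative to the first study
carrying the variant has its effect sign and frequency flipped, and an
allele pair that cannot be reconciled by flipping drops the variant with a
warning.  Variants present in only a subset of studies are combined over
that subset, with '?' at the missing studies' slots of the direction
string.
"""
from __future__ import annotations

import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import neglog10p_two_sided, p_two_sided
from .assoc import ScanResult

__all__ = ["fixed_effects_meta", "write_meta", "read_meta"]

logger = logging.getLogger(__name__)

_META_COLS = [
    "id", "chrom", "pos", "a1", "a2", "b_meta", "se_meta",
    "z", "p", "neglog10p", "n_studies", "direction", "n",
]


def _as_frame(scan: ScanResult | pd.DataFrame) -> pd.DataFrame:
    t = scan.table if isinstance(scan, ScanResult) else scan
    return t[
        ["id", "chrom", "pos", "effect_allele", "other_allele", "freq", "b", "se", "n"]
    ].copy()


def fixed_effects_meta(
    scans: Sequence[ScanResult | pd.DataFrame], scheme: str = "stderr"
) -> pd.DataFrame:
    """Combine per-variant effects across studies; study order fixes the
    direction-string slots but does not affect the statistics."""
    if not scans:
        raise ValueError("need at least one scan")
    if scheme not in ("stderr", "samplesize"):
        raise ValueError(f"unknown meta scheme {scheme!r}")
    frames = [_as_frame(s) for s in scans]
    k = len(frames)

    # reference allele orientation: first study that carries the variant
    ref: dict[tuple, tuple[str, str, str]] = {}  # key -> (id, a1, a2)
    dropped: set[tuple] = set()
    aligned: list[pd.DataFrame] = []
    for frame in frames:
        rows = []
        for r in frame.itertuples(index=False):
            key = (r.chrom, r.pos, frozenset((r.effect_allele, r.other_allele)))
            if key not in ref:
                ref[key] = (r.id, r.effect_allele, r.other_allele)
            rid, a1, a2 = ref[key]
            if (r.effect_allele, r.other_allele) == (a1, a2):
                b, freq = r.b, r.freq
            elif (r.effect_allele, r.other_allele) == (a2, a1):
                b, freq = -r.b, 1.0 - r.freq
            else:  # same unordered pair but weird case (shouldn't happen)
                dropped.add(key)
                continue
            rows.append((key, rid, r.chrom, r.pos, a1, a2, freq, b, r.se, r.n))
        aligned.append(
            pd.DataFrame(
                rows,
                columns=["key", "id", "chrom", "pos", "a1", "a2", "freq", "b", "se", "n"],
            )
        )
    # alleles clashing beyond a flip: distinct allele-pair keys at one locus
    locus_pairs: dict[tuple, set] = {}
    for key in ref:
        locus_pairs.setdefault(key[:2], set()).add(key[2])
    for locus, pairs in locus_pairs.items():
        if len(pairs) > 1:
            for pair in pairs:
                dropped.add((locus[0], locus[1], pair))
    if dropped:
        logger.warning("meta: dropped %d variant(s) with irreconcilable alleles", len(dropped))

    per_variant: dict[tuple, list] = {}
    for s_idx, frame in enumerate(aligned):
        for r in frame.itertuples(index=False):
            if r.key in dropped:
                continue
            per_variant.setdefault(r.key, []).append((s_idx, r))

    out = []
    for key, entries in per_variant.items():
        rid, a1, a2 = ref[key]
        bs = np.array([e.b for _, e in entries])
        ses = np.array([e.se for _, e in entries])
        ns = np.array([e.n for _, e in entries])
        direction = ["?"] * k
        for s_idx, e in entries:
            direction[s_idx] = "+" if e.b >= 0 else "-"
        if scheme == "stderr":
            w = 1.0 / ses**2
            b_meta = float((w * bs).sum() / w.sum())
            se_meta = float(w.sum() ** -0.5)
            z = b_meta / se_meta
        else:
            zi = bs / ses
            w = np.sqrt(ns.astype(float))
            z = float((w * zi).sum() / np.sqrt((w**2).sum()))
            b_meta = np.nan
            se_meta = np.nan
        out.append(
            (
                rid, key[0], key[1], a1, a2, b_meta, se_meta, z,
                float(p_two_sided(z)), float(neglog10p_two_sided(z)),
                len(entries), "".join(direction), int(ns.sum()),
            )
        )
    result = pd.DataFrame(out, columns=_META_COLS)
    return result.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_meta(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_meta(path: str | os.PathLike) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str, "direction": str})
    missing = set(_META_COLS) - set(raw.columns)
    if missing:
        raise ValueError(f"meta table {path} lacks columns {sorted(missing)}")
    return raw
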