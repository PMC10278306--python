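"""Iterative LD-based QTL-region calling from a single-chromosome scan.

Given per-variant summary statistics and a dosage reference for LD, QTL
are peeled off one at a time:

1. the *lead* is the variant with the maximal -log10(p), provided it
   reaches the significance threshold (default 7.3, i.e. P = 0.05
   Bonferroni-corrected for ~1 million independent tests);
2. a window of +/- 10 Mb (configurable half-width) is centered on the lead;
3. r, the Pearson correlation of allele dosages between the lead and every
   window variant, is computed in the scan cohort (signed — the
   conditional statistic below needs the sign);
4. the QTL confidence interval is the set of window variants in high LD
   with the lead (|r| >= 0.7), the lead included;
5. each window variant i outside the CI is tested for being a shadow of
   the lead via the conditional statistic

       T_new = (b_i - b_lead * r(i, lead)) / se_i ;

   i is *explained* (and removed) when its conditional signal is
   sub-threshold, -log10(p_new) < threshold, AND T_new keeps the sign of
   the marginal statistic T_i = b_i / se_i;
6. CI members and explained variants leave the working set, and the
   procedure repeats until no variant reaches the threshold.

Termination is guaranteed because the lead (r = 1 with itself) is removed
every iteration.  Variants outside the current window are never touched.
Equal -log10(p) ties break to the smallest bp, then lexicographic id, so
calls are deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import neglog10p_two_sided, p_two_sided
from .assoc import AssocStat, ScanResult

__all__ = [
    "PeelingConfig",
    "QTLRegion",
    "significance_threshold",
    "conditional_statistic",
    "call_qtl",
    "qtl_table",
]


@dataclass(frozen=True)
class PeelingConfig:
    sig_threshold_neglog10p: float = 7.3
    window_halfwidth_bp: int = 10_000_000
    ci_ld_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.sig_threshold_neglog10p <= 0:
            raise ValueError("significance threshold must be positive")
        if self.window_halfwidth_bp <= 0:
            raise ValueError("window halfwidth must be positive")
        if not (0.0 < self.ci_ld_threshold <= 1.0):
            raise ValueError("ci_ld_threshold must be in (0, 1]")


@dataclass
class QTLRegion:
    trait: str
    analysis: str
    lead: AssocStat
    ci_start_bp: int
    ci_end_bp: int
    ci_variant_ids: list[str]
    iteration_index: int

    @property
    def n_ci_variants(self) -> int:
        return len(self.ci_variant_ids)

    @property
    def ci_length_bp(self) -> int:
        return self.ci_end_bp - self.ci_start_bp


def significance_threshold(alpha: float, n_tests: int) -> float:
    """-log10 of the Bonferroni-corrected per-test level alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))


def conditional_statistic(
    b_i, se_i, b_lead: float, r_i_lead
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(T_new, p_new, T_i): the lead-conditional Wald statistic.

    Accepts scalars or arrays for the per-variant arguments.
    """
    b_i = np.asarray(b_i, dtype=float)
    se_i = np.asarray(se_i, dtype=float)
    r = np.asarray(r_i_lead, dtype=float)
    if (se_i <= 0).any():
        raise ValueError("se_i must be positive")
    if (np.abs(r) > 1 + 1e-12).any():
        raise ValueError("r must lie in [-1, 1]")
    t_i = b_i / se_i
    t_new = (b_i - b_lead * r) / se_i
    p_new = p_two_sided(t_new)
    if t_new.ndim == 0:
        return float(t_new), float(p_new), float(t_i)
    return t_new, p_new, t_i


def _scan_frame(scan) -> pd.DataFrame:
    """Normalize a ScanResult, scan table or meta table to (id, chrom, pos, b, se, neglog10p)."""
    t = scan.table if isinstance(scan, ScanResult) else scan
    t = t.copy()
    if "b_meta" in t.columns:  # meta-analysis table
        t = t.rename(columns={"b_meta": "b", "se_meta": "se"})
    need = {"id", "chrom", "pos", "b", "se", "neglog10p"}
    missing = need - set(t.columns)
    if missing:
        raise ValueError(f"scan table lacks columns {sorted(missing)}")
    return t


def call_qtl(
    scan,
    dm,
    cfg: PeelingConfig = PeelingConfig(),
    trait: str = "",
    analysis: str = "",
    trace: list | None = None,
) -> list[QTLRegion]:
    """Run the peeling procedure on one chromosome.

    `scan` is a ScanResult, its table, or a meta-analysis table; `dm` is
    the dosage reference used for LD (the scan cohort itself in the
    within-population case).  Every scan variant must exist in `dm`.
    Pass a list as `trace` to collect one audit record per removal.
    """
    t = _scan_frame(scan)
    chroms = t["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"scan must cover a single chromosome, got {list(chroms)}")
    col = {v: j for j, v in enumerate(dm.variant_ids())}
    missing = [v for v in t["id"] if v not in col]
    if missing:
        raise ValueError(f"scan variants missing from LD reference: {missing[:5]}")

    ids = t["id"].to_numpy()
    pos = t["pos"].to_numpy(dtype=np.int64)
    b = t["b"].to_numpy(dtype=float)
    se = t["se"].to_numpy(dtype=float)
    nlp = t["neglog10p"].to_numpy(dtype=float)
    x = dm.dosages[:, [col[v] for v in ids]]
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))

    active = np.ones(ids.size, dtype=bool)
    regions: list[QTLRegion] = []
    iteration = 0
    while True:
        cand = np.flatnonzero(active & (nlp >= cfg.sig_threshold_neglog10p))
        if cand.size == 0:
            break
        iteration += 1
        # lead: max -log10(p); ties -> smallest bp, then smallest id
        best = nlp[cand].max()
        tied = cand[nlp[cand] == best]
        order = np.lexsort((ids[tied], pos[tied]))
        lead = int(tied[order[0]])

        window = active & (np.abs(pos - pos[lead]) <= cfg.window_halfwidth_bp)
        widx = np.flatnonzero(window)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc[:, widx].T @ xc[:, lead]) / (norms[widx] * norms[lead])
        r = np.clip(np.nan_to_num(r), -1.0, 1.0)

        in_ci = np.abs(r) >= cfg.ci_ld_threshold
        ci_idx = widx[in_ci]
        ci_pos = pos[ci_idx]
        out_idx = widx[~in_ci]
        t_new, _, t_i = conditional_statistic(
            b[out_idx], se[out_idx], float(b[lead]), r[~in_ci]
        )
        nlp_new = neglog10p_two_sided(np.asarray(t_new))
        explained = (nlp_new < cfg.sig_threshold_neglog10p) & (
            np.sign(t_new) * np.sign(t_i) > 0
        )
        exp_idx = out_idx[explained]

        row = t.iloc[lead]
        lead_stat = AssocStat(
            id=str(row["id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row.get("effect_allele", row.get("a1", "."))),
            freq=float(row["freq"]) if "freq" in row and pd.notna(row["freq"]) else np.nan,
            b=float(row["b"]),
            se=float(row["se"]),
            p=float(row["p"]) if "p" in row else float(p_two_sided(row["b"] / row["se"])),
            neglog10p=float(row["neglog10p"]),
            n=int(row["n"]) if "n" in row and pd.notna(row["n"]) else 0,
        )
        regions.append(
            QTLRegion(
                trait=trait,
                analysis=analysis,
                lead=lead_stat,
                ci_start_bp=int(ci_pos.min()),
                ci_end_bp=int(ci_pos.max()),
                ci_variant_ids=[str(v) for v in ids[ci_idx]],
                iteration_index=iteration,
            )
        )
        if trace is not None:
            trace.append(
                {
                    "iteration": iteration,
                    "lead": str(ids[lead]),
                    "ci": [str(v) for v in ids[ci_idx]],
                    "explained": [
                        {"id": str(ids[j]), "neglog10p_new": float(v)}
                        for j, v in zip(exp_idx, nlp_new[explained])
                    ],
                }
            )
        active[ci_idx] = False
        active[exp_idx] = False
    return regions


def qtl_table(regions: list[QTLRegion]) -> pd.DataFrame:
    """Flat table of called regions (one row per QTL)."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "analysis": r.analysis,
                "lead_snp": r.lead.id,
                "lead_chr": r.lead.chrom,
                "lead_bp": r.lead.pos,
                "lead_neglog10p": r.lead.neglog10p,
                "ci_start": r.ci_start_bp,
                "ci_end": r.ci_end_bp,
                "ci_n_variants": r.n_ci_variants,
                "ci_kbp": r.ci_length_bp / 1000.0,
                "iteration": r.iteration_index,
            }
            for r in regions
        ],
        columns=[
            "trait", "analysis", "lead_snp", "lead_chr", "lead_bp",
            "lead_neglog10p", "ci_start", "ci_end", "ci_n_variants",
            "ci_kbp", "iteration",
        ],
    )
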