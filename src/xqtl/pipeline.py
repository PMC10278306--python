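"""End-to-end orchestration: simulate -> QC -> GRM -> REML -> scan -> meta -> QTL.

One YAML config drives the whole analysis; every stage's randomness is
derived deterministically from the single config seed through
``numpy.random.SeedSequence(seed).spawn(...)`` (stage order: simulation,
then one stream per downstream stage that needs randomness), so a config
re-run reproduces every output byte-for-byte.

Outputs per run directory:

* ``vc_<pop>_<trait>.json`` — variance components + heritability partition
* ``scan_<pop>.tsv`` — per-population X-chromosome summary statistics
* ``meta.tsv`` — fixed-effects meta-analysis over populations
* ``qtl_<analysis>.tsv`` — peeled QTL regions per analysis
* ``qtl_counts.tsv`` — QTL-per-trait-per-analysis count matrix
* ``qtl_summary.tsv`` — per-analysis mean/min/max of lead -log10(p),
  CI variant counts and CI length (kbp)
* ``manifest.json`` — file list with SHA-256 hashes and row counts
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .assoc import ScanResult, run_scan, write_scan
from .genotypes_io import (
    DosageMatrix,
    PhenotypeTable,
    QCThresholds,
    apply_variant_qc,
    read_dosages,
    read_phenotypes,
    write_dosages,
    write_phenotypes,
)
from .grm import compute_grm
from .meta import fixed_effects_meta, write_meta
from .qtl_caller import PeelingConfig, call_qtl, qtl_table
from .reml import fit_reml_two_components, heritability_from_components
from .synthetic_data import SimConfig, simulate_population

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    sim: SimConfig | None = None  # either simulate ...
    dosages_path: str | None = None  # ... or load from files
    phenotypes_path: str | None = None
    traits: list[str] = field(default_factory=list)
    qc: QCThresholds = field(default_factory=QCThresholds)
    peeling: PeelingConfig = field(default_factory=PeelingConfig)
    scan_chrom: str = "X"
    grm_chroms: list[str] = field(default_factory=lambda: ["2"])
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and (self.dosages_path is None or self.phenotypes_path is None):
            raise ValueError("config needs either a sim section or input paths")
        if self.sim is not None and not self.traits:
            self.traits = [self.sim.trait_name]


def load_pipeline_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("sim", None)
    if sim is not None:
        if "planted_qtl" in sim:
            sim["planted_qtl"] = [tuple(q) for q in sim["planted_qtl"]]
        sim = SimConfig(**sim)
    qc = QCThresholds(**raw.pop("qc", {}))
    peeling = PeelingConfig(**raw.pop("peeling", {}))
    return PipelineConfig(sim=sim, qc=qc, peeling=peeling, **raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _log_stage(stage: str, **counts) -> None:
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    def _register(name: str, path: str, n_rows: int | None = None) -> None:
        outputs[name] = path
        if n_rows is not None:
            counts[name] = n_rows

    # -- stage: inputs -----------------------------------------------------
    try:
        if cfg.sim is not None:
            sim_cfg = SimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
            dm, pheno, truth = simulate_population(sim_cfg)
            dpath = os.path.join(cfg.out_dir, "dosages.tsv")
            write_dosages(dm, dpath)
            ppath = os.path.join(cfg.out_dir, "phenotypes.tsv")
            write_phenotypes(pheno, ppath)
            tpath = os.path.join(cfg.out_dir, "truth.json")
            with open(tpath, "w") as fh:
                json.dump(truth.to_dict(), fh, indent=1)
            _register("dosages", dpath, dm.n_variants)
            _register("phenotypes", ppath, len(pheno.table))
            _register("truth", tpath)
        else:
            dm = read_dosages(cfg.dosages_path)
            pheno = read_phenotypes(cfg.phenotypes_path)
        _log_stage("inputs", n_samples=dm.n_samples, n_variants=dm.n_variants)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {e}") from e

    manifest = {"outputs": outputs, "counts": counts, "seed": cfg.seed}
    try:
        dm_seq, qc_report = apply_variant_qc(dm, cfg.qc, "sequence_filter")
        _log_stage(
            "sequence_qc",
            n_in=qc_report.n_input,
            n_pass=qc_report.n_pass,
            **{f"removed_{k}": v for k, v in qc_report.removed_by.items()},
        )
    except Exception as e:
        _dump_manifest(cfg, manifest)
        raise RuntimeError(f"pipeline stage 'sequence_qc' failed: {e}") from e

    # -- per-population stages --------------------------------------------
    if dm_seq.sample_info is not None and "population" in dm_seq.sample_info.columns:
        pop_labels = list(dict.fromkeys(dm_seq.sample_info["population"]))
        pop_of = dm_seq.sample_info["population"].to_numpy()
    else:
        pop_labels = ["ALL"]
        pop_of = np.full(dm_seq.n_samples, "ALL")

    scans: dict[str, dict[str, ScanResult]] = {t: {} for t in cfg.traits}
    try:
        for pop in pop_labels:
            sub = dm_seq.subset_samples(pop_of == pop)
            # drop variants that became monomorphic inside the population
            poly = sub.maf() > 0
            sub = sub.subset_variants(poly)
            g_a = compute_grm(sub, chroms=cfg.grm_chroms, label="autosomal")
            g_x = compute_grm(sub, chroms=[cfg.scan_chrom], label="X")
            x_dm = sub.select_chrom(cfg.scan_chrom)
            for trait in cfg.traits:
                yvec = pheno.vector(trait, sub.samples)
                vc = fit_reml_two_components(yvec, g_a, g_x)
                h2 = heritability_from_components(vc)
                vc_path = os.path.join(cfg.out_dir, f"vc_{pop}_{trait}.json")
                with open(vc_path, "w") as fh:
                    json.dump({**vc.to_dict(), **h2.to_dict()}, fh, indent=1)
                _register(f"vc_{pop}_{trait}", vc_path)
                scan = run_scan(x_dm, yvec, g_a, trait=trait, population=pop)
                scans[trait][pop] = scan
                spath = os.path.join(cfg.out_dir, f"scan_{pop}_{trait}.tsv")
                write_scan(scan, spath)
                _register(f"scan_{pop}_{trait}", spath, len(scan.table))
            _log_stage(
                "population", pop=pop, n_samples=sub.n_samples,
                n_scan_variants=x_dm.n_variants,
            )
    except Exception as e:
        _dump_manifest(cfg, manifest)
        raise RuntimeError(f"pipeline stage 'population_analyses' failed: {e}") from e

    # -- meta and QTL ------------------------------------------------------
    try:
        qtl_frames = []
        count_rows = []
        for trait in cfg.traits:
            analyses: dict[str, object] = dict(scans[trait])
            if len(pop_labels) > 1:
                meta_tab = fixed_effects_meta([scans[trait][p] for p in pop_labels])
                mpath = os.path.join(cfg.out_dir, f"meta_{trait}.tsv")
                write_meta(meta_tab, mpath)
                _register(f"meta_{trait}", mpath, len(meta_tab))
                analyses["META"] = meta_tab
            for label, scan in analyses.items():
                if label == "META":
                    ld_ref = dm_seq.select_chrom(cfg.scan_chrom)
                else:
                    sub = dm_seq.subset_samples(pop_of == label)
                    sub = sub.subset_variants(sub.maf() > 0)
                    ld_ref = sub.select_chrom(cfg.scan_chrom)
                regions = call_qtl(
                    scan, ld_ref, cfg.peeling, trait=trait, analysis=label
                )
                tab = qtl_table(regions)
                qpath = os.path.join(cfg.out_dir, f"qtl_{label}_{trait}.tsv")
                tab.to_csv(qpath, sep="\t", index=False)
                _register(f"qtl_{label}_{trait}", qpath, len(tab))
                qtl_frames.append(tab)
                count_rows.append({"analysis": label, "trait": trait, "n_qtl": len(tab)})
                _log_stage("qtl", trait=trait, analysis=label, n_qtl=len(tab))
        all_qtl = pd.concat(qtl_frames, ignore_index=True) if qtl_frames else qtl_table([])
        count_mat = (
            pd.DataFrame(count_rows)
            .pivot(index="analysis", columns="trait", values="n_qtl")
            .fillna(0)
            .astype(int)
        )
        cpath = os.path.join(cfg.out_dir, "qtl_counts.tsv")
        count_mat.to_csv(cpath, sep="\t")
        _register("qtl_counts", cpath, len(count_mat))
        summary = _qtl_summary(all_qtl)
        spath = os.path.join(cfg.out_dir, "qtl_summary.tsv")
        summary.to_csv(spath, sep="\t", index=False)
        _register("qtl_summary", spath, len(summary))
        if cfg.make_plots:
            for trait in cfg.traits:
                for pop, scan in scans[trait].items():
                    _manhattan(
                        scan.table,
                        cfg.peeling.sig_threshold_neglog10p,
                        os.path.join(cfg.out_dir, f"manhattan_{pop}_{trait}.png"),
                    )
    except Exception as e:
        _dump_manifest(cfg, manifest)
        raise RuntimeError(f"pipeline stage 'meta_and_qtl' failed: {e}") from e

    for name, path in outputs.items():
        manifest.setdefault("sha256", {})[name] = _sha256(path)
    _dump_manifest(cfg, manifest)
    return manifest


def _qtl_summary(all_qtl: pd.DataFrame) -> pd.DataFrame:
    """Per-analysis lead significance and CI-size summary (mean/min/max)."""
    if all_qtl.empty:
        return pd.DataFrame(
            columns=["analysis", "n_qtl"]
            + [f"{v}_{s}" for v in ("lead_neglog10p", "ci_n_variants", "ci_kbp")
               for s in ("mean", "min", "max")]
        )
    rows = []
    for analysis, grp in all_qtl.groupby("analysis"):
        row = {"analysis": analysis, "n_qtl": len(grp)}
        for v in ("lead_neglog10p", "ci_n_variants", "ci_kbp"):
            row[f"{v}_mean"] = grp[v].mean()
            row[f"{v}_min"] = grp[v].min()
            row[f"{v}_max"] = grp[v].max()
        rows.append(row)
    return pd.DataFrame(rows)


def _manhattan(table: pd.DataFrame, threshold: float, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(table["pos"] / 1e6, table["neglog10p"], s=4, c="steelblue")
    ax.axhline(threshold, color="firebrick", lw=1, ls="--")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _dump_manifest(cfg: PipelineConfig, manifest: dict) -> None:
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
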