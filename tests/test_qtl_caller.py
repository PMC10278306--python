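import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _naive import naive_call_qtl
from xqtl.assoc import run_scan
from xqtl.genotypes_io import DosageMatrix, VariantRecord
from xqtl.grm import compute_grm
from xqtl.qtl_caller import (
    PeelingConfig,
    call_qtl,
    conditional_statistic,
    qtl_table,
    significance_threshold,
)
from xqtl.synthetic_data import SimConfig, simulate_population


class TestSignificanceThreshold:
    def test_bonferroni_million_tests(self):
        assert round(significance_threshold(0.05, 1_000_000), 1) == 7.3

    def test_log_arithmetic(self):
        assert significance_threshold(0.5, 1) == pytest.approx(np.log10(2))

    def test_chip_density_threshold(self):
        assert significance_threshold(0.05, 54_616) == pytest.approx(6.038, abs=5e-4)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            significance_threshold(alpha, 100)

    @given(
        alpha=st.floats(1e-6, 0.999),
        n=st.integers(1, 10**9),
    )
    @settings(max_examples=50, deadline=None)
    def test_threshold_decomposes(self, alpha, n):
        assert significance_threshold(alpha, n) == pytest.approx(
            np.log10(n) - np.log10(alpha), rel=1e-12
        )


class TestConditionalStatistic:
    def test_zero_ld_leaves_statistic_unchanged(self):
        t_new, _, t_i = conditional_statistic(0.3, 0.1, 0.9, 0.0)
        assert t_new == t_i

    def test_perfect_ld_shadow_vanishes(self):
        t_new, p_new, _ = conditional_statistic(0.4, 0.1, 0.4, 1.0)
        assert t_new == 0.0
        assert p_new == pytest.approx(1.0)

    def test_hand_example_with_sign_flip(self):
        t_new, _, t_i = conditional_statistic(0.30, 0.05, 0.40, 0.8)
        assert t_new == pytest.approx(-0.4)
        assert np.sign(t_new) != np.sign(t_i)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError, match="se"):
            conditional_statistic(0.1, 0.0, 0.1, 0.5)

    @given(
        b=st.floats(-2, 2), se=st.floats(0.01, 1), b_lead=st.floats(-2, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_r_zero_reduces_to_marginal(self, b, se, b_lead):
        t_new, _, t_i = conditional_statistic(b, se, b_lead, 0.0)
        assert t_new == t_i


def _synthetic_scan(positions, neglog10p, b=None, dosage_cols=None, n_samples=60):
    """Build a matched (scan table, dosage reference) pair by hand."""
    m = len(positions)
    b = np.ones(m) if b is None else np.asarray(b, float)
    rng = np.random.default_rng(123)
    if dosage_cols is None:
        dosage_cols = rng.binomial(2, 0.4, size=(n_samples, m)).astype(float)
    ids = [f"x{j}" for j in range(m)]
    table = pd.DataFrame(
        {
            "id": ids, "chrom": "X", "pos": positions, "b": b,
            "se": np.abs(b) / 5.0 + 0.01, "neglog10p": neglog10p,
        }
    )
    f = dosage_cols.mean(axis=0) / 2
    dm = DosageMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        variants=[
            VariantRecord(id=ids[j], chrom="X", pos=int(positions[j]),
                          ref_allele="A", alt_allele="G",
                          maf=float(min(f[j], 1 - f[j])))
            for j in range(m)
        ],
        dosages=dosage_cols,
    )
    return table, dm


class TestCallQtl:
    def test_subthreshold_scan_yields_nothing(self):
        table, dm = _synthetic_scan([100, 200, 300], [6.9, 5.0, 2.0])
        assert call_qtl(table, dm) == []

    def test_single_ld_block_yields_one_region(self):
        # three significant variants carried by the same dosage column
        rng = np.random.default_rng(7)
        col = rng.binomial(2, 0.5, size=80).astype(float)
        cols = np.column_stack([col, col, col])
        table, dm = _synthetic_scan(
            [1_000, 500_000, 900_000], [9.0, 12.0, 8.0], dosage_cols=cols, n_samples=80
        )
        regions = call_qtl(table, dm)
        assert len(regions) == 1
        r = regions[0]
        assert r.lead.id == "x1"
        assert sorted(r.ci_variant_ids) == ["x0", "x1", "x2"]
        assert (r.ci_start_bp, r.ci_end_bp) == (1_000, 900_000)
        assert r.n_ci_variants == 3

    def test_lead_tie_breaks_to_smallest_position(self):
        rng = np.random.default_rng(8)
        cols = rng.binomial(2, 0.5, size=(100, 2)).astype(float)
        table, dm = _synthetic_scan(
            [5_000, 2_000], [9.0, 9.0], dosage_cols=cols, n_samples=100
        )
        regions = call_qtl(table, dm)
        assert regions[0].lead.pos == 2_000

    def test_matches_naive_reference_on_simulation(self):
        cfg = SimConfig(
            seed=55, n_females_per_pop=800, n_autosomal_variants=200,
            n_x_variants=400, target_h2_aut=0.2, target_h2_x=0.0,
            planted_qtl=[("X", 30_000_000, 0.3), ("X", 95_000_000, 0.3)],
        )
        dm, pheno, _ = simulate_population(cfg)
        g_a = compute_grm(dm, chroms=["2"])
        xdm = dm.select_chrom("X")
        scan = run_scan(xdm, pheno.vector("YD", dm.samples), g_a)
        regions = call_qtl(scan, xdm, PeelingConfig(), trait="YD")
        by_id = dict(zip(xdm.variant_ids(), xdm.dosages.T))
        naive = naive_call_qtl(scan.table, by_id)
        assert len(regions) == len(naive) > 0
        for r, nr in zip(regions, naive):
            assert r.lead.id == nr["lead"]
            assert sorted(r.ci_variant_ids) == nr["ci"]
            assert (r.ci_start_bp, r.ci_end_bp) == (nr["ci_start"], nr["ci_end"])
            assert r.iteration_index == nr["iteration"]

    def test_reported_leads_are_separated(self):
        cfg = SimConfig(
            seed=19, n_females_per_pop=600, n_autosomal_variants=150,
            n_x_variants=300, target_h2_aut=0.1, target_h2_x=0.08,
            planted_qtl=[("X", 20_000_000, 0.35), ("X", 70_000_000, 0.35)],
        )
        dm, pheno, _ = simulate_population(cfg)
        g_a = compute_grm(dm, chroms=["2"])
        xdm = dm.select_chrom("X")
        scan = run_scan(xdm, pheno.vector("YD", dm.samples), g_a)
        cfg_peel = PeelingConfig()
        regions = call_qtl(scan, xdm, cfg_peel)
        ids = xdm.variant_ids()
        for i, a in enumerate(regions):
            for b in regions[i + 1 :]:
                xa = xdm.dosages[:, ids.index(a.lead.id)]
                xb = xdm.dosages[:, ids.index(b.lead.id)]
                r = np.corrcoef(xa, xb)[0, 1]
                close = abs(a.lead.pos - b.lead.pos) <= cfg_peel.window_halfwidth_bp
                assert (not close) or abs(r) < cfg_peel.ci_ld_threshold

    def test_raising_ld_threshold_never_grows_ci(self):
        rng = np.random.default_rng(21)
        base = rng.binomial(2, 0.5, size=100).astype(float)
        cols = np.column_stack(
            [base]
            + [np.clip(base + rng.binomial(1, q, size=100) - rng.binomial(1, q, size=100), 0, 2)
               for q in (0.05, 0.1, 0.2, 0.4, 0.6)]
        )
        table, dm = _synthetic_scan(
            [10_000 * (j + 1) for j in range(6)],
            [15.0, 6.0, 6.0, 6.0, 6.0, 6.0],
            dosage_cols=cols,
            n_samples=100,
        )
        sizes = []
        for thr in (0.5, 0.7, 0.9, 1.0):
            regions = call_qtl(table, dm, PeelingConfig(ci_ld_threshold=thr))
            sizes.append(regions[0].n_ci_variants)
        assert sizes == sorted(sizes, reverse=True)

    def test_trace_documents_every_explained_removal(self):
        table, dm = _synthetic_scan(
            [1_000, 2_000, 3_000], [9.0, 6.5, 3.0],
        )
        trace: list = []
        cfg = PeelingConfig()
        call_qtl(table, dm, cfg, trace=trace)
        for rec in trace:
            for e in rec["explained"]:
                assert e["neglog10p_new"] < cfg.sig_threshold_neglog10p

    def test_multi_chromosome_scan_rejected(self):
        table, dm = _synthetic_scan([100, 200], [9.0, 8.0])
        bad = table.copy()
        bad.loc[0, "chrom"] = "2"
        with pytest.raises(ValueError, match="single chromosome"):
            call_qtl(bad, dm)

    def test_missing_reference_variant_rejected(self):
        table, dm = _synthetic_scan([100, 200], [9.0, 8.0])
        bad = table.copy()
        bad.loc[0, "id"] = "unknown"
        with pytest.raises(ValueError, match="missing"):
            call_qtl(bad, dm)

    def test_qtl_table_layout(self):
        table, dm = _synthetic_scan([100, 200], [9.0, 2.0])
        tab = qtl_table(call_qtl(table, dm, trait="YD", analysis="POP1"))
        assert list(tab.columns) == [
            "trait", "analysis", "lead_snp", "lead_chr", "lead_bp",
            "lead_neglog10p", "ci_start", "ci_end", "ci_n_variants",
            "ci_kbp", "iteration",
        ]
        assert tab.iloc[0]["analysis"] == "POP1"
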