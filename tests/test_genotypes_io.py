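import numpy as np
import pandas as pd
import pytest

from xqtl.genotypes_io import (
    DosageMatrix,
    PhenotypeTable,
    QCThresholds,
    VariantRecord,
    apply_variant_qc,
    hwe_pvalues,
    read_dosages,
    read_phenotypes,
    write_dosages,
    write_phenotypes,
)


def _dm(dosages, chrom="1", r2=None, pos0=100):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    f = dosages.mean(axis=0) / 2.0
    maf = np.minimum(f, 1 - f)
    variants = [
        VariantRecord(
            id=f"v{j}",
            chrom=chrom,
            pos=pos0 + j * 1000,
            ref_allele="A",
            alt_allele="G",
            maf=float(maf[j]),
            imputation_r2=None if r2 is None else r2[j],
        )
        for j in range(m)
    ]
    return DosageMatrix(
        samples=[f"s{i}" for i in range(n)], variants=variants, dosages=dosages
    )


class TestDosageMatrix:
    def test_two_sample_one_variant_maf(self):
        dm = _dm([[0.0], [2.0]])
        assert dm.maf()[0] == pytest.approx(0.5)

    def test_maf_is_folded(self):
        dm = _dm([[2.0], [2.0], [2.0], [0.0]])  # ALT freq 0.75
        assert dm.alt_freq()[0] == pytest.approx(0.75)
        assert dm.maf()[0] == pytest.approx(0.25)

    def test_out_of_range_dosage_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _dm([[3.0]])

    def test_nan_dosage_rejected(self):
        v = VariantRecord(id="v", chrom="1", pos=1, ref_allele="A", alt_allele="G", maf=0.25)
        with pytest.raises(ValueError, match="missing"):
            DosageMatrix(samples=["a"], variants=[v], dosages=[[np.nan]])

    def test_duplicate_variant_id_rejected(self):
        v = VariantRecord(id="v", chrom="1", pos=1, ref_allele="A", alt_allele="G", maf=0.25)
        with pytest.raises(ValueError, match="duplicate"):
            DosageMatrix(samples=["a", "b"], variants=[v, v], dosages=[[1, 1], [0, 0]])

    def test_metadata_maf_must_match_data(self):
        v = VariantRecord(id="v", chrom="1", pos=1, ref_allele="A", alt_allele="G", maf=0.4)
        with pytest.raises(ValueError, match="maf"):
            DosageMatrix(samples=["a", "b"], variants=[v], dosages=[[0.0], [2.0]])

    def test_sample_subset_refreshes_maf(self, rng):
        dm = _dm(rng.integers(0, 3, size=(20, 5)).astype(float))
        sub = dm.subset_samples(np.arange(10))
        np.testing.assert_allclose([v.maf for v in sub.variants], sub.maf(), atol=1e-12)


class TestTsvIO:
    def test_round_trip_bit_for_bit(self, tmp_path, rng):
        dm = _dm(rng.uniform(0, 2, size=(7, 4)), r2=[0.9, 0.8, None, 1.0])
        path = tmp_path / "d.tsv"
        write_dosages(dm, path)
        back = read_dosages(path)
        assert back.samples == dm.samples
        np.testing.assert_array_equal(back.dosages, dm.dosages)
        assert back.variants == dm.variants
        # second write is byte-identical
        write_dosages(back, tmp_path / "d2.tsv")
        assert (tmp_path / "d.tsv").read_bytes() == (tmp_path / "d2.tsv").read_bytes()

    def test_missing_dosage_fails_loudly(self, tmp_path, rng):
        dm = _dm(rng.uniform(0, 2, size=(3, 2)))
        write_dosages(dm, tmp_path / "d.tsv")
        text = (tmp_path / "d.tsv").read_text().rsplit("\t", 1)[0] + "\t\n"
        (tmp_path / "d.tsv").write_text(text)
        with pytest.raises(ValueError, match="missing dosage"):
            read_dosages(tmp_path / "d.tsv")

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_dosages(tmp_path / "x.bed", format="bed")


class TestVcfIO:
    def test_gt_fallback_converts_to_dosage(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        dm = read_dosages(vcf, format="vcf")
        np.testing.assert_array_equal(dm.dosages[:, 0], [0.0, 1.0, 2.0])
        assert dm.variants[0].maf == pytest.approx(0.5)

    def test_ds_round_trip_value_for_value(self, tmp_path, rng):
        dm = _dm(rng.uniform(0, 2, size=(5, 3)), r2=[0.5, 0.75, 0.99])
        path = tmp_path / "d.vcf"
        write_dosages(dm, path, format="vcf")
        back = read_dosages(path, format="vcf")
        assert back.samples == dm.samples
        np.testing.assert_allclose(back.dosages, dm.dosages, atol=1e-5)
        np.testing.assert_allclose(
            [v.imputation_r2 for v in back.variants],
            [v.imputation_r2 for v in dm.variants],
            atol=1e-6,
        )


class TestPhenotypes:
    def test_round_trip_and_alignment(self, tmp_path):
        tab = PhenotypeTable(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b", "a"],
                    "trait": ["MY", "MY", "SCS"],
                    "value": [1.0, -0.5, 2.0],
                }
            )
        )
        write_phenotypes(tab, tmp_path / "p.tsv")
        back = read_phenotypes(tmp_path / "p.tsv")
        np.testing.assert_allclose(back.vector("MY", ["b", "a"]), [-0.5, 1.0])
        assert back.traits() == ["MY", "SCS"]

    def test_duplicate_record_rejected(self):
        with pytest.raises(ValueError, match="one value"):
            PhenotypeTable(
                pd.DataFrame(
                    {"sample_id": ["a", "a"], "trait": ["MY", "MY"], "value": [1, 2]}
                )
            )

    def test_missing_sample_raises(self):
        tab = PhenotypeTable(
            pd.DataFrame({"sample_id": ["a"], "trait": ["MY"], "value": [1.0]})
        )
        with pytest.raises(KeyError):
            tab.vector("MY", ["a", "zzz"])


class TestVariantQC:
    def _fixture(self):
        # 10 variants, n=100: columns 0-2 below the 0.005 MAF floor,
        # columns 2-3 below the 0.20 imputation-R2 floor (2 overlaps)
        n = 100
        dosages = np.zeros((n, 10))
        mafs = [0.001, 0.002, 0.004, 0.3, 0.3, 0.1, 0.2, 0.25, 0.4, 0.45]
        rng = np.random.default_rng(5)
        for j, maf in enumerate(mafs):
            if maf < 0.005:
                dosages[0, j] = 2 * maf * n  # one carrier holds all dose
            else:
                dosages[:, j] = rng.binomial(2, maf, size=n)
                dosages[0, j] = 0  # keep ALT freq below 0.5
        r2 = [0.9, 0.9, 0.1, 0.15, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9]
        return _dm(dosages, r2=r2)

    def test_sequence_filter_counts(self):
        dm = self._fixture()
        out, report = apply_variant_qc(dm, QCThresholds(), "sequence_filter")
        assert report.n_input == 10
        assert report.removed_by == {"maf": 3, "imputation_r2": 2}
        assert report.n_pass == out.n_variants == 6
        # order preserved
        assert out.variant_ids() == ["v4", "v5", "v6", "v7", "v8", "v9"]

    def test_low_maf_variant_removed_despite_good_r2(self):
        dm = _dm(np.array([[0.8] + [1.0]] + [[0.0, 1.0]] * 99), r2=[0.9, 0.9])
        assert dm.maf()[0] == pytest.approx(0.004)
        out, report = apply_variant_qc(dm, QCThresholds(), "sequence_filter")
        assert "v0" not in out.variant_ids()
        assert report.removed_by["maf"] == 1

    def test_missing_r2_fails_sequence_filter(self):
        dm = _dm(np.tile([0.0, 1.0, 2.0], (10, 1)).T.reshape(30, 1), r2=[None])
        out, _ = apply_variant_qc(dm, QCThresholds(), "sequence_filter")
        assert out.n_variants == 0

    def test_empty_matrix(self):
        dm = DosageMatrix(samples=["a"], variants=[], dosages=np.empty((1, 0)))
        out, report = apply_variant_qc(dm, QCThresholds(), "sequence_filter")
        assert out.n_variants == 0
        assert report.n_pass == 0

    def test_idempotent(self):
        dm = self._fixture()
        once, _ = apply_variant_qc(dm, QCThresholds(), "sequence_filter")
        twice, report = apply_variant_qc(once, QCThresholds(), "sequence_filter")
        assert twice.variant_ids() == once.variant_ids()
        assert all(v == 0 for v in report.removed_by.values())

    def test_unknown_stage(self):
        with pytest.raises(ValueError, match="stage"):
            apply_variant_qc(self._fixture(), QCThresholds(), "nonsense")

    def test_chip_qc_flags_hwe_outlier(self):
        n = 200
        rng = np.random.default_rng(9)
        ok = rng.binomial(2, 0.4, size=n).astype(float)
        all_het = np.ones(n)  # wildly out of HW equilibrium
        dm = _dm(np.column_stack([ok, all_het]))
        out, report = apply_variant_qc(dm, QCThresholds(), "chip_qc")
        assert "v1" not in out.variant_ids()
        assert report.removed_by["hwe"] >= 1

    def test_hwe_pvalue_monomorphic_is_one(self):
        p = hwe_pvalues(np.zeros((50, 1)))
        assert p[0] == pytest.approx(1.0)
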