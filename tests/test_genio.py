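"""Genotype IO, QC filters, PCA, and F_ST estimators."""

import numpy as np
import pandas as pd
import pytest

from pwasforge import (
    GenotypeMatrix,
    fst_hudson,
    fst_hudson_mean,
    fst_weir_cockerham,
    genotype_pca,
    qc_filter,
    simulate_genotypes,
)
from pwasforge.genio import (
    read_genotypes_tsv,
    read_genotypes_vcf,
    write_genotypes_tsv,
    write_genotypes_vcf,
)


def _toy_matrix(dosages, r2=None, populations=None):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    variants = pd.DataFrame({
        "variant_id": [f"1:{1000 + i}:A:G" for i in range(p)],
        "chrom": "1", "pos": np.arange(1000, 1000 + p),
        "ref": "A", "alt": "G",
        "r2": r2 if r2 is not None else np.ones(p),
    })
    samples = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "population": populations if populations is not None else ["ALL"] * n,
    })
    return GenotypeMatrix(dosages=dosages, samples=samples, variants=variants)


class TestReadWrite:
    def test_vcf_round_trip_preserves_dosages_and_metadata(self, small_panel, tmp_path):
        g, _ = small_panel
        path = tmp_path / "panel.vcf"
        write_genotypes_vcf(g, str(path))
        g2 = read_genotypes_vcf(str(path))
        assert np.allclose(g.dosages, g2.dosages, atol=1e-3)
        assert list(g2.variants["variant_id"]) == list(g.variants["variant_id"])
        assert np.allclose(g2.variants["r2"], g.variants["r2"], atol=1e-4)

    def test_gt_fallback_when_no_dosage_field(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        path = tmp_path / "gt.vcf"
        path.write_text(vcf)
        g = read_genotypes_vcf(str(path))
        assert g.dosages.tolist() == [[1.0], [2.0]]

    def test_multiallelic_records_are_skipped(self, tmp_path, caplog):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\tv1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
            "1\t200\tv2\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        path = tmp_path / "multi.vcf"
        path.write_text(vcf)
        g = read_genotypes_vcf(str(path))
        assert g.n_variants == 1
        assert g.variants["variant_id"].iloc[0] == "v2"

    def test_tsv_round_trip_and_shape(self, small_panel, tmp_path):
        g, _ = small_panel
        path = tmp_path / "panel.tsv"
        write_genotypes_tsv(g, str(path))
        g2 = read_genotypes_tsv(str(path))
        assert g2.dosages.shape == (g.n_samples, g.n_variants)
        assert np.allclose(g.dosages, g2.dosages, atol=1e-3)


class TestQcFilter:
    def test_monomorphic_variant_removed(self):
        g = _toy_matrix([[0, 1], [0, 2], [0, 1]])
        out = qc_filter(g, maf_min=0.01, r2_min=0.0)
        assert out.n_variants == 1

    def test_hand_computed_maf_retained(self):
        g = _toy_matrix([[0], [1], [1], [2]])
        assert g.alt_frequency("ALL")[0] == pytest.approx(0.5)
        assert g.maf("ALL")[0] == pytest.approx(0.5)
        assert qc_filter(g, maf_min=0.01, r2_min=0.0).n_variants == 1

    def test_all_mode_requires_r2_in_every_population(self):
        # one variant passes R2 in 3 of 4 populations only
        n_per = 4
        pops = sum([[p] * n_per for p in ("P1", "P2", "P3", "P4")], [])
        dosages = np.tile([[0.0], [1.0], [1.0], [2.0]], (4, 1))
        g = _toy_matrix(dosages, populations=pops)
        for p in ("P1", "P2", "P3"):
            g.variants[f"r2_{p}"] = 0.9
        g.variants["r2_P4"] = 0.7
        assert qc_filter(g, 0.01, 0.8, population="ALL").n_variants == 0
        for p in ("P1", "P2", "P3"):
            assert qc_filter(g, 0.01, 0.8, population=p).n_variants == 1
        assert qc_filter(g, 0.01, 0.8, population="P4").n_variants == 0

    def test_idempotent(self, small_panel):
        g, _ = small_panel
        once = qc_filter(g, 0.05, 0.5)
        twice = qc_filter(once, 0.05, 0.5)
        assert list(once.variants["variant_id"]) == list(twice.variants["variant_id"])

    def test_maf_symmetric_under_allele_swap(self, small_panel):
        g, _ = small_panel
        swapped = GenotypeMatrix(dosages=2.0 - g.dosages, samples=g.samples,
                                 variants=g.variants)
        assert np.allclose(g.maf("POP1"), swapped.maf("POP1"))


class TestPca:
    def test_pc1_separates_differentiated_populations(self):
        g, _ = simulate_genotypes({"A": 100, "B": 100}, n_loci=50,
                                  snps_per_locus=10, fst_target=0.3,
                                  ld_decay=0.2, seed=9)
        scores, evr = genotype_pca(g, k=2)
        labels = g.samples["population"].to_numpy()
        a, b = scores[labels == "A", 0], scores[labels == "B", 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
               max(b.min(), a.min()) > min(b.max(), a.max())
        assert evr[0] >= evr[1]
        assert evr.sum() <= 1.0 + 1e-12

    def test_duplicate_samples_get_identical_scores(self, small_panel):
        g, _ = small_panel
        dup = GenotypeMatrix(
            dosages=np.vstack([g.dosages, g.dosages[:1]]),
            samples=pd.concat([g.samples, g.samples.iloc[:1]], ignore_index=True),
            variants=g.variants,
        )
        scores, _ = genotype_pca(dup, k=3)
        assert np.allclose(scores[0], scores[-1], atol=1e-8)

    def test_k_zero_and_rank_errors(self, small_panel):
        g, _ = small_panel
        scores, evr = genotype_pca(g, k=0)
        assert scores.shape == (g.n_samples, 0)
        with pytest.raises(ValueError):
            genotype_pca(g.subset_samples(np.arange(3)), k=5)

    def test_scores_sign_invariant_to_variant_order(self, small_panel):
        g, _ = small_panel
        perm = np.random.default_rng(0).permutation(g.n_variants)
        s1, _ = genotype_pca(g, k=2)
        s2, _ = genotype_pca(g.subset_variants(perm), k=2)
        for j in range(2):
            assert np.allclose(s1[:, j], s2[:, j], atol=1e-8) or \
                   np.allclose(s1[:, j], -s2[:, j], atol=1e-8)


class TestFst:
    def test_no_differentiation_is_near_zero(self):
        assert abs(fst_hudson(0.3, 0.3, 10**6, 10**6)) < 1e-5

    def test_closed_form_value(self):
        # [(0.1-0.9)^2] / [0.1*0.1 + 0.9*0.9] at infinite n
        assert fst_hudson(0.1, 0.9, 10**9, 10**9) == pytest.approx(0.64 / 0.82, abs=1e-5)

    def test_fixed_difference_is_one(self):
        assert fst_hudson(0.0, 1.0, 10**9, 10**9) == pytest.approx(1.0, abs=1e-6)

    def test_both_fixed_same_allele_undefined(self):
        assert np.isnan(fst_hudson(0.0, 0.0, 100, 100))

    def test_small_n_requirement(self):
        with pytest.raises(ValueError):
            fst_hudson(0.5, 0.5, 1, 10)

    def test_hudson_matches_weir_cockerham_on_balanced_samples(self):
        g, _ = simulate_genotypes({"A": 300, "B": 300}, n_loci=50,
                                  snps_per_locus=10, fst_target=0.1,
                                  ld_decay=0.3, seed=13)
        p1, p2 = g.alt_frequency("A"), g.alt_frequency("B")
        h = np.nanmean(fst_hudson(p1, p2, 300, 300))
        wc = np.nanmean(fst_weir_cockerham(p1, p2, 300, 300))
        assert abs(h - wc) < 0.02

    def test_ratio_of_averages_aggregation(self):
        p1 = np.array([0.1, 0.2]); p2 = np.array([0.15, 0.5])
        n1 = n2 = 10**9
        num = ((p1 - p2) ** 2).sum()
        den = (p1 * (1 - p2) + p2 * (1 - p1)).sum()
        assert fst_hudson_mean(p1, p2, n1, n2) == pytest.approx(num / den, abs=1e-6)
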