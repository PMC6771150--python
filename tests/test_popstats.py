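"""Diversity/differentiation statistics: hand-computed examples, estimator
properties on simulated allele frequencies, format readers and PCoA."""

import numpy as np
import pandas as pd
import pytest

from arowana.popstats import (
    MISSING,
    GenotypeMatrix,
    diversity,
    ibs_distance,
    pairwise_fst,
    pcoa,
    read_genotypes,
    read_popmap,
    summarize_dataset,
    weir_cockerham_fst,
    write_matrix_csv,
)


def _gm(genotypes, pops, ids=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    ids = ids or [f"i{k}" for k in range(genotypes.shape[0])]
    return GenotypeMatrix(genotypes, ids, list(pops))


class TestDiversity:
    def test_single_locus_hand_example(self):
        """Genotypes AA, Aa, Aa, aa: p = 0.5, Ho = 0.5, unbiased He =
        (8/7) * 0.5 = 0.5714, Gis = 1 - 0.5/0.5714 = 0.125."""
        gm = _gm([[0], [1], [1], [2]], ["P"] * 4)
        row = diversity(gm).table.loc["P"]
        assert row["A"] == 2.0
        assert row["Ho"] == pytest.approx(0.5)
        assert row["He"] == pytest.approx(4 / 7, abs=1e-9)
        assert row["Gis"] == pytest.approx(0.125)

    def test_all_heterozygotes_negative_gis(self):
        gm = _gm([[1], [1], [1], [1]], ["P"] * 4)
        row = diversity(gm).table.loc["P"]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(4 / 7)
        assert row["Gis"] == pytest.approx(1 - 1 / (4 / 7))
        assert row["Gis"] < 0

    def test_monomorphic_locus_excluded(self):
        # locus 2 monomorphic in the whole dataset: ignored everywhere
        gm = _gm([[0, 0], [1, 0], [1, 0], [2, 0]], ["P"] * 4)
        row = diversity(gm).table.loc["P"]
        assert row["Ho"] == pytest.approx(0.5)
        assert row["He"] == pytest.approx(4 / 7)

    def test_hwe_population_ho_matches_he(self):
        """Under Hardy-Weinberg sampling the observed and unbiased expected
        heterozygosity agree in expectation (5,000 loci, paired check)."""
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 5000)
        geno = rng.binomial(2, p, size=(60, 5000)).astype(np.int8)
        gm = _gm(geno, ["P"] * 60)
        row = diversity(gm).table.loc["P"]
        assert row["Ho"] == pytest.approx(row["He"], rel=0.02)
        assert abs(row["Gis"]) < 0.02

    def test_missing_entries_handled_per_locus(self):
        gm = _gm([[0, MISSING], [1, 1], [1, 1], [2, 1]], ["P"] * 4)
        row = diversity(gm).table.loc["P"]
        assert np.isfinite(row["He"]) and np.isfinite(row["Ho"])

    def test_population_without_data_rejected(self):
        gm = _gm([[0], [1], [MISSING], [MISSING]], ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="B"):
            diversity(gm)


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        g1 = np.zeros((5, 50), dtype=np.int8)
        g2 = np.full((5, 50), 2, dtype=np.int8)
        assert weir_cockerham_fst([g1, g2]) == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, 1000)
        g1 = rng.binomial(2, p, size=(120, 1000)).astype(np.int8)
        g2 = rng.binomial(2, p, size=(120, 1000)).astype(np.int8)
        assert abs(weir_cockerham_fst([g1, g2])) < 0.02

    def test_balding_nichols_recovers_target(self):
        """Populations diverged at F = 0.5 around uniform ancestral
        frequencies: multi-locus theta lands in (0.45, 0.55) at 2,000 loci."""
        rng = np.random.default_rng(2)
        f = 0.5
        p0 = rng.uniform(0.05, 0.95, 2000)
        lam = (1 - f) / f
        pa = rng.beta(p0 * lam, (1 - p0) * lam)
        pb = rng.beta(p0 * lam, (1 - p0) * lam)
        ga = rng.binomial(2, pa, size=(100, 2000)).astype(np.int8)
        gb = rng.binomial(2, pb, size=(100, 2000)).astype(np.int8)
        assert 0.45 < weir_cockerham_fst([ga, gb]) < 0.55

    def test_pairwise_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(9, 100)).astype(np.int8)
        gm = _gm(geno, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        fst = pairwise_fst(gm).values
        assert (fst.values.diagonal() == 0).all()
        np.testing.assert_allclose(fst.values, fst.values.T)

    def test_no_cogenotyped_loci_undefined(self):
        g1 = np.array([[0], [1]], dtype=np.int8)
        g2 = np.full((2, 1), MISSING, dtype=np.int8)
        assert np.isnan(weir_cockerham_fst([g1, g2]))

    def test_single_population_rejected(self):
        gm = _gm([[0], [1]], ["A", "A"])
        with pytest.raises(ValueError, match="two populations"):
            pairwise_fst(gm)


class TestPcoa:
    def test_identical_individuals_coincide(self):
        geno = np.array([[0, 1, 2, 1]] * 2 + [[2, 1, 0, 1]] * 2, dtype=np.int8)
        gm = _gm(geno, ["A"] * 4)
        coords, _ = pcoa(gm, n_axes=1)
        assert coords.iloc[0, 0] == pytest.approx(coords.iloc[1, 0], abs=1e-9)

    def test_distance_reconstruction_collinear(self):
        """d(1,2) = d(1,3) = 1, d(2,3) = 2 is a line; classical scaling must
        reproduce the distances to numerical precision."""
        gm = _gm(np.zeros((3, 2), dtype=np.int8), ["A"] * 3)
        dist = np.array([[0.0, 1, 1], [1, 0, 2], [1, 2, 0]])
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa
        res = skbio_pcoa(DistanceMatrix(dist, ids=list("abc")), number_of_dimensions=0)
        pts = res.samples.to_numpy()
        for i in range(3):
            for j in range(3):
                assert np.linalg.norm(pts[i] - pts[j]) == pytest.approx(dist[i, j], abs=1e-9)

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(4)
        gm = _gm(rng.integers(0, 3, size=(8, 60)).astype(np.int8), ["A"] * 8)
        _, eig = pcoa(gm, n_axes=4)
        assert np.all(np.diff(eig) <= 1e-12)

    def test_ibs_distance_range_and_symmetry(self):
        gm = _gm([[0, 2], [2, 0], [1, 1]], ["A"] * 3)
        d = ibs_distance(gm)
        assert d[0, 1] == pytest.approx(1.0)   # opposite homozygotes
        assert d[0, 2] == pytest.approx(0.5)
        np.testing.assert_allclose(d, d.T)

    def test_separates_differentiated_populations(self):
        """Axis 1 separates two populations generated at F_ST ~ 0.3."""
        rng = np.random.default_rng(5)
        f, lam = 0.3, 0.7 / 0.3
        p0 = rng.uniform(0.05, 0.95, 500)
        pa = rng.beta(p0 * lam, (1 - p0) * lam)
        pb = rng.beta(p0 * lam, (1 - p0) * lam)
        geno = np.vstack([
            rng.binomial(2, pa, size=(6, 500)),
            rng.binomial(2, pb, size=(6, 500)),
        ]).astype(np.int8)
        gm = _gm(geno, ["A"] * 6 + ["B"] * 6)
        coords, _ = pcoa(gm, n_axes=1)
        a = coords.iloc[:6, 0].to_numpy()
        b = coords.iloc[6:, 0].to_numpy()
        assert (a.max() < b.min()) or (b.max() < a.min())


class TestReaders:
    def test_vcf_genotype_codes(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "1\t2\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\t./.\n"
            "1\t3\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        gm = read_genotypes(vcf, "vcf", {"s1": "P1", "s2": "P2"})
        np.testing.assert_array_equal(
            gm.genotypes, [[0, 2, 1], [1, MISSING, 2]])
        assert gm.populations == ["P1", "P2"]

    def test_dart_two_row_convention(self, tmp_path):
        f = tmp_path / "dart.csv"
        f.write_text(
            "locus,allele,s1,s2,s3\n"
            "L0,ref,1,1,0\n"
            "L0,alt,0,1,1\n"
            "L1,ref,1,-,1\n"
            "L1,alt,1,-,0\n"
        )
        gm = read_genotypes(f, "dart-two-row", {"s1": "P", "s2": "P", "s3": "P"})
        np.testing.assert_array_equal(
            gm.genotypes, [[0, 1], [1, MISSING], [2, 0]])

    def test_matrix_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        geno = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
        geno[1, 2] = MISSING
        gm = _gm(geno, ["A", "A", "B", "B"])
        path = tmp_path / "m.csv"
        write_matrix_csv(gm, path)
        back = read_genotypes(path, "matrix-csv",
                              dict(zip(gm.individuals, gm.populations)))
        np.testing.assert_array_equal(back.genotypes, gm.genotypes)
        assert back.individuals == gm.individuals

    def test_popmap_file_and_missing_individual(self, tmp_path):
        pm = tmp_path / "popmap.tsv"
        pm.write_text("s1\tP1\ns2\tP2\n")
        assert read_popmap(pm) == {"s1": "P1", "s2": "P2"}
        f = tmp_path / "m.csv"
        write_matrix_csv(_gm([[0], [1]], ["x", "x"], ids=["s1", "s3"]), f)
        with pytest.raises(ValueError, match="s3"):
            read_genotypes(f, "matrix-csv", pm)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_genotypes(tmp_path / "x", "plink", {})


class TestSummarize:
    def test_counts_and_missing_fraction(self):
        geno = np.zeros((2, 4), dtype=np.int8)
        geno[0, 0] = 1  # keep polymorphic irrelevant here
        geno[1, 3] = MISSING
        gm = _gm(geno, ["A", "B"])
        s = summarize_dataset(gm)
        assert s["n_individuals"] == 2
        assert s["n_loci"] == 4
        assert s["missing_fraction"] == pytest.approx(0.125)
        assert s["populations"] == {"A": 1, "B": 1}
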