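"""Marker coding, standardization, kinships, PC reduction and file IO."""

import numpy as np
import pytest

import hybridts as ht


class TestCodeMarkers:
    def test_coding_table(self):
        g = ht.GenotypeTable.from_strings(
            np.array([["AA", "AB"], ["AB", "AA"], ["BB", "BB"]], dtype=object)
        )
        WA, WD = ht.code_markers(g)
        assert WA.tolist() == [[1, 0], [0, 1], [-1, -1]]
        assert WD.tolist() == [[0, 1], [1, 0], [0, 0]]

    def test_two_by_two_lookup(self):
        g = ht.GenotypeTable.from_strings(
            np.array([["AB", "AA"], ["BB", "AB"]], dtype=object)
        )
        WA, WD = ht.code_markers(g)
        assert WA.tolist() == [[0, 1], [-1, 0]]
        assert WD.tolist() == [[1, 0], [0, 1]]

    def test_all_major_homozygote_column(self):
        g = ht.GenotypeTable.from_strings(
            np.array([["AA"], ["AA"], ["AA"]], dtype=object)
        )
        WA, WD = ht.code_markers(g)
        assert (WA == 1).all() and (WD == 0).all()

    def test_unknown_call_names_cell(self):
        with pytest.raises(ValueError, match="row 1, column 0"):
            ht.GenotypeTable.from_strings(
                np.array([["AA", "AB"], ["XX", "BB"]], dtype=object)
            )

    def test_integer_dialect_matches_strings(self):
        ints = np.array([[2, 1], [1, 0], [0, 2]], dtype=np.int8)
        strs = np.array([["AA", "AB"], ["AB", "BB"], ["BB", "AA"]], dtype=object)
        a = ht.GenotypeTable(ints, ["a", "b", "c"], ["m1", "m2"])
        b = ht.GenotypeTable.from_strings(strs)
        assert (a.calls == b.calls).all()


class TestStandardize:
    def test_self_standardized_column(self):
        X, retained, dropped = ht.standardize(np.array([[1.0], [0.0], [-1.0]]))
        np.testing.assert_allclose(X[:, 0], [1.0, 0.0, -1.0], atol=1e-12)
        assert retained == [0] and dropped == []

    def test_formula_example(self):
        # mean 1/3, sample sd sqrt(4/3)
        X, _, _ = ht.standardize(np.array([[1.0], [1.0], [-1.0]]))
        np.testing.assert_allclose(
            X[:, 0], [0.5773503, 0.5773503, -1.1547005], atol=1e-6
        )

    def test_constant_column_dropped(self):
        W = np.array([[1.0, 5.0], [0.0, 5.0], [-1.0, 5.0]])
        X, retained, dropped = ht.standardize(W)
        assert retained == [0] and dropped == [1]
        assert X.shape == (3, 1)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="no usable markers"):
            ht.standardize(np.ones((4, 3)))

    def test_columns_centered_and_unit_sd(self, small_population):
        _, scores, _ = small_population
        for X in (scores.XA, scores.XD):
            assert np.abs(X.mean(axis=0)).max() < 1e-10
            assert np.abs(X.std(axis=0, ddof=1) - 1).max() < 1e-10


class TestKinship:
    def test_single_column_outer_product(self):
        X = np.array([[1.0], [0.0], [-1.0]])
        K = ht.kinship(X, 1)
        np.testing.assert_allclose(K, [[1, 0, -1], [0, 0, 0], [-1, 0, 1]])

    def test_invariants(self, small_population):
        g, _, kin = small_population
        nc = g.n_hybrids
        for K in (kin.KA, kin.KD):
            assert np.abs(K - K.T).max() < 1e-10
            assert np.abs(np.trace(K) - (nc - 1)) < 1e-8
            assert np.abs(K.sum(axis=1)).max() < 1e-8
            assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_duplicating_markers_leaves_kinship_unchanged(self):
        rng = np.random.default_rng(3)
        X, _, _ = ht.standardize(rng.normal(size=(10, 20)))
        K1 = ht.kinship(X, 20)
        K2 = ht.kinship(np.hstack([X, X]), 40)
        np.testing.assert_allclose(K1, K2, atol=1e-12)

    def test_zero_markers_errors(self):
        with pytest.raises(ValueError, match="p_used"):
            ht.kinship(np.zeros((3, 1)), 0)


class TestPCReduce:
    def test_rank_one(self):
        u = np.array([[1.0], [-1.0], [2.0], [-2.0]])
        v = np.ones((1, 5))
        pcs = ht.pc_reduce(u @ v, u @ v, threshold=0.9)
        assert pcs.n_components == 1
        assert pcs.explained_cumvar == pytest.approx(1.0)

    def test_near_one_threshold_keeps_full_rank(self):
        rng = np.random.default_rng(0)
        XA, _, _ = ht.standardize(rng.normal(size=(6, 4)))
        XD, _, _ = ht.standardize(rng.normal(size=(6, 4)))
        pcs = ht.pc_reduce(XA, XD, threshold=1 - 1e-12)
        M = np.hstack([XA, XD])
        assert pcs.n_components == np.linalg.matrix_rank(M - M.mean(0))

    def test_scores_match_svd_oracle(self):
        M = np.array(
            [[1.0, 2.0, 0.5], [0.0, -1.0, 1.5], [-2.0, 0.5, 0.0], [1.0, -1.5, -2.0]]
        )
        Mc = M - M.mean(axis=0)
        pcs = ht.pc_reduce(M[:, :2], M[:, 2:], threshold=1 - 1e-12)
        U, s, _ = np.linalg.svd(Mc, full_matrices=False)
        Z_ref = U[:, : pcs.n_components] * s[: pcs.n_components]
        # column signs are arbitrary
        for j in range(pcs.n_components):
            col, ref = pcs.Z[:, j], Z_ref[:, j]
            assert np.allclose(col, ref, atol=1e-10) or np.allclose(
                col, -ref, atol=1e-10
            )

    def test_gram_preserved_at_full_threshold(self, small_population):
        _, scores, _ = small_population
        pcs = ht.pc_reduce(scores.XA, scores.XD, threshold=1 - 1e-12)
        M = np.hstack([scores.XA, scores.XD])
        G = (M - M.mean(0)) @ (M - M.mean(0)).T
        err = np.linalg.norm(pcs.Z @ pcs.Z.T - G) / np.linalg.norm(G)
        assert err < 1e-8

    @pytest.mark.parametrize("threshold", [0.0, -0.5, 1.1])
    def test_bad_threshold(self, threshold):
        with pytest.raises(ValueError, match="threshold"):
            ht.pc_reduce(np.eye(3), np.eye(3), threshold=threshold)


class TestDominanceVarianceProfile:
    def test_scaled_diagonal(self):
        K = np.array([[1.0, 0, -1], [0, 0, 0], [-1, 0, 1]])
        np.testing.assert_allclose(
            ht.dominance_variance_profile(K, 2.0), [2.0, 0.0, 2.0]
        )

    def test_zero_variance_and_trace_mean(self, small_population):
        g, _, kin = small_population
        assert (ht.dominance_variance_profile(kin.KD, 0.0) == 0).all()
        prof = ht.dominance_variance_profile(kin.KD, 1.0)
        assert prof.min() > -1e-10
        assert prof.mean() == pytest.approx((g.n_hybrids - 1) / g.n_hybrids)


class TestFileIO:
    def test_delimited_roundtrip(self, tmp_path, small_population):
        g, _, _ = small_population
        path = tmp_path / "geno.tsv"
        ht.write_genotype_matrix(g, path)
        g2 = ht.read_genotype_matrix(path)
        assert (g2.calls == g.calls).all()
        assert g2.hybrid_ids == g.hybrid_ids
        assert g2.marker_ids == g.marker_ids

    def test_comma_and_integer_cells(self, tmp_path):
        path = tmp_path / "geno.csv"
        path.write_text("id,m1,m2\nh1,2,AB\nh2,0,AA\n")
        g = ht.read_genotype_matrix(path)
        assert g.calls.tolist() == [[2, 1], [0, 2]]

    def test_bad_cell_reported(self, tmp_path):
        path = tmp_path / "geno.csv"
        path.write_text("id,m1\nh1,AA\nh2,NN\n")
        with pytest.raises(ValueError, match="h2"):
            ht.read_genotype_matrix(path)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


class TestVCF:
    def test_biallelic_gt_mapping(self, tmp_path):
        path = tmp_path / "x.vcf"
        path.write_text(
            VCF_HEADER
            + "1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            + "1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\n"
            + "1\t300\tsnp3\tC\tT\t.\tPASS\t.\tGT\t1/0\t1/1\t0/0\n"
        )
        g = ht.read_vcf(path)
        assert g.hybrid_ids == ["s1", "s2", "s3"]
        # multi-allelic record skipped
        assert g.marker_ids == ["snp1", "snp3"]
        assert g.calls.tolist() == [[2, 1], [1, 0], [0, 2]]

    def test_missing_genotype_rejected(self, tmp_path):
        path = tmp_path / "x.vcf"
        path.write_text(
            VCF_HEADER + "1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t./.\t1/1\n"
        )
        with pytest.raises(ValueError, match="missing genotype"):
            ht.read_vcf(path)


def test_genotype_table_validation():
    with pytest.raises(ValueError, match="2 hybrids"):
        ht.GenotypeTable(np.array([[1, 2]]), ["a"], ["m1", "m2"])
    with pytest.raises(ValueError, match="unknown genotype call"):
        ht.GenotypeTable(np.array([[3, 1], [0, 1]]), ["a", "b"], ["m1", "m2"])
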