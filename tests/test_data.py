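"""Data plumbing: triplet I/O, barcode alignment, quality filtering, TF-IDF."""

import logging

import numpy as np
import pytest
from scipy import sparse

from pairedvae.data import (FilterSpec, JointProfile, filter_joint_profile,
                            read_embedding, read_joint_profile, tfidf_inverse,
                            tfidf_transform, write_outputs, write_triplet)


def _write_pair(tmp_path, rna, rna_cells, atac, atac_cells, genes=None, peaks=None):
    genes = genes or [f"g{i}" for i in range(np.asarray(rna).shape[1])]
    peaks = peaks or [f"p{i}" for i in range(np.asarray(atac).shape[1])]
    write_triplet(sparse.csr_matrix(rna), genes, rna_cells, tmp_path / "rna")
    write_triplet(sparse.csr_matrix(atac), peaks, atac_cells, tmp_path / "atac")
    return tmp_path / "rna", tmp_path / "atac"


class TestReadJointProfile:
    def test_identical_barcodes_round_trip(self, tmp_path):
        rna = [[1, 0, 2], [0, 3, 0], [4, 0, 0]]
        atac = [[0, 1], [2, 0], [1, 1]]
        cells = ["A", "B", "C"]
        rp, ap = _write_pair(tmp_path, rna, cells, atac, cells)
        jp = read_joint_profile(rp, ap)
        assert jp.cell_ids == cells
        np.testing.assert_array_equal(np.asarray(jp.rna_counts.todense()), rna)
        np.testing.assert_array_equal(np.asarray(jp.atac_counts.todense()), atac)

    def test_barcode_intersection_keeps_rna_order(self, tmp_path, caplog):
        rp, ap = _write_pair(tmp_path,
                             [[1, 0], [2, 1], [0, 3]], ["A", "B", "C"],
                             [[1, 1], [0, 2], [3, 0]], ["B", "C", "D"])
        with caplog.at_level(logging.INFO, logger="pairedvae"):
            jp = read_joint_profile(rp, ap)
        assert jp.cell_ids == ["B", "C"]
        np.testing.assert_array_equal(np.asarray(jp.rna_counts.todense()), [[2, 1], [0, 3]])
        np.testing.assert_array_equal(np.asarray(jp.atac_counts.todense()), [[1, 1], [0, 2]])
        assert any("dropped 1 RNA-only, 1 ATAC-only" in r.message for r in caplog.records)

    def test_zero_overlap_raises(self, tmp_path):
        rp, ap = _write_pair(tmp_path, [[1]], ["A"], [[1]], ["B"])
        with pytest.raises(ValueError, match="overlapping"):
            read_joint_profile(rp, ap)

    def test_missing_path_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_joint_profile(tmp_path / "nope", tmp_path / "nope2")

    def test_negative_entry_raises(self, tmp_path):
        rp, ap = _write_pair(tmp_path, [[1]], ["A"], [[-1]], ["A"])
        with pytest.raises(ValueError, match="negative"):
            read_joint_profile(rp, ap)

    def test_dense_table_input(self, tmp_path):
        path = tmp_path / "rna.tsv"
        path.write_text("\tA\tB\ng1\t1\t0\ng2\t2\t3\n")
        path2 = tmp_path / "atac.tsv"
        path2.write_text("\tA\tB\np1\t0\t1\n")
        jp = read_joint_profile(path, path2)
        assert jp.gene_ids == ["g1", "g2"]
        np.testing.assert_array_equal(np.asarray(jp.rna_counts.todense()), [[1, 2], [0, 3]])


class TestFilter:
    def test_cell_then_feature_removal(self, toy_profile):
        out = filter_joint_profile(toy_profile,
                                   FilterSpec(min_features_per_cell=2,
                                              min_cells_per_feature=2))
        assert out.cell_ids == ["c1", "c2"]          # c3 detects one gene
        assert out.gene_ids == ["g1", "g2", "g3"]    # g4 left with one cell
        assert out.peak_ids == ["p3", "p4"]

    def test_zero_thresholds_no_op(self, toy_profile):
        out = filter_joint_profile(toy_profile, FilterSpec(0, 0))
        assert out.cell_ids == toy_profile.cell_ids
        np.testing.assert_array_equal(np.asarray(out.rna_counts.todense()),
                                      np.asarray(toy_profile.rna_counts.todense()))

    def test_max_cells_per_peak(self, toy_profile):
        out = filter_joint_profile(toy_profile,
                                   FilterSpec(min_features_per_cell=0,
                                              min_cells_per_feature=1,
                                              max_cells_per_peak=2))
        assert "p3" not in out.peak_ids              # detected in all 3 cells
        assert set(out.peak_ids) == {"p1", "p2", "p4"}

    def test_idempotent_on_stable_fixture(self, toy_profile):
        spec = FilterSpec(min_features_per_cell=2, min_cells_per_feature=2)
        once = filter_joint_profile(toy_profile, spec)
        twice = filter_joint_profile(once, spec)
        assert twice.cell_ids == once.cell_ids
        assert twice.gene_ids == once.gene_ids
        assert twice.peak_ids == once.peak_ids

    def test_all_cells_removed_raises(self, toy_profile):
        with pytest.raises(ValueError, match="all"):
            filter_joint_profile(toy_profile, FilterSpec(min_features_per_cell=100))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FilterSpec(min_features_per_cell=-1)
        with pytest.raises(ValueError):
            FilterSpec(min_cells_per_feature=10, max_cells_per_peak=5)


class TestTfidf:
    def test_hand_worked_two_by_two(self):
        m = np.array([[1, 0], [1, 1]])
        out = np.asarray(tfidf_transform(m).todense())
        idf = np.log1p(np.array([2 / 2, 2 / 1]))   # log(2), log(3)
        expected = np.array([[1.0 * idf[0], 0.0],
                             [0.5 * idf[0], 0.5 * idf[1]]]) * 1e4
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_uniform_peak_single_peak_cells(self):
        # every cell detects exactly the one shared peak: TF=1, IDF=log 2
        m = np.array([[3], [1], [7]])
        out = np.asarray(tfidf_transform(m).todense())
        np.testing.assert_allclose(out, np.log(2) * 1e4 * np.ones((3, 1)), rtol=1e-12)

    def test_zero_set_preserved(self, rng):
        m = (rng.random((30, 50)) < 0.3) * rng.poisson(2, (30, 50))
        m[:, 0] = 1   # avoid empty cells
        out = np.asarray(tfidf_transform(m).todense())
        assert ((out == 0) == (m == 0)).all()
        assert np.isfinite(out).all() and (out >= 0).all()

    def test_all_zero_cell_raises(self):
        with pytest.raises(ValueError, match="no detected peaks"):
            tfidf_transform(np.array([[1, 1], [0, 0]]))

    def test_inverse_recovers_presence_scale(self, rng):
        m = (rng.random((20, 30)) < 0.4).astype(int)
        m[:, 0] = 1
        out = np.asarray(tfidf_transform(m).todense())
        back = tfidf_inverse(out, m)
        # inverse undoes the idf/scale/depth weighting exactly, leaving presence
        np.testing.assert_allclose(back, (m > 0).astype(float), atol=1e-9)


class TestWriteOutputs:
    def test_embedding_round_trip(self, tmp_path, rng):
        z = rng.standard_normal((5, 3))
        imput = rng.random((5, 4))
        files = write_outputs(z, imput, imput, tmp_path / "out",
                              cell_ids=[f"c{i}" for i in range(5)],
                              gene_ids=list("abcd"), peak_ids=list("wxyz"))
        z2, cells = read_embedding(files["embedding"])
        np.testing.assert_allclose(z2, z, atol=1e-6)
        assert cells == [f"c{i}" for i in range(5)]

    def test_triplet_round_trip_exact(self, tmp_path, rng):
        m = sparse.csr_matrix(rng.poisson(1, (6, 9)))
        write_triplet(m, [f"f{i}" for i in range(9)], [f"c{i}" for i in range(6)],
                      tmp_path / "t")
        jp_dir = tmp_path / "t"
        from pairedvae.data import _read_single
        m2, cells, feats = _read_single(jp_dir)
        np.testing.assert_array_equal(np.asarray(m2.todense()), np.asarray(m.todense()))

    def test_zero_cells_raises(self, tmp_path):
        with pytest.raises(ValueError, match="0 cells"):
            write_outputs(np.zeros((0, 3)), np.zeros((0, 1)), np.zeros((0, 1)),
                          tmp_path, cell_ids=[], gene_ids=["g"], peak_ids=["p"])

    def test_negative_imputation_raises(self, tmp_path):
        with pytest.raises(ValueError, match="negative"):
            write_outputs(np.zeros((2, 3)), np.array([[-1.0], [0.0]]),
                          np.zeros((2, 1)), tmp_path,
                          cell_ids=["a", "b"], gene_ids=["g"], peak_ids=["p"])


class TestJointProfileInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            JointProfile(rna_counts=np.eye(2), atac_counts=np.eye(2),
                         cell_ids=["a", "a"], gene_ids=["g1", "g2"],
                         peak_ids=["p1", "p2"])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            JointProfile(rna_counts=np.array([[1.5, 0], [0, 1]]),
                         atac_counts=np.eye(2),
                         cell_ids=["a", "b"], gene_ids=["g1", "g2"],
                         peak_ids=["p1", "p2"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            JointProfile(rna_counts=np.eye(3), atac_counts=np.eye(2),
                         cell_ids=["a", "b", "c"], gene_ids=["g"] * 3,
                         peak_ids=["p", "q"])
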