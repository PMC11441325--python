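"""Similarity fusion, attribute construction, normalization, and I/O."""

import numpy as np
import pytest

from dhdmp.data_graph import (
    AssociationDataset,
    assemble_block_adjacency,
    bipartite_normalize,
    build_graph_bundle,
    build_node_attributes,
    fuse_drug_similarity,
    gaussian_kernel_similarity,
    laplacian_normalize,
    load_bundle,
    load_dataset,
    save_bundle,
    save_dataset,
)
from dhdmp.synthetic_data import SyntheticSpec, generate_dataset


class TestGaussianKernel:
    def test_identity_matrix_hand_value(self):
        # two drugs with disjoint single-microbe profiles: mean squared
        # profile norm is 1, so mu = 1 and the off-diagonal is exp(-2)
        dgauss, mu = gaussian_kernel_similarity(np.eye(2))
        assert mu == pytest.approx(1.0)
        assert dgauss[0, 1] == pytest.approx(np.exp(-2.0))
        np.testing.assert_allclose(np.diag(dgauss), 1.0)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(3)
        R = (rng.random((7, 5)) < 0.4).astype(float)
        R[0] = 1.0  # ensure non-zero
        d, mu = gaussian_kernel_similarity(R)
        assert mu > 0
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 1.0)
        assert d.min() > 0 and d.max() <= 1.0

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        R = (rng.random((6, 8)) < 0.3).astype(float)
        R[1, 2] = 1.0
        d1, _ = gaussian_kernel_similarity(R)
        d2, _ = gaussian_kernel_similarity(R[:, rng.permutation(8)])
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gaussian_kernel_similarity(np.zeros((3, 4)))


class TestFusionAndAttributes:
    def test_average_of_hand_matrices(self):
        dstruct = np.array([[1.0, 0.4], [0.4, 1.0]])
        dgauss = np.array([[1.0, np.exp(-2)], [np.exp(-2), 1.0]])
        dsim = fuse_drug_similarity(dstruct, dgauss)
        assert dsim[0, 1] == pytest.approx((0.4 + np.exp(-2)) / 2)
        np.testing.assert_allclose(fuse_drug_similarity(dstruct, dstruct), dstruct)

    def test_fuse_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            fuse_drug_similarity(np.eye(2), np.eye(3))

    def test_block_placement_and_symmetry(self):
        R = np.array([[1.0], [0.0]])
        Z = build_node_attributes(np.eye(2), np.eye(1), R)
        assert Z.shape == (3, 3)
        assert Z[0, 2] == 1.0 and Z[2, 0] == 1.0 and Z[1, 2] == 0.0
        np.testing.assert_allclose(Z, Z.T)

    def test_block_extraction_roundtrip(self):
        rng = np.random.default_rng(5)
        ds, _ = generate_dataset(SyntheticSpec(Nd=9, Nm=6, seed=8))
        b = build_graph_bundle(ds)
        nd = ds.n_drugs
        np.testing.assert_array_equal(b.Z[:nd, nd:], ds.R)
        np.testing.assert_array_equal(b.Z[nd:, nd:], ds.Msim)
        np.testing.assert_array_equal(b.Z[:nd, :nd], b.Dsim)


class TestLaplacianNormalize:
    def test_identity_and_all_ones(self):
        np.testing.assert_allclose(laplacian_normalize(np.eye(4)), np.eye(4))
        np.testing.assert_allclose(
            laplacian_normalize(np.ones((2, 2))), np.full((2, 2), 0.5))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            M = rng.random((6, 6)) * (rng.random((6, 6)) < 0.6)
            got = laplacian_normalize(M)
            deg = (M != 0).sum(axis=1).astype(float)
            ref = np.zeros_like(M)
            for i in range(6):
                for j in range(6):
                    if deg[i] > 0 and deg[j] > 0:
                        ref[i, j] = M[i, j] / np.sqrt(deg[i] * deg[j])
            np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_zero_row_stays_finite_and_zero(self):
        M = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        out = laplacian_normalize(M)
        assert np.isfinite(out).all()
        assert not out[2].any() and not out[:, 2].any()

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            laplacian_normalize(np.array([[1.0, -0.1], [-0.1, 1.0]]))

    def test_bipartite_block_agrees_with_square_embedding(self):
        rng = np.random.default_rng(7)
        R = (rng.random((5, 3)) < 0.5).astype(float)
        got = bipartite_normalize(R)
        rdeg = (R != 0).sum(axis=1)
        cdeg = (R != 0).sum(axis=0)
        for i in range(5):
            for j in range(3):
                if R[i, j] and rdeg[i] and cdeg[j]:
                    assert got[i, j] == pytest.approx(
                        R[i, j] / np.sqrt(rdeg[i] * cdeg[j]))
                else:
                    assert got[i, j] == 0.0


class TestBlockAdjacency:
    def test_block_placement(self):
        rdm = np.array([[1.0], [0.0]])
        ahomo, ahete = assemble_block_adjacency(np.eye(2), np.eye(1), rdm)
        assert ahete[0, 2] == 1.0 and ahete[2, 0] == 1.0
        assert not ahete[:2, :2].any() and not ahete[2:, 2:].any()
        assert not ahomo[:2, 2:].any() and not ahomo[2:, :2].any()

    def test_union_sparsity(self):
        ds, _ = generate_dataset(SyntheticSpec(Nd=8, Nm=5, seed=2))
        b = build_graph_bundle(ds)
        total = b.Ahomo + b.Ahete
        expect = (b.Ahomo != 0) | (b.Ahete != 0)
        np.testing.assert_array_equal(total != 0, expect)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            assemble_block_adjacency(np.eye(2), np.eye(2), np.zeros((3, 2)))


class TestIO:
    def test_roundtrip_dataset(self, tmp_path):
        ds, _ = generate_dataset(SyntheticSpec(Nd=10, Nm=6, seed=3))
        paths = save_dataset(ds, tmp_path)
        back = load_dataset(paths["assoc"], paths["drug_sim"],
                            paths["microbe_sim"], paths["drug_ids"],
                            paths["microbe_ids"])
        np.testing.assert_array_equal(back.R, ds.R)
        np.testing.assert_allclose(back.Dstruct, ds.Dstruct, atol=1e-12)
        np.testing.assert_allclose(back.Msim, ds.Msim, atol=1e-12)
        assert back.drug_ids == ds.drug_ids
        assert back.microbe_ids == ds.microbe_ids

    def test_roundtrip_bundle(self, tmp_path):
        ds, _ = generate_dataset(SyntheticSpec(Nd=7, Nm=4, seed=3))
        b = build_graph_bundle(ds)
        save_bundle(b, tmp_path / "b.h5")
        back = load_bundle(tmp_path / "b.h5")
        np.testing.assert_array_equal(back.Z, b.Z)
        np.testing.assert_array_equal(back.Ahete, b.Ahete)
        assert back.mu == b.mu and back.n_drugs == b.n_drugs

    def test_nonbinary_association_rejected_with_cell(self):
        ds, _ = generate_dataset(SyntheticSpec(Nd=5, Nm=4, seed=3))
        R = ds.R.copy()
        R[2, 1] = 2.0
        with pytest.raises(ValueError, match=r"R\[2,1\]"):
            AssociationDataset(R, ds.Dstruct, ds.Msim, ds.drug_ids, ds.microbe_ids)

    def test_asymmetric_similarity_rejected(self):
        ds, _ = generate_dataset(SyntheticSpec(Nd=5, Nm=4, seed=3))
        bad = ds.Dstruct.copy()
        bad[0, 1] += 1e-3
        with pytest.raises(ValueError, match="symmetric"):
            AssociationDataset(ds.R, bad, ds.Msim, ds.drug_ids, ds.microbe_ids)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path / "none.tsv", tmp_path / "a.tsv",
                         tmp_path / "b.tsv")

    def test_real_scale_dataset_dimensions_and_count(self):
        # sparse matrix at the real dataset's scale: 1373 x 173 with 2470
        # known associations
        rng = np.random.default_rng(0)
        nd, nm = 1373, 173
        R = np.zeros((nd, nm))
        idx = rng.choice(nd * nm, size=2470, replace=False)
        R.ravel()[idx] = 1.0
        ds = AssociationDataset(R, np.eye(nd), np.eye(nm),
                                [f"d{i}" for i in range(nd)],
                                [f"m{j}" for j in range(nm)])
        assert ds.n_positives == 2470
        assert (ds.n_drugs, ds.n_microbes) == (1373, 173)
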