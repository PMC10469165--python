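"""QC filtering, normalization, variable genes, PCA and clustering tests."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from caflineage import qc
from caflineage.errors import DataError


def _adata(counts: np.ndarray, genes=None) -> ad.AnnData:
    n, g = counts.shape
    genes = genes or [f"g{i}" for i in range(g)]
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(float)),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


class TestFilterCells:
    def test_low_gene_cell_removed_and_inlier_retained(self):
        # cell 0: 150 detected genes (removed, <=200); cell 1: 3000 genes,
        # ~5000 UMI, ~5% mito (retained)
        n_genes = 3100
        counts = np.zeros((2, n_genes))
        counts[0, :150] = 20  # 3000 UMI on 150 genes
        counts[1, :3000] = 1
        counts[1, :2000] += 1
        counts[1, 0] = 250  # mito gene: 250/5250 ~ 4.8%
        genes = ["MT-1"] + [f"g{i}" for i in range(n_genes - 1)]
        out = qc.filter_cells(_adata(counts, genes))
        assert list(out.obs_names) == ["c1"]

    def test_exclusive_bounds(self):
        # exactly at each boundary -> removed
        n_genes = 6100
        counts = np.zeros((4, n_genes))
        counts[0, :200] = 10  # exactly 200 genes: removed
        counts[1, :6000] = 1  # exactly 6000 genes: removed
        counts[2, :300] = np.r_[[1000 - 299], np.ones(299)]  # 1000 UMI: removed
        counts[3, :500] = 4  # 2000 UMI; 20% mito via first gene
        counts[3, 0] = 499 + (counts[3, 1:].sum() / 4)
        genes = ["MT-1"] + [f"g{i}" for i in range(n_genes - 1)]
        a = _adata(counts, genes)
        rep = qc.qc_report(a)
        assert (rep["status"] == "fail").iloc[:3].all()
        out = qc.filter_cells(a)
        assert "c0" not in out.obs_names and "c1" not in out.obs_names
        assert "c2" not in out.obs_names

    def test_planted_violations_filtered_exactly(self, qc_fixture_100):
        adata, truth = qc_fixture_100
        out = qc.filter_cells(adata)
        assert out.n_obs == 90
        surv = truth.cells.loc[out.obs_names]
        assert (surv["qc_violation"] == "none").all()

    def test_idempotent(self, qc_fixture_100):
        adata, _ = qc_fixture_100
        once = qc.filter_cells(adata)
        twice = qc.filter_cells(once)
        assert list(once.obs_names) == list(twice.obs_names)


class TestLogNormalize:
    def test_closed_form(self):
        counts = np.array([[5.0, 9995.0]])
        out = qc.log_normalize(_adata(counts), scale_factor=10_000)
        nm = np.asarray(sp.csr_matrix(out.layers["lognorm"]).todense())
        assert nm[0, 0] == pytest.approx(np.log(6.0), abs=1e-12)
        assert (np.asarray(sp.csr_matrix(out.X).todense()) == counts).all()

    def test_zero_count_stays_zero_and_values_nonnegative(self, rng):
        counts = rng.poisson(1.0, size=(20, 30)).astype(float)
        counts[:, 0] = 0
        counts[:, 1] = 1  # keep totals positive
        out = qc.log_normalize(_adata(counts))
        nm = np.asarray(sp.csr_matrix(out.layers["lognorm"]).todense())
        assert (nm[:, 0] == 0).all() and (nm >= 0).all()

    def test_depth_invariance_within_cell(self, rng):
        counts = rng.poisson(2.0, size=(1, 50)).astype(float) + 1
        a = qc.log_normalize(_adata(counts))
        b = qc.log_normalize(_adata(2 * counts))
        np.testing.assert_allclose(
            np.asarray(sp.csr_matrix(a.layers["lognorm"]).todense()),
            np.asarray(sp.csr_matrix(b.layers["lognorm"]).todense()),
        )

    def test_commutes_with_cell_subsetting(self, rng):
        counts = rng.poisson(3.0, size=(10, 40)).astype(float) + 1
        full = qc.log_normalize(_adata(counts))
        sub = qc.log_normalize(_adata(counts)[::2].copy())
        np.testing.assert_allclose(
            np.asarray(sp.csr_matrix(full.layers["lognorm"]).todense())[::2],
            np.asarray(sp.csr_matrix(sub.layers["lognorm"]).todense()),
        )

    def test_zero_total_cell_is_error(self):
        counts = np.zeros((2, 5))
        counts[0, 0] = 1
        with pytest.raises(DataError):
            qc.log_normalize(_adata(counts))


class TestVariableGenes:
    def _norm(self, rng, n=300, g=60):
        # half the genes overdispersed, half Poisson-like
        base = rng.poisson(2.0, size=(n, g)).astype(float)
        base[:, : g // 2] *= rng.integers(1, 6, size=(n, g // 2))
        base[:, -1] = 1  # keep totals positive
        return qc.log_normalize(_adata(base))

    def test_bounds_and_truncation(self, rng):
        a = self._norm(rng)
        res = qc.select_variable_genes(a, min_mean=0.0125, max_mean=10, n_top=10)
        assert len(res) <= 10
        assert (res["mean"] > 0.0125).all() and (res["dispersion_norm"] > 0.5).all()
        assert res["dispersion_norm"].is_monotonic_decreasing

    def test_mean_cutoffs_exclude(self, rng):
        a = self._norm(rng)
        all_res = qc.select_variable_genes(
            a, min_mean=0.0, max_mean=np.inf, min_dispersion=-np.inf, n_top=1000
        )
        lo, hi = all_res["mean"].min(), all_res["mean"].max()
        res = qc.select_variable_genes(
            a, min_mean=lo + 1e-9, max_mean=hi - 1e-9,
            min_dispersion=-np.inf, n_top=1000,
        )
        assert all_res["mean"].idxmin() not in res.index
        assert all_res["mean"].idxmax() not in res.index

    def test_no_passing_gene_is_error(self, rng):
        a = self._norm(rng)
        with pytest.raises(DataError):
            qc.select_variable_genes(a, min_dispersion=1e9)


class TestCommonVariableFeatures:
    def test_hand_intersection(self):
        out = qc.common_variable_features(
            [["A", "B", "C"], ["B", "C", "D"], ["C", "B", "E"]]
        )
        assert set(out) == {"B", "C"}

    def test_identity_and_order_invariance(self):
        s = ["X", "Y", "Z"]
        assert qc.common_variable_features([s, s, s]) == s
        a, b = ["A", "B", "C"], ["C", "B", "A"]
        assert set(qc.common_variable_features([a, b])) == set(
            qc.common_variable_features([b, a])
        )

    def test_disjoint_sets_error(self):
        with pytest.raises(DataError):
            qc.common_variable_features([["A"], ["B"]])


class TestPCA:
    def test_rank_two_data(self, rng):
        u = rng.normal(size=(100, 2))
        v = rng.normal(size=(2, 20))
        counts = np.exp(u @ v)  # rank-2 in log space after scaling
        a = qc.log_normalize(_adata(counts))
        feats = list(a.var_names)
        _, var = qc.scale_and_pca(a, feats, n_pcs=10)
        assert np.all(np.diff(var) <= 1e-9)

    def test_embedding_preserves_blob_separation(self, rng):
        n = 100
        counts = rng.poisson(2.0, size=(2 * n, 30)).astype(float) + 1
        counts[n:, :10] += 40
        a = qc.log_normalize(_adata(counts))
        emb, _ = qc.scale_and_pca(a, list(a.var_names), n_pcs=5)
        d = np.linalg.norm(emb[:n].mean(0) - emb[n:].mean(0))
        within = emb[:n].std(0).mean()
        assert d > 5 * within

    def test_sign_invariant_to_gene_order(self, rng):
        counts = rng.poisson(3.0, size=(50, 20)).astype(float) + 1
        a = qc.log_normalize(_adata(counts))
        perm = list(rng.permutation(list(a.var_names)))
        e1, _ = qc.scale_and_pca(a, list(a.var_names), n_pcs=3)
        e2, _ = qc.scale_and_pca(a, perm, n_pcs=3)
        for j in range(3):
            r = abs(np.corrcoef(e1[:, j], e2[:, j])[0, 1])
            assert r > 1 - 1e-8

    def test_elbow_on_synthetic_scree(self):
        scree = np.r_[np.array([100, 60, 30]), 2 * 0.95 ** np.arange(17)]
        assert qc.find_elbow(scree) in (3, 4)


class TestSnnCluster:
    def test_two_blobs(self, rng):
        emb = np.vstack(
            [rng.normal(0, 1, size=(200, 5)), rng.normal(10, 1, size=(200, 5))]
        )
        labels = qc.snn_cluster(emb, k_neighbors=20, resolution=0.8, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:200])) == 1 and len(np.unique(labels[200:])) == 1

    def test_identical_cells_one_cluster(self):
        emb = np.ones((50, 3))
        labels = qc.snn_cluster(emb, k_neighbors=10, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic_given_seed(self, rng):
        emb = rng.normal(size=(120, 4))
        l1 = qc.snn_cluster(emb, k_neighbors=10, seed=5)
        l2 = qc.snn_cluster(emb, k_neighbors=10, seed=5)
        assert (l1 == l2).all()

    def test_too_few_cells_error(self):
        with pytest.raises(DataError):
            qc.snn_cluster(np.zeros((5, 2)), k_neighbors=2)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_filter_cells_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rng.uniform(0, 3), size=(30, 50)).astype(float)
    a = _adata(counts)
    once = qc.filter_cells(a, min_genes=5, max_genes=45, min_umi=10, max_mito=0.5)
    twice = qc.filter_cells(once, min_genes=5, max_genes=45, min_umi=10, max_mito=0.5)
    assert list(once.obs_names) == list(twice.obs_names)
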