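"""Single-cell QC, normalization, PCA, clustering, annotation and DE calling."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from sctargetmr import (
    EmptyResultError,
    annotate_clusters,
    cluster_cells,
    find_all_markers,
    find_degs,
    log_normalize,
    qc_filter,
    run_pca,
    simulate_sc_counts,
)

from conftest import MARKER_SETS, make_gene_names


def counts_adata(X, mito_flags=None, conditions=None):
    X = np.asarray(X)
    n_cells, n_genes = X.shape
    genes = [f"g{j + 1}" for j in range(n_genes)]
    obs = pd.DataFrame(index=[f"c{i + 1}" for i in range(n_cells)])
    if conditions is not None:
        obs["condition"] = conditions
    var = pd.DataFrame({"mito": mito_flags if mito_flags is not None
                        else [False] * n_genes}, index=genes)
    return ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)


class TestQCFilter:
    def test_cell_detected_gene_boundary(self):
        # 300 genes; 3 dense support cells keep every gene detected in >= 3 cells
        n_genes = 300
        dense = np.ones((3, n_genes))
        cell_250 = np.zeros(n_genes); cell_250[:250] = 1
        cell_249 = np.zeros(n_genes); cell_249[:249] = 1
        adata = counts_adata(np.vstack([dense, cell_250, cell_249]))
        kept = qc_filter(adata, min_genes_per_cell=250)
        assert "c4" in kept.obs_names      # 250 detected genes: retained
        assert "c5" not in kept.obs_names  # 249: removed

    def test_gene_detection_boundary(self):
        # column detected in exactly 3 cells retained, in 2 cells removed
        X = np.zeros((5, 4))
        X[:, 0] = 1                      # detected in 5
        X[:3, 1] = 1                     # detected in 3 -> retained
        X[:2, 2] = 1                     # detected in 2 -> removed
        X[:, 3] = [1, 2, 3, 4, 5]        # detected in 5
        adata = counts_adata(X)
        kept = qc_filter(adata, min_genes_per_cell=1)
        assert list(kept.var_names) == ["g1", "g2", "g4"]

    def test_six_by_six_toy_hand_enumeration(self):
        """Hand-counted toy: the mito-heavy cell and the shallow cell fall out,
        the two singleton/doubleton genes fall out first."""
        #        G1 G2 G3 G4 G5 MT1
        X = np.array([
            [5, 3, 2, 0, 0, 1],   # c1: mito 1/11 < 0.10 -> kept
            [4, 2, 1, 0, 0, 0],   # c2: kept
            [3, 1, 0, 1, 0, 7],   # c3: mito 7/11 after gene filter -> removed
            [2, 2, 3, 0, 1, 0],   # c4: kept (G5 removed first, 3 genes remain)
            [5, 3, 2, 0, 0, 1],   # c5: kept
            [0, 1, 1, 0, 2, 0],   # c6: only 2 detected after G5 removed -> removed
        ])
        mito = [False] * 5 + [True]
        adata = counts_adata(X, mito_flags=mito)
        kept = qc_filter(adata, min_cells_per_gene=3, min_genes_per_cell=3,
                         max_mito_fraction=0.10)
        assert list(kept.obs_names) == ["c1", "c2", "c4", "c5"]
        assert list(kept.var_names) == ["g1", "g2", "g3", "g6"]

    def test_idempotent_on_planted_data(self, planted_sc):
        adata, _ = planted_sc
        once = qc_filter(adata, min_genes_per_cell=150)
        twice = qc_filter(once, min_genes_per_cell=150)
        assert list(twice.obs_names) == list(once.obs_names)
        assert list(twice.var_names) == list(once.var_names)

    def test_everything_removed_raises(self):
        adata = counts_adata(np.ones((4, 10)))
        with pytest.raises(EmptyResultError):
            qc_filter(adata, min_genes_per_cell=50)


class TestLogNormalize:
    def test_zero_counts_stay_zero(self, planted_sc):
        adata, _ = planted_sc
        norm = log_normalize(adata)
        raw = adata.X.toarray()
        val = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X)
        assert np.all(val[raw == 0] == 0)
        assert np.all(val[raw > 0] > 0)

    def test_count_equal_to_total_scale_one(self):
        # a cell expressing a single gene: value = ln(1 + 1 * c/c) = ln 2
        X = np.array([[7, 0], [3, 4]])
        norm = log_normalize(counts_adata(X), scale_factor=1.0)
        val = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X)
        assert val[0, 0] == pytest.approx(np.log(2))

    def test_arithmetic_fixture(self):
        # counts 2 of total 100 at scale 1e4 -> ln(1 + 1e4*2/100) = ln(201)
        X = np.zeros((1, 3)); X[0] = [2, 49, 49]
        norm = log_normalize(counts_adata(X), scale_factor=1e4)
        val = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X)
        assert val[0, 0] == pytest.approx(np.log(201))


class TestPCA:
    def test_rank_one_matrix_first_component_dominates(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.uniform(1, 5, 40), rng.uniform(0.5, 2, 25))
        adata = counts_adata(X)
        scores = run_pca(adata, n_components=5, n_hvg=None)
        var = scores.var(axis=0)
        assert var[0] / var.sum() > 0.99

    def test_score_covariance_orthogonal(self):
        rng = np.random.default_rng(1)
        adata = counts_adata(rng.poisson(3, size=(100, 30)))
        scores = run_pca(adata, n_components=8, n_hvg=None)
        cov = np.cov(scores.T)
        off = cov[~np.eye(8, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-8

    def test_agrees_with_dense_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(10, 3, size=(30, 20))
        adata = counts_adata(X)
        scores = run_pca(adata, n_components=10, n_hvg=None)
        # oracle: eigen-decompose the covariance of the standardized matrix
        Z = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(np.cov(Z.T, ddof=0))
        order = np.argsort(evals)[::-1]
        oracle = Z @ evecs[:, order[:10]]
        for j in range(10):
            r = np.corrcoef(scores[:, j], oracle[:, j])[0, 1]
            assert abs(r) > 0.999

    def test_too_many_components_rejected(self):
        adata = counts_adata(np.ones((5, 4)))
        with pytest.raises(Exception):
            run_pca(adata, n_components=10, n_hvg=None)


class TestClustering:
    def test_two_separated_blobs_perfectly_recovered(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(0, 1, size=(100, 5))
        blob2 = rng.normal(20, 1, size=(100, 5))
        labels = cluster_cells(np.vstack([blob1, blob2]), resolution=0.5, seed=0)
        truth = [0] * 100 + [1] * 100
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_blob_low_resolution_one_cluster(self):
        rng = np.random.default_rng(1)
        labels = cluster_cells(rng.normal(0, 1, size=(150, 5)),
                               resolution=0.01, seed=0)
        assert len(set(labels)) == 1

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1, size=(120, 6))
        a = cluster_cells(scores, resolution=1.0, seed=3)
        b = cluster_cells(scores, resolution=1.0, seed=3)
        assert np.array_equal(a, b)

    def test_two_planted_types_recovered(self):
        gene_names = make_gene_names(500)
        adata, _ = simulate_sc_counts(
            cells_per_type={"A": 200, "B": 200}, n_genes=500,
            markers={"A": MARKER_SETS["A"], "B": MARKER_SETS["B"]},
            gene_names=gene_names, seed=7)
        norm = log_normalize(adata)
        scores = run_pca(norm, n_components=20, n_hvg=None, seed=0)
        labels = cluster_cells(scores, resolution=0.3, seed=0)
        assert len(set(labels)) == 2
        assert adjusted_rand_score(adata.obs["true_cell_type"], labels) > 0.9

    def test_four_planted_types_recovered(self, planted_sc_norm):
        norm, _ = planted_sc_norm
        scores = run_pca(norm, n_components=20, n_hvg=None, seed=0)
        labels = cluster_cells(scores, resolution=0.3, seed=0)
        assert adjusted_rand_score(norm.obs["true_cell_type"], labels) > 0.9


class TestAnnotation:
    def test_planted_types_all_correctly_labeled(self, planted_sc_norm):
        norm, _ = planted_sc_norm
        scores = run_pca(norm, n_components=20, n_hvg=None, seed=0)
        labels = cluster_cells(scores, resolution=0.3, seed=0)
        assignment = annotate_clusters(labels, norm, MARKER_SETS)
        truth = norm.obs["true_cell_type"].to_numpy()
        called = assignment.cell_types
        assert (called == truth).mean() > 0.95

    def test_empty_marker_set_never_assigned(self, planted_sc_norm):
        norm, _ = planted_sc_norm
        labels = np.zeros(norm.n_obs, dtype=int)
        assignment = annotate_clusters(labels, norm, {"ghost": []})
        assert assignment.cluster_types[0] == "unassigned"

    def test_exclusive_marker_expression_wins(self):
        # cluster 0 expresses only type-A markers, cluster 1 only type-B
        X = np.zeros((20, 4))
        X[:10, :2] = 5
        X[10:, 2:] = 5
        adata = counts_adata(X)
        adata.var_names = ["a1", "a2", "b1", "b2"]
        norm = log_normalize(adata)
        assignment = annotate_clusters(
            np.array([0] * 10 + [1] * 10), norm,
            {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert assignment.cluster_types == {0: "A", 1: "B"}


class TestFindAllMarkers:
    def test_flat_gene_is_not_a_marker(self):
        # normalized values: g2 and g3 identical in every cell, g1 differs
        X = np.full((40, 3), np.log1p(5.0))
        X[:20, 0] = np.log1p(50.0)
        out = find_all_markers(counts_adata(X), np.array([0] * 20 + [1] * 20))
        assert "g2" not in set(out["gene"])
        assert "g3" not in set(out["gene"])
        assert "g1" in set(out["gene"])

    def test_exclusive_gene_is_a_marker(self):
        X = np.ones((40, 3))
        X[:20, 0] = 60
        X[20:, 0] = 0
        norm = log_normalize(counts_adata(X))
        out = find_all_markers(norm, np.array([0] * 20 + [1] * 20))
        sub = out[(out["gene"] == "g1") & (out["cell_type"] == "0")]
        assert len(sub) == 1 and sub.iloc[0]["log2fc"] > 0

    def test_planted_markers_fully_recovered(self):
        """Noise-free planted data: marker recovery rate 1.0."""
        gene_names = make_gene_names(300)
        adata, _ = simulate_sc_counts(
            cells_per_type={"A": 80, "B": 80, "C": 80}, n_genes=300,
            markers={t: MARKER_SETS[t] for t in "ABC"},
            nb_dispersion=0.0, gene_names=gene_names, seed=7)
        norm = log_normalize(adata)
        types = adata.obs["true_cell_type"].to_numpy()
        labels = pd.Categorical(types).codes
        out = find_all_markers(norm, labels)
        name_of = dict(enumerate(pd.Categorical(types).categories))
        for t in "ABC":
            cluster = str([k for k, v in name_of.items() if v == t][0])
            found = set(out.loc[out["cell_type"] == cluster, "gene"])
            assert set(MARKER_SETS[t]) <= found


class TestFindDEGs:
    def test_planted_de_gene_detected(self, planted_sc_norm):
        norm, truth = planted_sc_norm
        out = find_degs(norm, norm.obs["true_cell_type"].to_numpy())
        hit = out[(out["gene"] == "SG0001") & (out["cell_type"] == "B")]
        assert len(hit) == 1
        assert hit.iloc[0]["log2fc"] > 0.5
        assert hit.iloc[0]["padj"] <= 0.05
        assert hit.iloc[0]["padj"] >= hit.iloc[0]["pval"]

    def test_boundary_log2fc_excluded_regardless_of_p(self):
        # perfectly separated groups but |log2fc| = 0.29 < 0.3 -> never a DEG
        m2 = 1.0
        m1 = (m2 + 1) * 2 ** 0.29 - 1
        case = np.full((30, 2), np.log1p(m1)); case[:, 1] = np.log1p(5.0)
        ctrl = np.full((30, 2), np.log1p(m2)); ctrl[:, 1] = np.log1p(5.0)
        adata = counts_adata(np.vstack([case, ctrl]),
                             conditions=["case"] * 30 + ["control"] * 30)
        out = find_degs(adata, np.array(["T"] * 60))
        assert "g1" not in set(out["gene"])

    def test_permuted_labels_fdr_controlled(self, planted_sc_norm):
        norm, _ = planted_sc_norm
        types = norm.obs["true_cell_type"].to_numpy()
        cond = norm.obs["condition"].to_numpy().astype(str)
        false_calls = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            out = find_degs(norm, types, conditions=rng.permutation(cond))
            false_calls += len(out)
        # 3 permutations x 500 genes x 4 types: essentially nothing should pass
        assert false_calls / (3 * norm.n_vars) <= 0.05

    def test_invariant_to_gene_and_cell_permutation(self, planted_sc_norm):
        norm, _ = planted_sc_norm
        types = norm.obs["true_cell_type"].to_numpy()
        base = find_degs(norm, types)
        rng = np.random.default_rng(0)
        gi = rng.permutation(norm.n_vars)
        ci = rng.permutation(norm.n_obs)
        shuffled = norm[ci, gi].copy()
        out = find_degs(shuffled, types[ci])
        pd.testing.assert_frame_equal(
            base.reset_index(drop=True), out.reset_index(drop=True),
            check_exact=False, atol=1e-12)
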