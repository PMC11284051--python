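"""Single-cell QC, normalization, clustering, annotation and DE calling.

The in-memory container is :class:`anndata.AnnData` with raw integer counts
in ``X``, per-cell ``obs`` columns ``donor`` and ``condition`` (control/case)
and a boolean ``var['mito']`` flag.  The stage order mirrors the standard
droplet workflow: QC filtering (genes before cells), library-size
log-normalization, per-gene standardization + PCA on highly variable genes,
Leiden community detection on a nearest-neighbour graph of the PC scores,
marker-based cluster annotation, then cluster-vs-rest marker discovery and
within-cell-type case/control differential expression by Wilcoxon rank-sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError, ParameterError

DEG_COLUMNS = ["gene", "cell_type", "log2fc", "pct_group1", "pct_group2", "pval", "padj"]

#: pseudocount used in the fold-change ratio (Seurat-style, documented)
_FC_PSEUDO = 1.0 + 1e-9


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus the per-cluster annotated cell type."""

    labels: np.ndarray
    cluster_types: dict

    @property
    def cell_types(self) -> np.ndarray:
        return np.array([self.cluster_types.get(int(c), "unassigned") for c in self.labels])


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    adata: ad.AnnData,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 250,
    max_mito_fraction: float = 0.10,
) -> ad.AnnData:
    """Remove undetected genes, shallow cells and mitochondria-heavy cells.

    Genes detected (count > 0) in fewer than ``min_cells_per_gene`` cells are
    dropped first; then cells with fewer than ``min_genes_per_cell`` detected
    genes, or with a mitochondrial count fraction of ``max_mito_fraction`` or
    more, are dropped.  Boundaries follow the stated rules: a cell at exactly
    the gene minimum is retained, a gene detected in exactly the cell minimum
    is retained, and the mitochondrial cut is "strictly less than".
    """
    if "mito" not in adata.var.columns:
        raise ParameterError("adata.var must carry a boolean 'mito' flag")
    X = adata.X
    detected_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    keep_genes = detected_cells >= min_cells_per_gene
    out = adata[:, keep_genes].copy()
    if out.n_vars == 0:
        raise EmptyResultError("QC removed every gene")

    Xg = out.X
    genes_per_cell = np.asarray((Xg > 0).sum(axis=1)).ravel()
    totals = np.asarray(Xg.sum(axis=1)).ravel().astype(float)
    mito_mask = out.var["mito"].to_numpy(bool)
    mito_counts = np.asarray(Xg[:, mito_mask].sum(axis=1)).ravel().astype(float) \
        if mito_mask.any() else np.zeros(out.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
    keep_cells = (genes_per_cell >= min_genes_per_cell) & (mito_frac < max_mito_fraction)
    out = out[keep_cells].copy()
    if out.n_obs == 0:
        raise EmptyResultError("QC removed every cell")
    return out


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalization: ``ln(1 + scale_factor * count / cell_total)``.

    Returns a copy with the normalized values in ``X`` and the raw counts
    preserved in ``layers['counts']``.  Zero counts stay exactly zero.
    """
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be > 0")
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    sc.pp.normalize_total(out, target_sum=scale_factor)
    sc.pp.log1p(out)
    return out


# ---------------------------------------------------------------------------
# dimensionality reduction and clustering
# ---------------------------------------------------------------------------

def run_pca(
    adata_norm: ad.AnnData,
    n_components: int = 31,
    n_hvg: int | None = 2000,
    seed: int = 0,
) -> np.ndarray:
    """PC scores of the per-gene standardized normalized matrix.

    When the matrix carries more than ``n_hvg`` genes, the top ``n_hvg`` by
    standardized dispersion are selected first.  Components are ordered by
    decreasing explained variance.  Uses the deterministic full-SVD solver.
    """
    work = adata_norm.copy()
    if n_hvg is not None and work.n_vars > n_hvg:
        sc.pp.highly_variable_genes(work, n_top_genes=n_hvg, flavor="seurat")
        work = work[:, work.var["highly_variable"]].copy()
    if n_components > min(work.n_obs, work.n_vars):
        raise ParameterError("n_components exceeds min(cells, genes)")
    X = _dense(work.X).astype(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    return pca.fit_transform(Z)


def cluster_cells(
    scores: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a nearest-neighbour graph of PC scores.

    Deterministic for a fixed seed; every cell receives an integer label.
    """
    scores = np.asarray(scores, dtype=float)
    n_cells = scores.shape[0]
    if n_cells < 2:
        raise ParameterError("need at least 2 cells to cluster")
    if resolution <= 0:
        raise ParameterError("resolution must be > 0")
    n_neighbors = min(n_neighbors, n_cells - 1)
    tmp = ad.AnnData(X=np.zeros((n_cells, 1), dtype=float))
    tmp.obsm["X_pca"] = scores
    sc.pp.neighbors(tmp, n_neighbors=n_neighbors, use_rep="X_pca", random_state=seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            tmp, resolution=resolution, key_added="leiden", random_state=seed,
            flavor="leidenalg", directed=False, n_iterations=2,
        )
    return tmp.obs["leiden"].astype(int).to_numpy()


def annotate_clusters(
    labels: np.ndarray,
    adata_norm: ad.AnnData,
    marker_sets: dict,
    min_margin: float = 0.0,
) -> ClusterAssignment:
    """Assign each cluster the marker set with the highest mean scaled expression.

    Marker expression is z-scored per gene across all cells, then averaged
    over each cluster and each type's marker genes.  A cluster whose
    best-vs-second-best score margin falls below ``min_margin`` (or whose
    best score is undefined, e.g. empty marker set) is left "unassigned".
    """
    labels = np.asarray(labels)
    X = _dense(adata_norm.X).astype(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    gene_index = {g: i for i, g in enumerate(adata_norm.var_names)}

    cluster_types: dict[int, str] = {}
    for cl in np.unique(labels):
        in_cl = labels == cl
        scores = {}
        for cell_type, genes in marker_sets.items():
            idx = [gene_index[g] for g in genes if g in gene_index]
            if not idx:
                continue  # empty (or fully absent) marker set: never assigned
            scores[cell_type] = float(Z[np.ix_(in_cl, idx)].mean())
        if not scores:
            cluster_types[int(cl)] = "unassigned"
            continue
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        best_type, best = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else -np.inf
        cluster_types[int(cl)] = best_type if best - second >= min_margin else "unassigned"
    return ClusterAssignment(labels=labels, cluster_types=cluster_types)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _log2fc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Seurat-style fold change of mean de-logged expression, pseudocount 1."""
    m1 = np.expm1(x).mean(axis=0)
    m2 = np.expm1(y).mean(axis=0)
    return np.log2((m1 + _FC_PSEUDO) / (m2 + _FC_PSEUDO))


def _ranksum_de(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values per gene (columns)."""
    res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)  # constant genes: no evidence


def _de_frame(adata_norm, mask1, mask2, group_name) -> pd.DataFrame:
    X = _dense(adata_norm.X).astype(float)
    x, y = X[mask1], X[mask2]
    pct1 = (x > 0).mean(axis=0)
    pct2 = (y > 0).mean(axis=0)
    lfc = _log2fc(x, y)
    pval = _ranksum_de(x, y)
    padj = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": list(adata_norm.var_names), "cell_type": group_name,
        "log2fc": lfc, "pct_group1": pct1, "pct_group2": pct2,
        "pval": pval, "padj": np.maximum(padj, pval),
    }, columns=DEG_COLUMNS)


def find_all_markers(
    adata_norm: ad.AnnData,
    labels: np.ndarray,
    min_abs_log2fc: float = 0.25,
    min_pct: float = 0.25,
) -> pd.DataFrame:
    """Cluster-vs-rest marker genes.

    A gene is reported for a cluster when ``|log2FC| >= min_abs_log2fc`` and
    the detection fraction in at least one of the two populations reaches
    ``min_pct``.  Rank-sum p-values and BH-adjusted values are reported but
    not filtered on.
    """
    labels = np.asarray(labels)
    frames = []
    for cl in np.unique(labels):
        in_cl = labels == cl
        if in_cl.all() or not in_cl.any():
            continue
        df = _de_frame(adata_norm, in_cl, ~in_cl, str(cl))
        keep = (np.abs(df["log2fc"]) >= min_abs_log2fc) & \
               (np.maximum(df["pct_group1"], df["pct_group2"]) >= min_pct)
        frames.append(df[keep])
    if not frames:
        return pd.DataFrame(columns=DEG_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["cell_type", "pval", "gene"], kind="mergesort").reset_index(drop=True)


def find_degs(
    adata_norm: ad.AnnData,
    cell_types: np.ndarray,
    conditions: np.ndarray | None = None,
    min_abs_log2fc: float = 0.3,
    min_pct: float = 0.25,
    max_padj: float = 0.05,
) -> pd.DataFrame:
    """Case-vs-control differential expression within each annotated cell type.

    Group 1 is "case".  Thresholds follow the stated rules strictly:
    ``|log2FC| > min_abs_log2fc``, detection fraction ``> min_pct`` in at
    least one group, and BH-adjusted p-value ``<= max_padj`` (adjustment
    within each cell type).  Cells typed "unassigned" are skipped.
    """
    cell_types = np.asarray(cell_types)
    if conditions is None:
        conditions = adata_norm.obs["condition"].to_numpy()
    conditions = np.asarray(conditions).astype(str)
    bad = set(np.unique(conditions)) - {"case", "control"}
    if bad:
        raise ParameterError(f"conditions must be case/control, got extras {sorted(bad)}")
    frames = []
    for ct in sorted(set(cell_types) - {"unassigned"}):
        in_type = cell_types == ct
        case = in_type & (conditions == "case")
        control = in_type & (conditions == "control")
        if not case.any() or not control.any():
            continue
        df = _de_frame(adata_norm, case, control, ct)
        keep = (np.abs(df["log2fc"]) > min_abs_log2fc) & \
               (np.maximum(df["pct_group1"], df["pct_group2"]) > min_pct) & \
               (df["padj"] <= max_padj)
        frames.append(df[keep])
    if not frames:
        return pd.DataFrame(columns=DEG_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["cell_type", "pval", "gene"], kind="mergesort").reset_index(drop=True)
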