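"""Shared fixtures: small planted single-cell datasets and instrument tables."""

import numpy as np
import pandas as pd
import pytest

from sctargetmr import log_normalize, qc_filter, simulate_sc_counts

MARKER_SETS = {
    "A": ["MKA1", "MKA2", "MKA3"],
    "B": ["MKB1", "MKB2", "MKB3"],
    "C": ["MKC1", "MKC2", "MKC3"],
    "D": ["MKD1", "MKD2", "MKD3"],
}


def make_gene_names(n_genes, n_mito=2, extra=()):
    named = [f"MT-{i + 1}" for i in range(n_mito)]
    named += [m for ms in MARKER_SETS.values() for m in ms]
    named += list(extra)
    return named + [f"SG{i + 1:04d}" for i in range(n_genes - len(named))]


def make_hset(bx, sx, by, sy, eaf=0.3):
    """Assemble a harmonized instrument table from effect arrays."""
    bx = np.asarray(bx, float)
    k = len(bx)
    return pd.DataFrame({
        "snp": [f"v{i + 1}" for i in range(k)],
        "chr": "1",
        "pos": (np.arange(k) + 1) * 10_000_000,
        "ea": "A", "oa": "G",
        "beta_exposure": bx,
        "se_exposure": np.broadcast_to(np.asarray(sx, float), (k,)).copy(),
        "beta_outcome": np.asarray(by, float),
        "se_outcome": np.broadcast_to(np.asarray(sy, float), (k,)).copy(),
        "eaf": eaf, "flipped": False,
        "excluded_reason": pd.Series([None] * k, dtype=object),
    })


@pytest.fixture(scope="session")
def planted_sc():
    """400 cells in 4 planted types, 500 genes, one DE gene, 10% low-quality cells."""
    gene_names = make_gene_names(500)
    adata, truth = simulate_sc_counts(
        cells_per_type={t: 100 for t in "ABCD"},
        n_genes=500,
        markers=MARKER_SETS,
        de_genes={"B": [["SG0001", 1.5]]},
        lowq_cell_fraction=0.10,
        gene_names=gene_names,
        anchor_genes={"SG0001": 2.0},
        seed=7,
    )
    return adata, truth


@pytest.fixture(scope="session")
def planted_sc_norm(planted_sc):
    """QC-filtered and log-normalized version of the planted matrix."""
    adata, truth = planted_sc
    q = qc_filter(adata, min_genes_per_cell=150)
    return log_normalize(q), truth
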