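"""Pipeline configuration.

One flat YAML file configures one run.  Every default equals the study's
stated value where one exists (QC cuts, DEG thresholds, instrument p-value
and clumping settings per QTL class, coloc priors and flank, PheWAS alpha);
the ``synthetic`` mapping describes the simulated study the pipeline runs
end-to-end, with a bundled default scenario that plants one true target,
one distinct-causal-variant (H3) decoy and one pleiotropic (PheWAS) decoy.
Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ParameterError, ParseError


def default_synthetic_scenario() -> dict:
    """The bundled end-to-end demo scenario."""
    return {
        # single-cell study
        "n_genes": 1000,
        "cell_types": ["Tcell", "Bcell", "NKcell", "Monocyte"],
        "cells_per_type": 200,
        "n_markers_per_type": 6,
        "n_donors_per_condition": 2,
        "nb_dispersion": 0.4,
        "mito_gene_fraction": 0.03,
        "lowq_cell_fraction": 0.06,
        "candidate_base_mean": 2.0,
        # per-gene cis loci
        "locus_n_variants": 200,
        "locus_decay": 0.9,
        "cohort_n": 4000,
        "gwas_type": "case_control",
        "exposure_effect": 0.5,
        "outcome_effect": -0.25,
        "h3_gap": 6,
        # PheWAS emulation
        "phewas_n_traits": 400,
        "phewas_background_p_floor": 1e-6,
        # candidate genes and their planted roles
        "genes": [
            {"name": "SYTG1", "role": "true_target", "cell_type": "Bcell", "log2fc": -1.8},
            {"name": "SYDC2", "role": "h3_decoy", "cell_type": "Tcell", "log2fc": 1.8},
            {"name": "SYPH3", "role": "phewas_decoy", "cell_type": "Monocyte", "log2fc": 1.6},
            {"name": "SYNU4", "role": "no_gwas", "cell_type": "NKcell", "log2fc": 1.6},
            {"name": "SYQU5", "role": "not_de", "cell_type": "Tcell", "log2fc": 0.0},
        ],
    }


_ROLE_TO_LOCUS = {
    "true_target": "shared",
    "phewas_decoy": "shared",
    "h3_decoy": "distinct",
    "no_gwas": "exposure_only",
    "not_de": "exposure_only",
}


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run."""

    # single-cell QC / normalization / clustering
    qc_min_cells_per_gene: int = 3
    qc_min_genes_per_cell: int = 250
    qc_max_mito_fraction: float = 0.10
    normalize_scale_factor: float = 1e4
    n_pcs: int = 31
    n_hvg: int = 2000
    cluster_n_neighbors: int = 15
    cluster_resolution: float = 1.0
    annotate_min_margin: float = 0.0
    mito_prefix: str = "MT-"
    # marker / DEG thresholds
    marker_min_abs_log2fc: float = 0.25
    marker_min_pct: float = 0.25
    deg_min_abs_log2fc: float = 0.3
    deg_min_pct: float = 0.25
    deg_max_padj: float = 0.05
    # instrument selection (per QTL class) and harmonization
    eqtl_p_threshold: float = 5e-8
    eqtl_clump_r2: float = 0.001
    pqtl_p_threshold: float = 5e-8
    pqtl_clump_r2: float = 0.01
    clump_window_kb: float = 10000.0
    palindromic_eaf_limit: float = 0.42
    # MR
    mr_significance: float = 0.05
    wmedian_n_boot: int = 1000
    mr_random_effects: bool = False
    # colocalization
    coloc_flank_kb: float = 500.0
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_pp4_threshold: float = 0.8
    coloc_prior_sd_quant: float = 0.15
    coloc_prior_sd_cc: float = 0.2
    # PheWAS
    phewas_alpha: float = 2e-8
    disease_trait: str = "multiple sclerosis"
    # pipeline
    require_eqtl_support: bool = True
    seed: int = 1
    synthetic: dict = field(default_factory=default_synthetic_scenario)

    def __post_init__(self):
        for g in self.synthetic.get("genes", []):
            role = g.get("role")
            if role not in _ROLE_TO_LOCUS:
                raise ParameterError(f"unknown gene role {role!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            loc = f" line {mark.line + 1}, column {mark.column + 1}" if mark else ""
            raise ParseError(f"{path}:{loc}: invalid YAML: {exc}") from exc
        raw = raw or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def locus_role(self, gene_role: str) -> str:
        return _ROLE_TO_LOCUS[gene_role]
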