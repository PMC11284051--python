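qc_min_cells_per_gene: 3
qc_min_genes_per_cell: 250
qc_max_mito_fraction: 0.1
normalize_scale_factor: 10000.0
n_pcs: 31
n_hvg: 2000
cluster_n_neighbors: 15
cluster_resolution: 1.0
annotate_min_margin: 0.0
mito_prefix: MT-
marker_min_abs_log2fc: 0.25
marker_min_pct: 0.25
deg_min_abs_log2fc: 0.3
deg_min_pct: 0.25
deg_max_padj: 0.05
eqtl_p_threshold: 5.0e-08
eqtl_clump_r2: 0.001
pqtl_p_threshold: 5.0e-08
pqtl_clump_r2: 0.01
clump_window_kb: 10000.0
palindromic_eaf_limit: 0.42
mr_significance: 0.05
wmedian_n_boot: 1000
mr_random_effects: false
coloc_flank_kb: 500.0
coloc_p1: 0.0001
coloc_p2: 0.0001
coloc_p12: 1.0e-05
coloc_pp4_threshold: 0.8
coloc_prior_sd_quant: 0.15
coloc_prior_sd_cc: 0.2
phewas_alpha: 2.0e-08
disease_trait: multiple sclerosis
require_eqtl_support: true
seed: 1
synthetic:
  n_genes: 1000
  cell_types:
  - Tcell
  - Bcell
  - NKcell
  - Monocyte
  cells_per_type: 200
  n_markers_per_type: 6
  n_donors_per_condition: 2
  nb_dispersion: 0.4
  mito_gene_fraction: 0.03
  lowq_cell_fraction: 0.06
  candidate_base_mean: 2.0
  locus_n_variants: 200
  locus_decay: 0.9
  cohort_n: 4000
  gwas_type: case_control
  exposure_effect: 0.5
  outcome_effect: -0.25
  h3_gap: 6
  phewas_n_traits: 400
  phewas_background_p_floor: 1.0e-06
  genes:
  - name: SYTG1
    role: true_target
    cell_type: Bcell
    log2fc: -1.8
  - name: SYDC2
    role: h3_decoy
    cell_type: Tcell
    log2fc: 1.8
  - name: SYPH3
    role: phewas_decoy
    cell_type: Monocyte
    log2fc: 1.6
  - name: SYNU4
    role: no_gwas
    cell_type: NKcell
    log2fc: 1.6
  - name: SYQU5
    role: not_de
    cell_type: Tcell
    log2fc: 0.0
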