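"""End-to-end orchestration of the target-discovery cascade.

Stage order: simulate inputs → single-cell DEGs → eQTL-MR → pQTL-MR →
colocalization → PheWAS → target report.  Every stage reads and writes
plain-text tables under one output directory, so each can also be run on its
own through the CLI.  Candidate flow: DEGs are intersected with genes that
have eQTL instruments; only genes whose eQTL-MR reaches p < 0.05 proceed to
the pQTL stage (configurable); a gene reaches the top tier of the report iff
its pQTL-MR p < 0.05 AND the pQTL/GWAS region colocalizes (PP4 above the
threshold) AND its PheWAS verdict is clean.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import expression, instruments, mr, phewas, synthetic
from .config import PipelineConfig
from .errors import SCTargetMRError

logger = logging.getLogger("sctargetmr")

_FLOAT_FMT = "%.10g"


def _seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    state = np.random.SeedSequence(base_seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def _inputs(out_dir) -> Path:
    return Path(out_dir) / "inputs"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out_dir, seed: int | None = None) -> None:
    """Generate every pipeline input under ``out_dir/inputs`` with ground truth."""
    scn = config.synthetic
    base_seed = config.seed if seed is None else seed
    genes = scn["genes"]
    seeds = _seeds(base_seed, len(genes) * 2 + 1)
    inputs = _inputs(out_dir)
    (inputs / "sc").mkdir(parents=True, exist_ok=True)

    # --- single-cell study -------------------------------------------------
    cell_types = list(scn["cell_types"])
    n_genes = int(scn["n_genes"])
    n_mito = int(round(scn["mito_gene_fraction"] * n_genes))
    marker_names = {
        t: [f"MK{t}{i + 1}" for i in range(int(scn["n_markers_per_type"]))]
        for t in cell_types
    }
    candidate_names = [g["name"] for g in genes]
    named = [f"MT-{i + 1}" for i in range(n_mito)]
    for t in cell_types:
        named += marker_names[t]
    named += candidate_names
    if len(named) > n_genes:
        raise SCTargetMRError("synthetic n_genes too small for markers + candidates")
    gene_names = named + [f"SG{i + 1:04d}" for i in range(n_genes - len(named))]

    de_spec: dict[str, list] = {}
    for g in genes:
        if g["role"] != "not_de":
            de_spec.setdefault(g["cell_type"], []).append([g["name"], float(g["log2fc"])])
    adata, sc_truth = synthetic.simulate_sc_counts(
        cells_per_type={t: int(scn["cells_per_type"]) for t in cell_types},
        n_genes=n_genes,
        markers=marker_names,
        de_genes=de_spec,
        nb_dispersion=float(scn["nb_dispersion"]),
        mito_gene_fraction=float(scn["mito_gene_fraction"]),
        lowq_cell_fraction=float(scn["lowq_cell_fraction"]),
        n_donors_per_condition=int(scn["n_donors_per_condition"]),
        gene_names=gene_names,
        anchor_genes={n: float(scn.get("candidate_base_mean", 2.0)) for n in candidate_names},
        seed=seeds[0],
    )
    synthetic.write_cell_matrix(adata, inputs / "sc")
    marker_rows = [{"cell_type": t, "gene": g} for t in cell_types for g in marker_names[t]]
    _write(pd.DataFrame(marker_rows), inputs / "markers.tsv")
    logger.info("simulate: %d cells x %d genes across %d types",
                adata.n_obs, adata.n_vars, len(cell_types))

    # --- per-gene cis loci and the pooled GWAS ------------------------------
    gwas_frames = []
    truth_by_gene = {}
    for i, g in enumerate(genes):
        name = g["name"]
        res = synthetic.simulate_locus_triplet(
            role=config.locus_role(g["role"]),
            n_per_cohort=int(scn["cohort_n"]),
            n_variants=int(scn["locus_n_variants"]),
            decay=float(scn["locus_decay"]),
            exposure_effect=float(scn["exposure_effect"]),
            outcome_effect=float(scn["outcome_effect"]),
            gwas_type=scn["gwas_type"],
            h3_gap=int(scn["h3_gap"]),
            seed=seeds[1 + i],
        )
        chrom = str(i + 1)
        rename = {old: f"{name}_{old}" for old in res["ld"].snp_ids}
        for key in ("eqtl", "pqtl", "gwas"):
            df = res[key]
            df["snp"] = df["snp"].map(rename)
            df["chr"] = chrom
        ld = instruments.LDMatrix([rename[s] for s in res["ld"].snp_ids], res["ld"].r)
        instruments.write_sumstats(res["eqtl"], inputs / f"{name}_eqtl.tsv")
        instruments.write_sumstats(res["pqtl"], inputs / f"{name}_pqtl.tsv")
        ld.to_tsv(inputs / f"{name}_ld.tsv")
        gwas_frames.append(res["gwas"])
        t = res["truth"]
        truth_by_gene[name] = {
            "role": g["role"], "scenario": t.scenario,
            "causal_variant_ids": {k: [rename[s] for s in v]
                                   for k, v in t.causal_variant_ids.items()},
            "causal_effect": t.causal_effect,
        }
    instruments.write_sumstats(pd.concat(gwas_frames, ignore_index=True),
                               inputs / "gwas.tsv")

    # --- PheWAS panel --------------------------------------------------------
    phewas_frames = []
    for i, g in enumerate(genes):
        planted = []
        if config.locus_role(g["role"]) in ("shared", "distinct"):
            planted.append(("multiple sclerosis", 1e-12))
        if g["role"] == "phewas_decoy":
            planted.append(("rheumatoid arthritis", 1e-9))
        phewas_frames.append(synthetic.simulate_phewas_table(
            n_traits=int(scn["phewas_n_traits"]),
            planted=planted,
            background_p_floor=float(scn["phewas_background_p_floor"]),
            seed=seeds[1 + len(genes) + i],
            gene=g["name"],
        ))
    phewas.write_phewas(pd.concat(phewas_frames, ignore_index=True),
                        inputs / "phewas.tsv")

    truth = {"genes": truth_by_gene, "de_genes": sc_truth.de_genes}
    (inputs / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n")
    logger.info("simulate: wrote %d candidate loci + GWAS + PheWAS under %s",
                len(genes), inputs)


# ---------------------------------------------------------------------------
# stage: single-cell DEGs
# ---------------------------------------------------------------------------

def stage_sc_deg(config: PipelineConfig, out_dir, seed: int | None = None) -> pd.DataFrame:
    """QC → normalize → PCA → cluster → annotate → case/control DEGs per type."""
    out = Path(out_dir)
    inputs = _inputs(out_dir)
    base_seed = config.seed if seed is None else seed
    adata = synthetic.read_cell_matrix(inputs / "sc", mito_prefix=config.mito_prefix)
    n0 = adata.n_obs
    adata = expression.qc_filter(
        adata,
        min_cells_per_gene=config.qc_min_cells_per_gene,
        min_genes_per_cell=config.qc_min_genes_per_cell,
        max_mito_fraction=config.qc_max_mito_fraction,
    )
    logger.info("sc-deg: QC kept %d/%d cells and %d genes (min_genes=%d, mito<%.2f)",
                adata.n_obs, n0, adata.n_vars,
                config.qc_min_genes_per_cell, config.qc_max_mito_fraction)
    norm = expression.log_normalize(adata, scale_factor=config.normalize_scale_factor)
    scores = expression.run_pca(norm, n_components=min(config.n_pcs, min(norm.shape) ),
                                n_hvg=config.n_hvg, seed=base_seed)
    labels = expression.cluster_cells(
        scores, n_neighbors=config.cluster_n_neighbors,
        resolution=config.cluster_resolution, seed=base_seed)
    markers = pd.read_csv(inputs / "markers.tsv", sep="\t")
    marker_sets = {t: list(sub["gene"]) for t, sub in markers.groupby("cell_type")}
    assignment = expression.annotate_clusters(labels, norm, marker_sets,
                                              min_margin=config.annotate_min_margin)
    cell_types = assignment.cell_types
    logger.info("sc-deg: %d clusters annotated to %d types",
                len(set(labels)), len(set(cell_types) - {"unassigned"}))
    degs = expression.find_degs(
        norm, cell_types,
        conditions=norm.obs["condition"].to_numpy(),
        min_abs_log2fc=config.deg_min_abs_log2fc,
        min_pct=config.deg_min_pct,
        max_padj=config.deg_max_padj,
    )
    cells = pd.DataFrame({
        "barcode": list(norm.obs_names), "cluster": labels, "cell_type": cell_types,
        "condition": norm.obs["condition"].astype(str).to_numpy(),
        "donor": norm.obs["donor"].to_numpy(),
    })
    _write(cells, out / "cells.tsv")
    _write(degs, out / "degs.tsv")
    logger.info("sc-deg: %d DEG records (|log2FC|>%.2f, padj<=%.2f)",
                len(degs), config.deg_min_abs_log2fc, config.deg_max_padj)
    return degs


# ---------------------------------------------------------------------------
# stage: MR (eQTL or pQTL class)
# ---------------------------------------------------------------------------

def _candidate_genes(config: PipelineConfig, out_dir, instrument_class: str) -> list[str]:
    inputs = _inputs(out_dir)
    names = [g["name"] for g in config.synthetic["genes"]]
    with_files = [n for n in names if (inputs / f"{n}_{instrument_class}.tsv").exists()]
    if instrument_class == "eqtl":
        degs_path = Path(out_dir) / "degs.tsv"
        if not degs_path.exists():
            raise SCTargetMRError("stage eqtl-MR: degs.tsv missing; run sc-deg first")
        deg_table = pd.read_csv(degs_path, sep="\t")
        deg_genes = set(deg_table["gene"]) if len(deg_table) else set()
        kept = [n for n in with_files if n in deg_genes]
        logger.info("mr/eqtl: %d/%d candidates are DEGs", len(kept), len(with_files))
        return kept
    # pQTL class: require eQTL-MR support when configured
    if not config.require_eqtl_support:
        return with_files
    eqtl_path = Path(out_dir) / "eqtl_mr.tsv"
    if not eqtl_path.exists():
        raise SCTargetMRError("stage pqtl-MR: eqtl_mr.tsv missing; run mr --instrument-class eqtl first")
    eq = pd.read_csv(eqtl_path, sep="\t")
    passed = set(eq.loc[eq["pval"] < config.mr_significance, "gene"])
    kept = [n for n in with_files if n in passed]
    logger.info("mr/pqtl: %d/%d candidates pass eQTL-MR p<%.3g",
                len(kept), len(with_files), config.mr_significance)
    return kept


def stage_mr(config: PipelineConfig, out_dir, instrument_class: str,
             seed: int | None = None) -> pd.DataFrame:
    """Instrument selection, clumping, harmonization and MR per candidate gene."""
    if instrument_class not in ("eqtl", "pqtl"):
        raise SCTargetMRError("instrument_class must be 'eqtl' or 'pqtl'")
    out = Path(out_dir)
    inputs = _inputs(out_dir)
    base_seed = config.seed if seed is None else seed
    p_thr = config.eqtl_p_threshold if instrument_class == "eqtl" else config.pqtl_p_threshold
    r2_thr = config.eqtl_clump_r2 if instrument_class == "eqtl" else config.pqtl_clump_r2
    gwas = instruments.read_sumstats(inputs / "gwas.tsv")
    rows = []
    for gene in _candidate_genes(config, out_dir, instrument_class):
        ss = instruments.read_sumstats(inputs / f"{gene}_{instrument_class}.tsv")
        ld = instruments.LDMatrix.from_tsv(inputs / f"{gene}_ld.tsv")
        cand = instruments.select_instruments(ss, p_thr)
        clumped = instruments.ld_clump(cand, ld, r2_thr, config.clump_window_kb)
        harmon = instruments.harmonize(clumped, gwas,
                                       palindromic_eaf_limit=config.palindromic_eaf_limit)
        instruments.write_harmonization_log(
            harmon, out / f"{gene}_{instrument_class}_harmonization.tsv")
        kept = instruments.retained(harmon)
        logger.info("mr/%s %s: %d significant -> %d clumped -> %d harmonized",
                    instrument_class, gene, len(cand), len(clumped), len(kept))
        row = {"gene": gene, "method": "none", "nsnp": len(kept),
               "beta": np.nan, "se": np.nan, "pval": np.nan,
               "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "cochran_q": np.nan, "q_pval": np.nan,
               "egger_intercept": np.nan, "egger_intercept_pval": np.nan}
        if len(kept):
            summary = mr.run_mr(kept, n_boot=config.wmedian_n_boot, seed=base_seed,
                                random_effects=config.mr_random_effects)
            res = summary.primary
            row.update({"method": res.method, "nsnp": res.n_snps, "beta": res.beta,
                        "se": res.se, "pval": res.pval, "or": res.odds_ratio,
                        "ci_low": res.ci_low, "ci_high": res.ci_high})
            if summary.sensitivity is not None:
                s = summary.sensitivity
                row.update({"cochran_q": s.cochran_q, "q_pval": s.q_pval,
                            "egger_intercept": s.egger_intercept,
                            "egger_intercept_pval": s.egger_intercept_pval})
        rows.append(row)
    table = pd.DataFrame(rows)
    _write(table, out / f"{instrument_class}_mr.tsv")
    return table


# ---------------------------------------------------------------------------
# stage: colocalization
# ---------------------------------------------------------------------------

def stage_coloc(config: PipelineConfig, out_dir) -> pd.DataFrame:
    """ABF colocalization of each MR-significant protein's cis signal with the GWAS."""
    out = Path(out_dir)
    inputs = _inputs(out_dir)
    pq_path = out / "pqtl_mr.tsv"
    if not pq_path.exists():
        raise SCTargetMRError("stage coloc: pqtl_mr.tsv missing; run mr --instrument-class pqtl first")
    pq = pd.read_csv(pq_path, sep="\t")
    gwas = instruments.read_sumstats(inputs / "gwas.tsv")
    priors = coloc_mod.ColocPriors(p1=config.coloc_p1, p2=config.coloc_p2,
                                   p12=config.coloc_p12)
    gwas_type = config.synthetic.get("gwas_type", "case_control")
    rows = []
    for gene in pq.loc[pq["pval"] < config.mr_significance, "gene"]:
        ss = instruments.read_sumstats(inputs / f"{gene}_pqtl.tsv")
        anchor = ss.loc[ss["pval"].idxmin()]
        region = coloc_mod.extract_region(
            ss, gwas, anchor_pos=int(anchor["pos"]), flank_kb=config.coloc_flank_kb,
            trait_types=("quantitative", gwas_type), anchor_chr=str(anchor["chr"]),
            palindromic_eaf_limit=config.palindromic_eaf_limit,
        )
        result = coloc_mod.coloc_abf(
            region, priors=priors,
            prior_sd_quant=config.coloc_prior_sd_quant,
            prior_sd_cc=config.coloc_prior_sd_cc,
        )
        passed = coloc_mod.coloc_decision(result, threshold=config.coloc_pp4_threshold)
        logger.info("coloc %s: n_snps=%d PP4=%.3g pass=%s (threshold %.2f)",
                    gene, result.n_snps, result.pp4, passed, config.coloc_pp4_threshold)
        row = {"gene": gene}
        row.update(result.as_dict())
        row["pass"] = bool(passed)
        rows.append(row)
    table = pd.DataFrame(rows, columns=[
        "gene", "pp0", "pp1", "pp2", "pp3", "pp4", "n_snps", "top_shared_variant", "pass",
    ])
    _write(table, out / "coloc.tsv")
    return table


# ---------------------------------------------------------------------------
# stage: PheWAS
# ---------------------------------------------------------------------------

def stage_phewas(config: PipelineConfig, out_dir) -> pd.DataFrame:
    """Pleiotropy screen of every MR-tested protein across the trait panel."""
    out = Path(out_dir)
    inputs = _inputs(out_dir)
    pq_path = out / "pqtl_mr.tsv"
    if not pq_path.exists():
        raise SCTargetMRError("stage phewas: pqtl_mr.tsv missing; run the pqtl MR stage first")
    pq = pd.read_csv(pq_path, sep="\t")
    table = phewas.read_phewas(inputs / "phewas.tsv")
    hit_frames, rows = [], []
    for gene in pq["gene"]:
        hits = phewas.screen(table, gene, alpha=config.phewas_alpha)
        verdict = phewas.pleiotropy_verdict(hits, disease_trait=config.disease_trait)
        logger.info("phewas %s: %d hits at p<%.2g -> %s",
                    gene, len(hits), config.phewas_alpha, verdict)
        hit_frames.append(hits)
        rows.append({"gene": gene, "n_hits": len(hits), "verdict": verdict})
    hits_all = pd.concat(hit_frames, ignore_index=True) if hit_frames \
        else pd.DataFrame(columns=phewas.PHEWAS_COLUMNS)
    _write(hits_all, out / "phewas_hits.tsv")
    verdicts = pd.DataFrame(rows, columns=["gene", "n_hits", "verdict"])
    _write(verdicts, out / "phewas_verdicts.tsv")
    return verdicts


# ---------------------------------------------------------------------------
# stage: report
# ---------------------------------------------------------------------------

def stage_report(config: PipelineConfig, out_dir) -> pd.DataFrame:
    """Assemble the per-gene target report and tier every candidate."""
    out = Path(out_dir)

    def _read(name, required=True):
        p = out / name
        if not p.exists():
            if required:
                raise SCTargetMRError(f"stage report: {name} missing; run earlier stages first")
            return pd.DataFrame()
        return pd.read_csv(p, sep="\t")

    degs = _read("degs.tsv")
    eq = _read("eqtl_mr.tsv")
    pq = _read("pqtl_mr.tsv")
    co = _read("coloc.tsv")
    ph = _read("phewas_verdicts.tsv")

    rows = []
    for g in config.synthetic["genes"]:
        name = g["name"]
        sub = degs[degs["gene"] == name] if len(degs) else pd.DataFrame()
        de_types = sorted(sub["cell_type"].unique()) if len(sub) else []
        row = {
            "gene": name,
            "de_cell_types": ",".join(de_types),
            "de_max_abs_log2fc": float(np.max(np.abs(sub["log2fc"]))) if len(sub) else np.nan,
        }
        for prefix, table in (("eqtl", eq), ("pqtl", pq)):
            r = table[table["gene"] == name] if len(table) else pd.DataFrame()
            for c in ("method", "nsnp", "beta", "se", "pval", "or", "ci_low", "ci_high"):
                row[f"{prefix}_{c}"] = r.iloc[0][c] if len(r) else np.nan
        co_r = co[co["gene"] == name] if len(co) else pd.DataFrame()
        for c in ("pp0", "pp1", "pp2", "pp3", "pp4"):
            row[c] = co_r.iloc[0][c] if len(co_r) else np.nan
        row["coloc_pass"] = bool(co_r.iloc[0]["pass"]) if len(co_r) else False
        ph_r = ph[ph["gene"] == name] if len(ph) else pd.DataFrame()
        row["phewas_verdict"] = ph_r.iloc[0]["verdict"] if len(ph_r) else ""

        sig = config.mr_significance
        if not de_types:
            tier = "excluded:not_de"
        elif pd.isna(row["eqtl_pval"]) or row["eqtl_nsnp"] == 0:
            tier = "excluded:no_eqtl_instruments"
        elif not (row["eqtl_pval"] < sig):
            tier = "excluded:eqtl_mr"
        elif pd.isna(row["pqtl_pval"]) or row["pqtl_nsnp"] == 0:
            tier = "excluded:no_pqtl_instruments"
        elif not (row["pqtl_pval"] < sig):
            tier = "excluded:pqtl_mr"
        elif not row["coloc_pass"]:
            tier = "excluded:coloc"
        elif row["phewas_verdict"] != "clean":
            tier = "excluded:phewas"
        else:
            tier = "top"
        row["tier"] = tier
        logger.info("report %s: tier=%s", name, tier)
        rows.append(row)
    report = pd.DataFrame(rows)
    _write(report, out / "target_report.tsv")

    lines = ["Target prioritization report", "=" * 28, ""]
    for _, r in report.iterrows():
        lines.append(f"{r['gene']}: tier={r['tier']}")
        if r["de_cell_types"]:
            lines.append(f"  DE in: {r['de_cell_types']} (max |log2FC| {r['de_max_abs_log2fc']:.2f})")
        if not pd.isna(r["pqtl_pval"]):
            lines.append(
                f"  pQTL-MR {r['pqtl_method']}: OR {r['pqtl_or']:.2f} "
                f"({r['pqtl_ci_low']:.2f}-{r['pqtl_ci_high']:.2f}), p={r['pqtl_pval']:.3g}")
        if not pd.isna(r["pp4"]):
            lines.append(f"  coloc: PP4={r['pp4']:.3f} pass={r['coloc_pass']}")
        if r["phewas_verdict"]:
            lines.append(f"  PheWAS: {r['phewas_verdict']}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> pd.DataFrame:
    """Execute the whole cascade; returns the target report.

    A ``run_log.txt`` under ``out_dir`` records parameters, seeds and the
    in/out counts of every filter.  A stage failure aborts with the stage
    name; partial outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = config.seed if seed is None else seed
    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    old_level = logger.level
    if logger.level > logging.INFO or logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)
    try:
        logger.info("run: seed=%d out_dir=%s", base_seed, out)
        logger.info("run: config=%s", {k: v for k, v in vars(config).items() if k != "synthetic"})
        stages = [
            ("simulate", lambda: stage_simulate(config, out, seed=base_seed)),
            ("sc-deg", lambda: stage_sc_deg(config, out, seed=base_seed)),
            ("mr-eqtl", lambda: stage_mr(config, out, "eqtl", seed=base_seed)),
            ("mr-pqtl", lambda: stage_mr(config, out, "pqtl", seed=base_seed)),
            ("coloc", lambda: stage_coloc(config, out)),
            ("phewas", lambda: stage_phewas(config, out)),
            ("report", lambda: stage_report(config, out)),
        ]
        result = None
        for name, fn in stages:
            try:
                result = fn()
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise SCTargetMRError(f"stage {name!r} failed: {exc}") from exc
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
        logger.setLevel(old_level)
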