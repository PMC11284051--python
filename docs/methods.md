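# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic data does and does not emulate, and
the known limitations.

## Single-cell stage

**QC.** Genes detected (count > 0) in fewer than 3 cells are removed first;
then cells with fewer than 250 detected genes, or with a mitochondrial
count fraction ≥ 10 %, are removed. The order matters and is fixed:
gene filter before cell filter, so a cell's detected-gene count is taken
over the surviving genes. Boundaries are as stated: exactly 250 detected
genes is retained, exactly 3 detecting cells is retained, a mitochondrial
fraction of exactly 0.10 is removed. Mitochondrial genes are identified by
a configurable name prefix (default `MT-`). QC is idempotent on realistic
data; in the adversarial corner where removing cells drops a gene below the
detection minimum, a second application can remove more — we keep the
single-pass semantics because that is what the standard workflow does.

**Normalization.** `ln(1 + s·c/total)` per cell with scale factor
s = 10⁴ (scanpy's `normalize_total` + `log1p`). Zeros stay exactly zero.

**Dimensionality reduction.** When more than `n_hvg` (default 2,000) genes
survive QC, the top 2,000 by standardized dispersion are kept (the reference
workflow is silent here; this is the field default). Values are per-gene
standardized and decomposed with a deterministic full-SVD PCA; 31
components by default. The component count and the clustering resolution
are configuration knobs, not targets — the reference analysis reports
"31 PCs" and "thirty subclasses" without stating how either was chosen.

**Clustering.** Leiden community detection on a k-nearest-neighbour graph
of the PC scores (scanpy neighbours + leidenalg, seeded, deterministic).
The reference workflow names only t-SNE, which is visualization, not
clustering; graph community detection is the method actually behind that
workflow.

**Annotation.** Marker expression is z-scored per gene over all cells;
each cluster gets the marker set with the highest mean z over its cells.
A best-vs-second margin below `annotate_min_margin` (default 0, i.e.
always assign) yields "unassigned"; empty marker sets can never win.

**Markers and DEGs.** Wilcoxon rank-sum per gene (asymptotic, tie-corrected;
constant genes get p = 1), Benjamini–Hochberg within each comparison family
(one cluster or one cell type). Fold change is Seurat-style:
`log2((mean(expm1 x) + 1 + 1e-9) / (mean(expm1 y) + 1 + 1e-9))` on
normalized values. Markers: |log2FC| ≥ 0.25 and detection fraction ≥ 0.25
in at least one group (p-values reported, not filtered). Case/control DEGs:
strict |log2FC| > 0.3, detection > 0.25, padj ≤ 0.05 — so an effect of
exactly 0.29 can never be a DEG regardless of its p-value. Output order is
(cell type, p, gene), making results invariant to gene and cell permutation.

## Instruments

Candidates are variants with p strictly below the class threshold
(default 5×10⁻⁸ for both eQTL and pQTL instruments), sorted by p with
(chrom, pos) tie-break. Greedy clumping takes the best remaining candidate
as index and discards candidates within ±window (10,000 kb; base-pair
distance ≤ window·1000) at r² ≥ the class threshold — 0.001 for eQTL
instruments, 0.01 for pQTL panels, both configurable. Variants missing from
the LD matrix are conservatively discarded (independence cannot be
certified) and logged. Note the source protocol contains an internal
contradiction for pQTLs ("genome-wide significance level (P < 0.05)"); both
readings are exposed in configuration (`pqtl_p_threshold`), the default is
5×10⁻⁸, and the contradiction is recorded rather than resolved.

Harmonization aligns the outcome to the exposure's effect allele: swapped
alleles flip the outcome beta and complement its frequency; palindromic
variants (A/T, C/G) with missing EAF or EAF inside (0.42, 0.58) are
excluded (the conventional ambiguity band — the protocol never mentions
palindromic handling); unmatched variants are excluded with the reason
recorded. Harmonization is idempotent on its own output.

## MR engine

Dispatch follows the stated rule: one instrument → Wald ratio; two or
more → fixed-effect IVW; with three or more, MR-Egger, the weighted median
and Cochran's Q attach as sensitivity analyses.

- Wald ratio: first-order SE `σy/|βx|` by default (exposure-side
  uncertainty ignored); a second-order delta term is available via a flag.
- IVW: fixed-effect by default; the multiplicative random-effects variant
  (SE inflated by `max(1, sqrt(Q/(n−1)))`) sits behind a flag and is the
  thing to reach for when Q is large.
- MR-Egger: instruments are oriented so every exposure beta is positive
  before the weighted fit (the standard sign convention — without it a
  constant pleiotropic shift cancels). SEs carry the conventional
  multiplicative overdispersion factor floored at 1; p-values use t(n−2).
- Weighted median: inverse-variance ratio weights `βx²/σy²`, interpolated
  weighted median, SE from a seeded parametric bootstrap (1,000 draws
  resampling both sides from their reported sampling distributions).
- Cochran's Q uses first-order ratio weights and χ²(n−1).
- Reported p-values are floored at 10⁻³⁰⁰; odds ratios and CIs are
  `exp(β ± z·se)`. A table p of "0.000" means p < 0.0005 at 3-decimal
  display rounding.

The first-order weighting assumes the exposure betas are measured without
error (NOME). The instrument generator follows the same convention — the
outcome beta is built from the exposure beta plus outcome-scale noise — so
IVW is correctly specified on generated data and its CI coverage is
nominal. On real data with weak instruments (low mean F), first-order IVW
and especially the Egger intercept undercover; the second-order Wald flag
and the random-effects flag are the built-in mitigations, and regression
dilution itself is out of scope.

## Colocalization

Single-causal-variant ABF colocalization: per variant and trait, the
Wakefield log approximate Bayes factor `½[log(1−r) + r·z²]`,
`r = W/(W+σ²)`, with prior effect SD `W^½` of 0.15 for quantitative traits
and 0.2 on the log-odds scale for case-control traits (the established
defaults, configurable). Regions are ±500 kb around the index pQTL, the
intersection of both traits' variants after allele harmonization.
Hypothesis masses: `L1 = Σⱼ ABF1ⱼ`, `L2 = Σⱼ ABF2ⱼ`,
`L12 = Σⱼ ABF1ⱼ·ABF2ⱼ` (shared), `L1·L2 − L12` (distinct pairs), all
accumulated in log space with log-sum-exp; unnormalized posteriors
`{1, p1·L1, p2·L2, p1·p2·(L1·L2−L12), p12·L12}` with defaults
p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵ (only p12 is printed in the source
protocol). A single-variant region has PP3 = 0 identically — no distinct
pair exists — and H3 is otherwise computed as stated even when nearly
degenerate. The decision rule is strict: PP4 > 0.8 passes, exactly 0.8
does not (the source states both ">" and "≥" in different places; strict
is the default and the boundary is documented here).

Posteriors always sum to 1 within 10⁻⁹. Exact invariance under scaling
both traits' betas and SEs by a constant does **not** hold — the effect
prior W is on the absolute scale, so r shifts — but decisive posteriors are
insensitive to such scaling (verified to within 0.05 in the tests).

## PheWAS screen

Rows for the target with p strictly below α = 2×10⁻⁸ (the portal default
the protocol cites; the portal's own boundary convention is unstated, so
strict-< is fixed here and tested). The verdict is `clean` iff nothing
beyond the study disease is significant; the disease is matched by
case-insensitive substring on the trait name (default
"multiple sclerosis", configurable).

## Pipeline

Candidate flow: DEGs ∩ genes with eQTL instruments → eQTL-MR (keep
p < 0.05) → pQTL-MR (keep p < 0.05, the "marginal significance" gate) →
colocalization (keep PP4 > 0.8) → PheWAS (keep clean). Whether pQTL
candidates must carry eQTL-MR support is explicit and configurable
(`require_eqtl_support`, default true, matching the narrative order of the
source protocol). Every stage writes its table to the run directory, and
the run log records parameters, seeds and in/out counts of every filter, so
each report row is traceable. Re-running with the same configuration and
seed reproduces every output byte-identically.

## Synthetic data

What it emulates, and how the defaults were chosen:

- **LD panels** — two independent AR(1) latent Gaussian haplotypes per
  individual, thresholded at the per-variant MAF (uniform in (0.05, 0.5))
  and summed to 0/1/2 dosages. This is the simplest mechanism that yields
  monotonically distance-decaying r² (no LD model is stated in the source);
  thresholding attenuates the latent correlation (decay 0.9 gives adjacent
  dosage r ≈ 0.58). Variants sit on one synthetic chromosome at a fixed
  1 kb spacing, 1-based, so the ±500 kb and 10,000 kb windows bite.
- **Summary statistics** — marginal per-variant regressions on disjoint
  cohorts (two-sample design): closed-form simple linear regression for
  quantitative traits and a vectorized Newton–Raphson logistic fit for
  case-control traits, so binary-outcome betas are genuine log odds
  (balanced case-control, intercept 0). Both are validated against
  statsmodels on small fixtures.
- **Coloc scenarios** — H0–H4 planted exactly (shared variant, distinct
  variants, one-trait-only, null), causal variants drawn from the central
  half of the region to keep the cis window symmetric.
- **Single-cell counts** — Gamma-Poisson (NB) with dispersion 0.4,
  log-normal baseline means, per-type log-normal profile perturbations
  (SD 0.35), markers elevated 8-fold in their own type, planted DE genes
  shifted by the stated log2FC in the case condition, log-normal library
  sizes (SD 0.2), two donors per condition. Low-quality cells are damaged
  deliberately: half get mitochondrial counts inflated to ~1/3 of the cell
  total, half are truncated to ~100 detected genes, so QC has real work.
- **PheWAS panel** — uniform background p-values above a floor (10⁻⁶, so
  no background trait can cross 2×10⁻⁸ by construction), ~90 % binary
  traits, planted hits inserted verbatim.
- **Bundled demo** — four cell types × 200 cells, 1,000 genes, five
  candidate genes with planted roles; per-gene loci of 200 variants
  (decay 0.9), three disjoint cohorts of 4,000 (expression, protein,
  disease), exposure effect 0.5 SD per allele, disease effect −0.25
  log-odds. Candidate genes' baseline means are anchored at 2.0 so
  planted fold changes of 1.6–1.8 survive BH correction across 1,000
  genes — DE is planted in expressed genes, as in any sensible positive
  control. The H3 decoy's disease variant sits 6 variants (6 kb) from its
  QTL: close enough in LD (dosage r ≈ 0.35) for its MR to reach nominal
  significance, far enough for colocalization to separate the peaks.

What it does **not** emulate: realistic human LD maps and block structure,
population structure and relatedness, imputation uncertainty, winner's-curse
selection of instruments, ambient RNA/doublets, batch effects, donor-level
pseudoreplication. Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated models, not robustness to those
real-data pathologies.

## Problem sizes

The test suite and acceptance script run simulations at the scale the
checks need, chosen once: 500 instrument sets of 20 instruments for
estimator recovery; 20 seeds × 5 scenarios of 200-variant regions with
5,000 individuals per trait for colocalization; 10,000 individuals × 100
variants for GWAS hit-localisation sweeps; the demo at the sizes above.

## Known limitations

- Single-causal-variant assumption in colocalization (no SuSiE-style
  multi-signal decomposition; a second independent signal in the region
  dilutes PP4).
- First-order SEs throughout the MR default path (see NOME discussion).
- Greedy clumping guarantees pairwise independence of the kept set against
  each index, not joint independence; with distinct p-values it is fully
  deterministic, and tightening thresholds can in principle (rarely)
  produce non-nested sets.
- The PheWAS stage screens reported p-values only; it does not model the
  correlation structure among traits.
- The "horizontal multiplicity test" named in the source discussion is
  interpreted as the Egger intercept test; no further definition is given
  there, and none is invented here.
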