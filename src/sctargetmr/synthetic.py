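"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's real data
sources without requiring any download:

* an LD-structured genotype panel — first-order autoregressive latent
  haplotypes thresholded to alleles, giving correlations that decay
  monotonically with distance (variants sit on one synthetic chromosome at
  a fixed 1 kb spacing, 1-based);
* GWAS/QTL summary statistics — marginal single-variant regressions (linear
  for quantitative traits, logistic for case-control, so betas are log odds)
  computed on disjoint cohorts, honouring the two-sample MR design;
* pre-made harmonized instrument sets with a known causal effect and
  optional balanced pleiotropy, as a test bed for the MR estimators;
* negative-binomial single-cell counts with planted cell types, marker
  genes, case/control differential expression and deliberately low-quality
  cells for the QC stage to remove;
* a PheWAS association table with planted significant traits over a uniform
  background.

Everything is bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy import stats

from .errors import ParameterError
from .instruments import HARMONIZED_COLUMNS, LDMatrix, SUMSTATS_COLUMNS

SCENARIOS = ("H0", "H1", "H2", "H3", "H4")

# non-strand-ambiguous allele pairs only, so harmonization never drops
# simulated variants as palindromic
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator planted, for downstream validation.

    ``scenario`` is a colocalization hypothesis label (H0..H4) when the
    truth describes a two-trait region, else None.  ``causal_variant_ids``
    maps trait name to the planted causal variant ids.  ``causal_effect`` is
    the true MR effect of the exposure on the outcome (log odds per unit of
    exposure for a binary outcome).  ``de_genes`` maps cell type to
    [gene, true log2 fold change] pairs.
    """

    scenario: str | None = None
    causal_variant_ids: dict = field(default_factory=dict)
    causal_effect: float = 0.0
    de_genes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario is not None:
            if self.scenario not in SCENARIOS:
                raise ParameterError(f"unknown scenario {self.scenario!r}")
            exp_ids = set(self.causal_variant_ids.get("exposure", []))
            out_ids = set(self.causal_variant_ids.get("outcome", []))
            if self.scenario == "H0" and (exp_ids or out_ids):
                raise ParameterError("H0 admits no causal variants")
            if self.scenario == "H4" and not (
                len(exp_ids) == 1 and exp_ids == out_ids
            ):
                raise ParameterError("H4 requires exactly one shared causal variant")
            if self.scenario == "H3" and exp_ids & out_ids:
                raise ParameterError("H3 requires distinct causal variants")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# LD genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x variants) with variant metadata."""

    dosages: np.ndarray
    snp_ids: list
    chrom: str
    pos: np.ndarray
    ea: list
    oa: list

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


def ld_from_dosages(dosages: np.ndarray, snp_ids) -> LDMatrix:
    """Sample correlation of dosage columns as an :class:`LDMatrix`.

    Zero-variance columns get r = 0 with every other variant (their LD is
    undefined); identical columns get r = 1 exactly.
    """
    dosages = np.asarray(dosages, dtype=float)
    centred = dosages - dosages.mean(axis=0, keepdims=True)
    sd = centred.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    r = (centred / sd_safe).T @ (centred / sd_safe) / dosages.shape[0]
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return LDMatrix(list(snp_ids), r)


def _ar1_haplotypes(rng, n_hap: int, n_variants: int, decay: float, mafs: np.ndarray):
    """Latent AR(1) Gaussians thresholded to 0/1 alleles at the given MAFs."""
    z = np.empty((n_hap, n_variants))
    z[:, 0] = rng.standard_normal(n_hap)
    innov_sd = np.sqrt(1.0 - decay**2)
    for j in range(1, n_variants):
        z[:, j] = decay * z[:, j - 1] + innov_sd * rng.standard_normal(n_hap)
    thresh = stats.norm.ppf(mafs)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_ld_genotypes(
    n_individuals: int,
    n_variants: int,
    decay: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[GenotypePanel, LDMatrix]:
    """Generate an LD-structured diploid dosage panel and its sample LD.

    Two independent AR(1) latent haplotypes per individual are thresholded
    to alleles at per-variant MAFs drawn uniformly from ``maf_range``; the
    dosage is their sum.  ``decay`` in [0, 1) controls how fast
    between-variant correlation falls with distance (0 gives independent
    variants).  The returned LD matrix is the sample correlation of the
    dosage columns.
    """
    if n_individuals < 2 or n_variants < 1:
        raise ParameterError("need n_individuals >= 2 and n_variants >= 1")
    if not (0 <= decay < 1):
        raise ParameterError("decay must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    hap_a = _ar1_haplotypes(rng, n_individuals, n_variants, decay, mafs)
    hap_b = _ar1_haplotypes(rng, n_individuals, n_variants, decay, mafs)
    dosages = (hap_a + hap_b).astype(np.int8)

    snp_ids = [f"rs{j + 1}" for j in range(n_variants)]
    ld = ld_from_dosages(dosages, snp_ids)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_variants)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    pos = (np.arange(n_variants) + 1) * 1000  # 1 kb spacing, 1-based
    panel = GenotypePanel(dosages=dosages, snp_ids=snp_ids, chrom="1",
                          pos=pos, ea=ea, oa=oa)
    return panel, ld


# ---------------------------------------------------------------------------
# marginal single-variant regressions
# ---------------------------------------------------------------------------

def marginal_linear(G: np.ndarray, y: np.ndarray):
    """Per-variant simple linear regression of y on each dosage column.

    Returns (beta, se) arrays; the intercept is profiled out by centring.
    """
    n = len(y)
    if n < 3:
        raise ParameterError("need at least 3 individuals")
    gc = G - G.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    sxx = np.sum(gc * gc, axis=0)
    sxx_safe = np.where(sxx == 0, np.inf, sxx)
    beta = gc.T @ yc / sxx_safe
    syy = float(np.sum(yc * yc))
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    se = np.where(sxx == 0, np.inf, se)
    return beta, np.maximum(se, np.finfo(float).tiny)


def marginal_logistic(G: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10):
    """Per-variant logistic regression (intercept + dosage), vectorized Newton.

    ``y`` is 0/1 case status; returns (beta, se) on the log-odds scale for
    every column of ``G`` simultaneously.
    """
    n, m = G.shape
    ybar = y.mean()
    if not (0 < ybar < 1):
        raise ParameterError("case-control outcome needs both cases and controls")
    a = np.full(m, np.log(ybar / (1 - ybar)))
    b = np.zeros(m)
    yv = y[:, None].astype(float)
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = yv - p
        g0 = r.sum(axis=0)
        g1 = (G * r).sum(axis=0)
        s0 = w.sum(axis=0)
        s1 = (w * G).sum(axis=0)
        s2 = (w * G * G).sum(axis=0)
        det = np.maximum(s0 * s2 - s1 * s1, np.finfo(float).tiny)
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    eta = a[None, :] + G * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    s0 = w.sum(axis=0)
    s1 = (w * G).sum(axis=0)
    s2 = (w * G * G).sum(axis=0)
    det = np.maximum(s0 * s2 - s1 * s1, np.finfo(float).tiny)
    se = np.sqrt(s0 / det)
    return b, np.maximum(se, np.finfo(float).tiny)


def _sumstats_frame(panel: GenotypePanel, idx: np.ndarray, beta, se, n: int) -> pd.DataFrame:
    """Assemble a summary-statistics table for a cohort subset of a panel."""
    G = panel.dosages[idx].astype(float)
    eaf = G.mean(axis=0) / 2.0
    z = beta / se
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    return pd.DataFrame({
        "snp": panel.snp_ids, "chr": panel.chrom, "pos": panel.pos,
        "ea": panel.ea, "oa": panel.oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval, "n": len(idx),
    }, columns=SUMSTATS_COLUMNS)


def _standardize(g: np.ndarray) -> np.ndarray:
    sd = g.std()
    return (g - g.mean()) / (sd if sd > 0 else 1.0)


def _trait_sumstats(panel, idx, causal_idx, effect, trait_type, rng):
    """Phenotype + marginal GWAS for one cohort; returns a sumstats table."""
    G = panel.dosages[idx].astype(float)
    n = len(idx)
    signal = np.zeros(n)
    if causal_idx is not None and effect != 0:
        signal = effect * _standardize(G[:, causal_idx])
    if trait_type == "quantitative":
        y = signal + rng.standard_normal(n)
        beta, se = marginal_linear(G, y)
    elif trait_type == "case_control":
        p = 1.0 / (1.0 + np.exp(-signal))
        y = (rng.uniform(size=n) < p).astype(float)
        beta, se = marginal_logistic(G, y)
    else:
        raise ParameterError(f"unknown trait type {trait_type!r}")
    return _sumstats_frame(panel, idx, beta, se, n)


def simulate_two_trait_sumstats(
    panel: GenotypePanel,
    scenario: str,
    exposure_effect: float,
    outcome_effect: float,
    outcome_type: str = "quantitative",
    seed: int = 0,
    causal_index: int | None = None,
    causal_index2: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Exposure and outcome summary statistics under one coloc hypothesis.

    The panel's individuals are split into two disjoint halves (two-sample
    design); each trait's per-variant beta/SE/p come from marginal
    single-variant regressions on its own cohort.  Under H4 both traits are
    causal at the same variant; under H3 at two distinct variants; H1/H2 at
    one trait only; H0 at neither.  ``causal_index`` (and ``causal_index2``
    for the second trait under H3) may pin the planted variants; otherwise
    they are drawn from the central half of the region.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"scenario must be one of {SCENARIOS}")
    exp_active = scenario in ("H1", "H3", "H4")
    out_active = scenario in ("H2", "H3", "H4")
    if exp_active != (exposure_effect != 0):
        raise ParameterError(f"{scenario} requires exposure_effect {'!=' if exp_active else '=='} 0")
    if out_active != (outcome_effect != 0):
        raise ParameterError(f"{scenario} requires outcome_effect {'!=' if out_active else '=='} 0")

    rng = np.random.default_rng(seed)
    m = panel.n_variants
    lo, hi = m // 4, max(m // 4 + 1, (3 * m) // 4)

    def _draw(exclude=None):
        while True:
            k = int(rng.integers(lo, hi))
            if k != exclude:
                return k

    exp_idx = out_idx = None
    if exp_active:
        exp_idx = causal_index if causal_index is not None else _draw()
    if out_active:
        if scenario == "H2":
            out_idx = causal_index if causal_index is not None else _draw()
        elif scenario == "H3":
            out_idx = causal_index2 if causal_index2 is not None else _draw(exclude=exp_idx)
            if out_idx == exp_idx:
                raise ParameterError("H3 requires two distinct causal variants")
        else:  # H4
            out_idx = exp_idx
    for k in (exp_idx, out_idx):
        if k is not None and not (0 <= k < m):
            raise ParameterError("causal index outside the panel")

    n = panel.n_individuals
    half = n // 2
    cohort1 = np.arange(half)
    cohort2 = np.arange(half, n)

    exposure = _trait_sumstats(panel, cohort1, exp_idx, exposure_effect, "quantitative", rng)
    outcome = _trait_sumstats(panel, cohort2, out_idx, outcome_effect, outcome_type, rng)
    truth = GroundTruth(
        scenario=scenario,
        causal_variant_ids={
            "exposure": [panel.snp_ids[exp_idx]] if exp_idx is not None else [],
            "outcome": [panel.snp_ids[out_idx]] if out_idx is not None else [],
        },
        causal_effect=(outcome_effect / exposure_effect) if scenario == "H4" else 0.0,
    )
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# MR instrument test bed
# ---------------------------------------------------------------------------

def simulate_mr_instruments(
    n_instruments: int,
    causal_beta: float,
    pleiotropy_sd: float = 0.0,
    exposure_n: int = 20000,
    outcome_n: int = 20000,
    seed: int = 0,
    exposure_beta_range: tuple[float, float] = (0.05, 0.15),
    pleiotropy_mean: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """A harmonized instrument set with known causal effect.

    Instruments are mutually independent variants.  Exposure effects are
    drawn with magnitude uniform in ``exposure_beta_range`` (random sign)
    and enter the outcome as
    ``beta_outcome = causal_beta * beta_exposure + pleiotropy + noise``,
    with the noise scaled by the outcome standard error; the exposure betas
    themselves carry no additional sampling error (the no-measurement-error
    condition that first-order IVW weighting assumes).  Standard errors on
    both sides follow the usual ``1/sqrt(2*eaf*(1-eaf)*n)`` form for a
    variance-standardized trait; the exposure SE is reported for estimators
    that use it (second-order Wald, bootstrap).  ``pleiotropy_sd = 0`` (and
    mean 0) gives a valid-instrument setting.  Pleiotropy is applied
    relative to the exposure-increasing allele (the MR-Egger orientation),
    so a non-zero ``pleiotropy_mean`` is genuinely directional rather than
    cancelling under allele re-orientation.
    """
    if n_instruments < 1:
        raise ParameterError("n_instruments must be >= 1")
    if pleiotropy_sd < 0:
        raise ParameterError("pleiotropy_sd must be >= 0")
    if exposure_n < 2 or outcome_n < 2:
        raise ParameterError("sample sizes must be >= 2")
    rng = np.random.default_rng(seed)
    k = n_instruments
    eaf = rng.uniform(0.1, 0.5, size=k)
    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * exposure_n)
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * outcome_n)
    lo, hi = exposure_beta_range
    bx = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
    pleio = pleiotropy_mean + pleiotropy_sd * rng.standard_normal(k) \
        if (pleiotropy_sd > 0 or pleiotropy_mean != 0) else np.zeros(k)
    by = causal_beta * bx + pleio * np.sign(bx) + se_y * rng.standard_normal(k)
    hset = pd.DataFrame({
        "snp": [f"iv{j + 1}" for j in range(k)],
        "chr": "1",
        "pos": (np.arange(k) + 1) * 20_000_000,  # far apart: independent
        "ea": "A", "oa": "G",
        "beta_exposure": bx, "se_exposure": se_x,
        "beta_outcome": by, "se_outcome": se_y,
        "eaf": eaf, "flipped": False,
        "excluded_reason": pd.Series([None] * k, dtype=object),
    }, columns=HARMONIZED_COLUMNS)
    truth = GroundTruth(causal_effect=causal_beta,
                        causal_variant_ids={"exposure": list(hset["snp"]), "outcome": []})
    return hset, truth


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def simulate_sc_counts(
    cells_per_type: dict[str, int],
    n_genes: int,
    markers: dict[str, list] | None = None,
    de_genes: dict[str, list] | None = None,
    nb_dispersion: float = 0.4,
    mito_gene_fraction: float = 0.03,
    lowq_cell_fraction: float = 0.0,
    n_donors_per_condition: int = 2,
    gene_names: list | None = None,
    marker_fold: float = 8.0,
    base_mean: float = 0.8,
    type_effect_sd: float = 0.35,
    lowq_detect_target: int = 100,
    anchor_genes: dict | None = None,
    seed: int = 0,
) -> tuple[ad.AnnData, GroundTruth]:
    """Negative-binomial cell-by-gene counts with planted structure.

    Each cell type has its own mean profile (log-normal perturbation of a
    shared baseline); marker genes are elevated ``marker_fold``-fold in their
    own type; DE genes are shifted by the stated log2 fold change in the
    "case" condition within their cell type.  Cells split evenly between
    conditions and round-robin over donors.  A ``lowq_cell_fraction`` of
    cells is damaged so the QC stage has work to do: half get an inflated
    mitochondrial fraction (> 10 %), half are truncated to roughly
    ``lowq_detect_target`` detected genes.  Counts are Gamma-Poisson with
    dispersion ``nb_dispersion`` (variance mu + dispersion * mu^2).
    """
    if len(cells_per_type) < 2:
        raise ParameterError("need at least 2 cell types")
    if n_donors_per_condition < 2:
        raise ParameterError("need >= 2 donors per condition")
    if not (0 <= lowq_cell_fraction < 1) or not (0 <= mito_gene_fraction < 1):
        raise ParameterError("fractions must lie in [0, 1)")
    if nb_dispersion < 0:
        raise ParameterError("nb_dispersion must be >= 0")
    markers = markers or {}
    de_genes = de_genes or {}

    n_mito = int(round(mito_gene_fraction * n_genes))
    if gene_names is None:
        gene_names = [f"MT-{i + 1}" for i in range(n_mito)] + \
                     [f"SG{i + 1:04d}" for i in range(n_genes - n_mito)]
    if len(gene_names) != n_genes or len(set(gene_names)) != n_genes:
        raise ParameterError("gene_names must hold n_genes unique names")
    gene_index = {g: i for i, g in enumerate(gene_names)}
    cell_types = list(cells_per_type)
    for t, genes in markers.items():
        if t not in cells_per_type:
            raise ParameterError(f"marker set for unknown cell type {t!r}")
        for g in genes:
            if g not in gene_index:
                raise ParameterError(f"marker gene {g!r} not in gene list")
    for t, spec in de_genes.items():
        if t not in cells_per_type:
            raise ParameterError(f"DE spec for unknown cell type {t!r}")
        for g, _ in spec:
            if g not in gene_index:
                raise ParameterError(f"DE gene {g!r} not in gene list")

    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    # genes whose planted signal must be observable (e.g. DE candidates) can
    # be pinned to a stated baseline mean instead of the log-normal draw
    for g, mu0 in (anchor_genes or {}).items():
        if g not in gene_index:
            raise ParameterError(f"anchor gene {g!r} not in gene list")
        if mu0 <= 0:
            raise ParameterError("anchor gene means must be > 0")
        base[gene_index[g]] = float(mu0)
    type_means = {}
    for t in cell_types:
        mu = base * np.exp(type_effect_sd * rng.standard_normal(n_genes))
        for g in markers.get(t, []):
            mu[gene_index[g]] *= marker_fold
        type_means[t] = mu

    rows, obs_type, obs_cond, obs_donor = [], [], [], []
    for t in cell_types:
        n_cells = cells_per_type[t]
        for i in range(n_cells):
            cond = "control" if i < n_cells // 2 else "case"
            donor_slot = i % n_donors_per_condition
            mu = type_means[t].copy()
            if cond == "case":
                for g, lfc in de_genes.get(t, []):
                    mu[gene_index[g]] *= 2.0 ** float(lfc)
            size_factor = rng.lognormal(mean=0.0, sigma=0.2)
            lam = mu * size_factor
            if nb_dispersion > 0:
                lam = rng.gamma(shape=1.0 / nb_dispersion,
                                scale=lam * nb_dispersion)
            counts = rng.poisson(lam)
            rows.append(counts)
            obs_type.append(t)
            obs_cond.append(cond)
            obs_donor.append(f"{cond}_donor{donor_slot + 1}")
    X = np.asarray(rows, dtype=np.int64)
    n_total = X.shape[0]

    is_lowq = np.zeros(n_total, dtype=bool)
    n_lowq = int(round(lowq_cell_fraction * n_total))
    if n_lowq:
        damaged = rng.choice(n_total, size=n_lowq, replace=False)
        mito_mask = np.array([g.startswith("MT-") for g in gene_names])
        for k, c in enumerate(damaged):
            is_lowq[c] = True
            if k % 2 == 0 and mito_mask.any():
                # inflate mitochondrial counts to ~1/3 of the cell total
                non_mito_total = X[c, ~mito_mask].sum()
                n_mito_genes = int(mito_mask.sum())
                boost = max(1, int(np.ceil(non_mito_total / (2 * n_mito_genes))))
                X[c, mito_mask] += boost
            else:
                nz = np.flatnonzero(X[c] > 0)
                if len(nz) > lowq_detect_target:
                    drop = rng.choice(nz, size=len(nz) - lowq_detect_target, replace=False)
                    X[c, drop] = 0

    adata = ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame({
            "donor": obs_donor,
            "condition": pd.Categorical(obs_cond, categories=["control", "case"]),
            "true_cell_type": obs_type,
            "is_lowq": is_lowq,
        }, index=[f"cell{i + 1:05d}" for i in range(n_total)]),
        var=pd.DataFrame({
            "mito": [g.startswith("MT-") for g in gene_names],
        }, index=gene_names),
    )
    truth = GroundTruth(de_genes={
        t: [[g, float(lfc)] for g, lfc in spec] for t, spec in de_genes.items()
    })
    return adata, truth


# ---------------------------------------------------------------------------
# PheWAS table
# ---------------------------------------------------------------------------

def simulate_phewas_table(
    n_traits: int,
    planted: list | None = None,
    background_p_floor: float = 1e-6,
    seed: int = 0,
    gene: str = "TARGET",
) -> pd.DataFrame:
    """A multi-trait association table for one gene.

    Background p-values are uniform on ``(background_p_floor, 1)``; planted
    ``(trait, p)`` associations are inserted verbatim.  Roughly 9 in 10
    background traits are binary, mirroring the dichotomous-heavy composition
    of biobank phenome panels.
    """
    if n_traits < 0:
        raise ParameterError("n_traits must be >= 0")
    if not (0 < background_p_floor < 1):
        raise ParameterError("background_p_floor must lie in (0, 1)")
    planted = planted or []
    for trait, p in planted:
        if not (0 < p <= 1):
            raise ParameterError(f"planted p-value for {trait!r} must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_traits):
        records.append({
            "gene": gene,
            "trait": f"background trait {i + 1}",
            "trait_class": "binary" if rng.uniform() < 0.9 else "quantitative",
            "pval": rng.uniform(background_p_floor, 1.0),
            "effect": np.nan,
        })
    for trait, p in planted:
        records.append({"gene": gene, "trait": trait, "trait_class": "binary",
                        "pval": float(p), "effect": np.nan})
    df = pd.DataFrame(records, columns=["gene", "trait", "trait_class", "pval", "effect"])
    if df.duplicated(subset=["gene", "trait"]).any():
        raise ParameterError("duplicate (gene, trait) pairs in PheWAS table")
    return df


# ---------------------------------------------------------------------------
# per-locus triplet for the end-to-end pipeline
# ---------------------------------------------------------------------------

def simulate_locus_triplet(
    role: str,
    n_per_cohort: int,
    n_variants: int,
    decay: float,
    exposure_effect: float,
    outcome_effect: float,
    gwas_type: str = "case_control",
    h3_gap: int = 6,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> dict:
    """eQTL, pQTL and GWAS summary statistics over one gene's cis locus.

    Three disjoint cohorts of ``n_per_cohort`` individuals are drawn from one
    LD panel: expression (eQTL), protein (pQTL) and disease (GWAS).  ``role``
    selects the planted architecture:

    * ``shared`` — all three traits causal at one variant (the H4 geometry);
    * ``distinct`` — expression and protein causal at one variant, the
      disease at a variant ``h3_gap`` positions away (H3: LD leaks enough
      association for MR to bite, but the causal variants differ);
    * ``exposure_only`` — QTL signals present, disease null at the locus;
    * ``null`` — no causal variant anywhere.
    """
    roles = ("shared", "distinct", "exposure_only", "null")
    if role not in roles:
        raise ParameterError(f"role must be one of {roles}")
    rng = np.random.default_rng(seed)
    panel, ld = simulate_ld_genotypes(3 * n_per_cohort, n_variants, decay,
                                      maf_range=maf_range, seed=int(rng.integers(2**31)))
    m = n_variants
    qtl_idx = m // 2
    if role == "distinct":
        gwas_idx = qtl_idx + h3_gap
        if gwas_idx >= m:
            raise ParameterError("h3_gap pushes the GWAS causal variant off the locus")
    elif role == "shared":
        gwas_idx = qtl_idx
    else:
        gwas_idx = None
    qtl_active = role != "null"

    cohorts = [np.arange(i * n_per_cohort, (i + 1) * n_per_cohort) for i in range(3)]
    eqtl = _trait_sumstats(panel, cohorts[0], qtl_idx if qtl_active else None,
                           exposure_effect if qtl_active else 0.0, "quantitative", rng)
    pqtl = _trait_sumstats(panel, cohorts[1], qtl_idx if qtl_active else None,
                           exposure_effect if qtl_active else 0.0, "quantitative", rng)
    gwas = _trait_sumstats(panel, cohorts[2], gwas_idx,
                           outcome_effect if gwas_idx is not None else 0.0,
                           gwas_type, rng)
    scenario = {"shared": "H4", "distinct": "H3", "exposure_only": "H1", "null": "H0"}[role]
    truth = GroundTruth(
        scenario=scenario,
        causal_variant_ids={
            "exposure": [panel.snp_ids[qtl_idx]] if qtl_active else [],
            "outcome": [panel.snp_ids[gwas_idx]] if gwas_idx is not None else [],
        },
        causal_effect=(outcome_effect / exposure_effect) if role == "shared" else 0.0,
    )
    return {"eqtl": eqtl, "pqtl": pqtl, "gwas": gwas, "ld": ld,
            "panel": panel, "truth": truth}


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_cell_matrix(adata: ad.AnnData, out_dir) -> None:
    """Write counts as MatrixMarket (genes x cells) + genes/barcodes/metadata TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X) if not sp.issparse(adata.X) else adata.X
    scipy.io.mmwrite(str(out / "counts.mtx"), X.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = adata.obs.reset_index().rename(columns={"index": "barcode"})
    meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False)


def read_cell_matrix(in_dir, mito_prefix: str = "MT-") -> ad.AnnData:
    """Read the MTX + genes/barcodes/metadata layout back into AnnData."""
    src = Path(in_dir)
    X = scipy.io.mmread(str(src / "counts.mtx")).tocsr().T.tocsr()
    genes = pd.read_csv(src / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    meta = pd.read_csv(src / "cell_meta.tsv", sep="\t").set_index("barcode")
    meta = meta.loc[barcodes]
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=meta,
        var=pd.DataFrame({"mito": [g.startswith(mito_prefix) for g in genes]}, index=genes),
    )
    return adata
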