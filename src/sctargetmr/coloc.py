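"""Bayesian colocalization of two association signals in a cis region.

The model is the standard single-causal-variant approximate-Bayes-factor
formulation: per variant and trait, a Wakefield approximate Bayes factor is
computed from the reported beta and standard error; the five mutually
exclusive hypotheses about the region are

* H0 — no causal variant for either trait,
* H1 / H2 — a causal variant for the first / second trait only,
* H3 — both traits causal, at two distinct variants,
* H4 — both traits causal at one shared variant,

and each receives a posterior probability (PP0..PP4) from per-variant prior
probabilities ``p1``, ``p2`` (trait-specific) and ``p12`` (shared).  All
accumulation happens in log space with log-sum-exp so large regions cannot
underflow.  A region "colocalizes" when PP4 exceeds a decision threshold,
0.8 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ParameterError, RegionError
from .instruments import harmonize, retained, validate_sumstats

#: default per-variant prior standard deviations for the effect size, by trait type
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.2  # on the log-odds scale

TRAIT_TYPES = ("quantitative", "case_control")


@dataclass
class ColocPriors:
    """Per-variant prior probabilities of causality."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def validate(self, n_snps: int) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ParameterError("coloc priors must be > 0")
        if n_snps * (self.p1 + self.p2 + self.p12) >= 1:
            raise ParameterError(
                "priors too large for region size: n_snps*(p1+p2+p12) must be < 1"
            )


@dataclass
class ColocRegion:
    """Two aligned per-variant effect series over one variant set."""

    snp_ids: list
    pos: np.ndarray
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait_types: tuple = ("quantitative", "case_control")
    case_fraction2: float | None = None

    def __post_init__(self):
        n = len(self.snp_ids)
        for name in ("pos", "beta1", "se1", "beta2", "se2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ParameterError(f"region field {name} length mismatch")
        for t in self.trait_types:
            if t not in TRAIT_TYPES:
                raise ParameterError(f"unknown trait type {t!r}")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0):
            raise ParameterError("standard errors must be > 0")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class ColocResult:
    """Posterior probabilities for H0..H4 over one region."""

    pp: np.ndarray  # length 5, sums to 1
    priors: ColocPriors
    n_snps: int
    top_shared_variant: str

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def as_dict(self) -> dict:
        d = {f"pp{i}": float(self.pp[i]) for i in range(5)}
        d["n_snps"] = self.n_snps
        d["top_shared_variant"] = self.top_shared_variant
        return d


def extract_region(
    sumstats1: pd.DataFrame,
    sumstats2: pd.DataFrame,
    anchor_pos: int,
    flank_kb: float = 500.0,
    trait_types: tuple = ("quantitative", "case_control"),
    anchor_chr: str | None = None,
    palindromic_eaf_limit: float = 0.42,
) -> ColocRegion:
    """Pair the two traits' effects over variants within ±flank of an anchor.

    Keeps the intersection of variants present in both tables with
    ``|pos - anchor_pos| <= flank_kb * 1000`` (and matching chromosome when
    ``anchor_chr`` is given), harmonizes trait 2 onto trait 1's effect
    alleles, and returns the aligned series.  Raises ``RegionError`` when no
    variant survives.
    """
    validate_sumstats(sumstats1)
    validate_sumstats(sumstats2)
    if flank_kb < 0:
        raise ParameterError("flank_kb must be >= 0")
    window = sumstats1[np.abs(sumstats1["pos"] - anchor_pos) <= flank_kb * 1000.0]
    if anchor_chr is not None:
        window = window[window["chr"].astype(str) == str(anchor_chr)]
    if window.empty:
        raise RegionError(f"no trait-1 variants within ±{flank_kb} kb of {anchor_pos}")
    paired = retained(harmonize(window, sumstats2, palindromic_eaf_limit=palindromic_eaf_limit))
    if paired.empty:
        raise RegionError("no shared, harmonizable variants in the region")
    paired = paired.sort_values("pos", kind="mergesort")
    return ColocRegion(
        snp_ids=list(paired["snp"]),
        pos=paired["pos"].to_numpy(float),
        beta1=paired["beta_exposure"].to_numpy(float),
        se1=paired["se_exposure"].to_numpy(float),
        beta2=paired["beta_outcome"].to_numpy(float),
        se2=paired["se_outcome"].to_numpy(float),
        trait_types=tuple(trait_types),
    )


def log_abf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor for one association.

    With ``z = beta/se`` and shrinkage ``r = prior_sd^2/(prior_sd^2 + se^2)``:
    ``log ABF = 0.5*(log(1 - r) + r*z^2)``.  Positive values favour a real
    effect; ``se -> inf`` gives 0 (no information).
    """
    if prior_sd <= 0:
        raise ParameterError("prior_sd must be > 0")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ParameterError("se must be > 0")
    z2 = (beta / se) ** 2
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (np.log1p(-r) + r * z2)


def _prior_sd_for(trait_type: str, prior_sd_quant: float, prior_sd_cc: float) -> float:
    return prior_sd_quant if trait_type == "quantitative" else prior_sd_cc


def coloc_abf(
    region: ColocRegion,
    priors: ColocPriors | None = None,
    prior_sd_quant: float = PRIOR_SD_QUANTITATIVE,
    prior_sd_cc: float = PRIOR_SD_CASE_CONTROL,
) -> ColocResult:
    """Enumerate the five hypotheses over a region and return PP0..PP4.

    In log space, with per-variant log ABFs ``l1`` and ``l2``::

        L1  = logsumexp(l1)          # one causal variant, trait 1
        L2  = logsumexp(l2)          # one causal variant, trait 2
        L12 = logsumexp(l1 + l2)     # one shared causal variant

    and the distinct-variant (H3) mass is ``exp(L1)*exp(L2) - exp(L12)``
    computed stably.  Unnormalized posteriors are
    ``{1, p1*L1, p2*L2, p1*p2*L12_distinct, p12*L12}`` (log scale), then
    normalized.  A single-variant region has PP3 = 0 exactly: no distinct
    pair of variants exists.
    """
    priors = priors or ColocPriors()
    priors.validate(region.n_snps)
    sd1 = _prior_sd_for(region.trait_types[0], prior_sd_quant, prior_sd_cc)
    sd2 = _prior_sd_for(region.trait_types[1], prior_sd_quant, prior_sd_cc)
    l1 = log_abf(region.beta1, region.se1, sd1)
    l2 = log_abf(region.beta2, region.se2, sd2)

    big1 = logsumexp(l1)
    big2 = logsumexp(l2)
    shared = l1 + l2
    big12 = logsumexp(shared)
    # log(exp(big1+big2) - exp(big12)); the subtraction is exact when only
    # one variant exists, in which case H3 has zero mass.
    diff = big12 - (big1 + big2)
    if diff >= 0:
        log_distinct = -np.inf
    else:
        log_distinct = big1 + big2 + np.log1p(-np.exp(diff))

    lp = np.array([
        0.0,
        np.log(priors.p1) + big1,
        np.log(priors.p2) + big2,
        np.log(priors.p1) + np.log(priors.p2) + log_distinct,
        np.log(priors.p12) + big12,
    ])
    pp = np.exp(lp - logsumexp(lp))
    pp /= pp.sum()
    top = region.snp_ids[int(np.argmax(shared))]
    return ColocResult(pp=pp, priors=priors, n_snps=region.n_snps, top_shared_variant=top)


def coloc_decision(result: ColocResult, threshold: float = 0.8) -> bool:
    """True when the shared-causal-variant posterior PP4 strictly exceeds the
    threshold (default 0.8; a region at exactly the threshold does not pass)."""
    if not (0 < threshold < 1):
        raise ParameterError("threshold must lie in (0, 1)")
    return result.pp4 > threshold


def coloc_table(named_results: dict[str, ColocResult]) -> pd.DataFrame:
    """One row per target: n_snps, PP0..PP4 and the top shared variant."""
    rows = []
    for label, res in named_results.items():
        row = {"target": label}
        row.update(res.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
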