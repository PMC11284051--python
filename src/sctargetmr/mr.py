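"""Two-sample Mendelian randomization estimators and sensitivity statistics.

All estimators consume a harmonized instrument table (see
:mod:`sctargetmr.instruments`): per instrument, the exposure effect ``beta_x``
with standard error ``se_x`` and the outcome effect ``beta_y`` with ``se_y``,
both expressed per copy of the same effect allele.  For a binary outcome the
betas are log odds ratios, so the causal estimate is a log odds ratio per
unit of exposure and ``exp(beta)`` is the odds ratio reported alongside it.

Estimators implemented:

* Wald ratio — single instrument, ``beta_y / beta_x`` with a first-order
  (default) or second-order delta standard error.
* IVW — fixed-effect inverse-variance-weighted pooling, algebraically the
  zero-intercept weighted least-squares slope of ``beta_y`` on ``beta_x``
  with weights ``1/se_y**2``; a multiplicative random-effects variant is
  available behind a flag.
* MR-Egger — the same regression with a free intercept; a non-zero intercept
  signals directional pleiotropy.  Standard errors carry the conventional
  multiplicative overdispersion factor floored at 1, and p-values use the
  t distribution with n-2 degrees of freedom.
* Weighted median — consistent when instruments carrying at least half the
  weight are valid; standard error by seeded parametric bootstrap.
* Cochran's Q — heterogeneity of the per-instrument ratios about the IVW
  estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ParameterError
from .instruments import retained

#: reported p-values are floored here to avoid exact zeros in output tables
P_FLOOR = 1e-300


@dataclass
class MRResult:
    """A single causal estimate on the log-odds (or outcome-unit) scale."""

    method: str
    n_snps: int
    beta: float
    se: float
    pval: float
    odds_ratio: float
    ci_low: float
    ci_high: float


@dataclass
class SensitivityResult:
    """Heterogeneity and pleiotropy diagnostics for an instrument set."""

    cochran_q: float = np.nan
    q_df: int = 0
    q_pval: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_pval: float = np.nan


@dataclass
class MRSummary:
    """Primary estimate plus whatever sensitivity analyses the SNP count permits."""

    primary: MRResult
    egger: MRResult | None = None
    weighted_median: MRResult | None = None
    sensitivity: SensitivityResult | None = None
    extra: dict = field(default_factory=dict)


def _two_sided_normal_p(z: np.ndarray | float) -> np.ndarray | float:
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)


def beta_to_or(beta: float, se: float, level: float = 0.95):
    """Convert a log-odds estimate to OR, normal CI and two-sided p-value.

    Returns ``(odds_ratio, ci_low, ci_high, pval)``.  Display code rounds OR
    and CI to 2 decimals and the p-value to 3; a p printed as 0.000 means
    p < 0.0005.
    """
    if se < 0:
        raise ParameterError("se must be >= 0")
    if not (0 < level < 1):
        raise ParameterError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    or_ = float(np.exp(beta))
    lo = float(np.exp(beta - z * se))
    hi = float(np.exp(beta + z * se))
    p = float(_two_sided_normal_p(beta / se)) if se > 0 else (1.0 if beta == 0 else P_FLOOR)
    return or_, lo, hi, p


def _make_result(method: str, n: int, beta: float, se: float,
                 pval: float | None = None, level: float = 0.95) -> MRResult:
    or_, lo, hi, p_normal = beta_to_or(beta, se, level)
    return MRResult(
        method=method, n_snps=int(n), beta=float(beta), se=float(se),
        pval=float(p_normal if pval is None else max(pval, P_FLOOR)),
        odds_ratio=or_, ci_low=lo, ci_high=hi,
    )


def _arrays(instruments: pd.DataFrame):
    kept = retained(instruments) if "excluded_reason" in instruments.columns else instruments
    bx = kept["beta_exposure"].to_numpy(float)
    sx = kept["se_exposure"].to_numpy(float)
    by = kept["beta_outcome"].to_numpy(float)
    sy = kept["se_outcome"].to_numpy(float)
    if np.any(sy <= 0) or np.any(sx < 0):
        raise ParameterError("instrument standard errors must be positive")
    return bx, sx, by, sy


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(instruments: pd.DataFrame, second_order: bool = False) -> MRResult:
    """Single-instrument causal estimate ``beta_y / beta_x``.

    The default first-order standard error ``se_y / |beta_x|`` ignores
    exposure-side uncertainty; ``second_order=True`` adds the delta-method
    term ``beta_y**2 * se_x**2 / beta_x**4``.
    """
    bx, sx, by, sy = _arrays(instruments)
    if len(bx) != 1:
        raise ContractError(f"wald_ratio requires exactly 1 instrument, got {len(bx)}")
    bx, sx, by, sy = bx[0], sx[0], by[0], sy[0]
    if bx == 0:
        raise ParameterError("wald_ratio undefined for zero exposure beta")
    beta = by / bx
    var = sy**2 / bx**2
    if second_order:
        var += by**2 * sx**2 / bx**4
    return _make_result("wald_ratio", 1, beta, np.sqrt(var))


def ivw(instruments: pd.DataFrame, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate over two or more instruments.

    Fixed-effect by default: ``beta = sum(w*bx*by) / sum(w*bx^2)`` with
    ``w = 1/se_y^2`` and ``se = sqrt(1/sum(w*bx^2))``.  With
    ``random_effects=True`` the standard error is inflated by the
    multiplicative overdispersion factor ``max(1, sqrt(Q/(n-1)))``.
    """
    bx, _, by, sy = _arrays(instruments)
    n = len(bx)
    if n < 2:
        raise ContractError("ivw requires >= 2 instruments; use wald_ratio")
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / denom
    se = np.sqrt(1.0 / denom)
    if random_effects:
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (n - 1)))
    return _make_result("ivw", n, beta, se)


def _wls_with_intercept(x, y, w):
    """Closed-form weighted least squares of y on x with intercept.

    Returns (intercept, slope, var_intercept, var_slope), the variances being
    the unscaled diagonal of (X' W X)^-1.
    """
    sw = np.sum(w)
    swx = np.sum(w * x)
    swy = np.sum(w * y)
    swxx = np.sum(w * x * x)
    swxy = np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ParameterError("degenerate design in weighted regression")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return intercept, slope, swxx / det, sw / det


def mr_egger(instruments: pd.DataFrame) -> tuple[MRResult, SensitivityResult]:
    """MR-Egger regression: weighted regression of outcome on exposure betas
    with a free intercept.

    Instruments are oriented so every exposure beta is positive before the
    fit (the conventional sign alignment).  Returns the slope as the causal
    estimate and the intercept with its p-value as the pleiotropy diagnostic;
    both use t(n-2) p-values and a residual overdispersion factor floored
    at 1.
    """
    bx, _, by, sy = _arrays(instruments)
    n = len(bx)
    if n < 3:
        raise ContractError("mr_egger requires >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = 1.0 / sy**2
    intercept, slope, var_int, var_slope = _wls_with_intercept(x, y, w)
    resid = y - intercept - slope * x
    s2 = float(np.sum(w * resid**2) / (n - 2))
    scale = max(1.0, s2)
    se_slope = float(np.sqrt(var_slope * scale))
    se_int = float(np.sqrt(var_int * scale))
    p_slope = max(float(2 * stats.t.sf(abs(slope / se_slope), df=n - 2)), P_FLOOR)
    p_int = max(float(2 * stats.t.sf(abs(intercept / se_int), df=n - 2)), P_FLOOR)
    result = _make_result("egger", n, slope, se_slope, pval=p_slope)
    sens = SensitivityResult(
        egger_intercept=float(intercept),
        egger_intercept_se=se_int,
        egger_intercept_pval=p_int,
    )
    return result, sens


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the per-instrument Wald ratios.

    Inverse-variance weights ``bx^2/se_y^2`` (first-order ratio variance);
    the estimate is consistent as long as valid instruments carry more than
    half the total weight.  The standard error comes from a parametric
    bootstrap (``n_boot`` draws, seeded) that re-samples both exposure and
    outcome betas from their reported sampling distributions.
    """
    bx, sx, by, sy = _arrays(instruments)
    n = len(bx)
    if n < 3:
        raise ContractError("weighted_median requires >= 3 instruments")
    if np.any(bx == 0):
        raise ParameterError("weighted_median undefined with a zero exposure beta")
    ratios = by / bx
    weights = bx**2 / sy**2
    est = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.standard_normal(n) * sx
        byb = by + rng.standard_normal(n) * sy
        bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
        boots[b] = _weighted_median(byb / bxb, bxb**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _make_result("weighted_median", n, est, se)


def cochran_q(instruments: pd.DataFrame) -> SensitivityResult:
    """Cochran's Q heterogeneity of the per-instrument ratios.

    ``Q = sum(w_j * (ratio_j - beta_ivw)^2)`` with first-order ratio weights
    ``w_j = bx_j^2 / se_y_j^2``; p-value from chi-square with n-1 degrees of
    freedom.
    """
    bx, _, by, sy = _arrays(instruments)
    n = len(bx)
    if n < 2:
        raise ContractError("cochran_q requires >= 2 instruments")
    if np.any(bx == 0):
        raise ParameterError("cochran_q undefined with a zero exposure beta")
    w = bx**2 / sy**2
    ratios = by / bx
    beta_ivw = np.sum(w * ratios) / np.sum(w)  # identical to the IVW slope
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    df = n - 1
    return SensitivityResult(cochran_q=q, q_df=df, q_pval=float(stats.chi2.sf(q, df)))


def run_mr(
    instruments: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    random_effects: bool = False,
) -> MRSummary:
    """Dispatch the appropriate estimator for the instrument count.

    One instrument: Wald ratio.  Two or more: fixed-effect IVW.  With three
    or more, MR-Egger, the weighted median and Cochran's Q are attached as
    sensitivity analyses (Q is attached from two onward).
    """
    kept = retained(instruments) if "excluded_reason" in instruments.columns else instruments
    n = len(kept)
    if n == 0:
        raise ContractError("run_mr requires at least 1 retained instrument")
    if n == 1:
        return MRSummary(primary=wald_ratio(kept))
    summary = MRSummary(primary=ivw(kept, random_effects=random_effects))
    sens = cochran_q(kept)
    if n >= 3:
        egger_res, egger_sens = mr_egger(kept)
        sens.egger_intercept = egger_sens.egger_intercept
        sens.egger_intercept_se = egger_sens.egger_intercept_se
        sens.egger_intercept_pval = egger_sens.egger_intercept_pval
        summary.egger = egger_res
        summary.weighted_median = weighted_median(kept, n_boot=n_boot, seed=seed)
    summary.sensitivity = sens
    return summary


def results_table(named_results: dict[str, MRResult]) -> pd.DataFrame:
    """Tabulate MR results, one row per (label, method), in report style."""
    rows = []
    for label, res in named_results.items():
        rows.append({
            "target": label, "method": res.method, "nsnp": res.n_snps,
            "beta": res.beta, "se": res.se, "pval": res.pval,
            "or": res.odds_ratio, "ci_low": res.ci_low, "ci_high": res.ci_high,
        })
    return pd.DataFrame(rows)
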