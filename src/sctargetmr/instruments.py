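"""Instrument selection and harmonization for two-sample MR.

Summary statistics travel as pandas DataFrames with the column set
``SUMSTATS_COLUMNS`` (one row per variant, one table per trait).  Instrument
selection keeps genome-wide-significant variants, LD clumping greedily thins
them to an approximately independent set, and harmonization aligns exposure
and outcome effects to a common effect allele before the MR estimators see
them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError

logger = logging.getLogger("sctargetmr")

#: canonical column order for a summary-statistics table
SUMSTATS_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

#: columns of a harmonized exposure/outcome instrument table
HARMONIZED_COLUMNS = [
    "snp", "chr", "pos", "ea", "oa",
    "beta_exposure", "se_exposure", "beta_outcome", "se_outcome",
    "eaf", "flipped", "excluded_reason",
]

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


# ---------------------------------------------------------------------------
# summary-statistics I/O
# ---------------------------------------------------------------------------

def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check a summary-statistics table against the schema; returns the table."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"summary statistics missing columns: {missing}")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise ParameterError(f"duplicate variant id in summary statistics: {dup!r}")
    se = df["se"].to_numpy(float)
    if not np.all(se > 0):
        raise ParameterError("all standard errors must be > 0")
    p = df["pval"].to_numpy(float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    return df


def read_sumstats(path) -> pd.DataFrame:
    """Read a tab-separated summary-statistics table."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str, "ea": str, "oa": str})
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse summary statistics: {exc}") from exc
    return validate_sumstats(df)


def write_sumstats(df: pd.DataFrame, path) -> None:
    validate_sumstats(df)
    df.to_csv(path, sep="\t", index=False, columns=SUMSTATS_COLUMNS)


# ---------------------------------------------------------------------------
# LD matrix
# ---------------------------------------------------------------------------

class LDMatrix:
    """Pairwise correlation ``r`` among variants.

    Parameters
    ----------
    snp_ids
        Variant identifiers in matrix order.
    r
        Square symmetric correlation matrix with unit diagonal.
    """

    def __init__(self, snp_ids, r):
        snp_ids = list(snp_ids)
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] != len(snp_ids):
            raise ParameterError("LD matrix shape does not match the variant id list")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ParameterError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-6):
            raise ParameterError("LD matrix diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-8):
            raise ParameterError("LD correlations must satisfy |r| <= 1")
        self.snp_ids = snp_ids
        self.r = r
        self._index = {s: i for i, s in enumerate(snp_ids)}

    def __contains__(self, snp_id) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants."""
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", index_label="snp"
        )

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: cannot parse LD matrix: {exc}") from exc
        return cls(list(df.columns), df.to_numpy(float))


# ---------------------------------------------------------------------------
# instrument selection and clumping
# ---------------------------------------------------------------------------

def select_instruments(sumstats: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Variants with ``pval < p_threshold``, sorted by significance.

    Ties on the p-value are broken by (chr, pos) so the candidate order, and
    hence the greedy clumping result, is fully deterministic.
    """
    if not (0 < p_threshold <= 1):
        raise ParameterError("p_threshold must lie in (0, 1]")
    validate_sumstats(sumstats)
    hits = sumstats[sumstats["pval"] < p_threshold]
    return hits.sort_values(["pval", "chr", "pos"], kind="mergesort").reset_index(drop=True)


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    r2_threshold: float,
    window_kb: float,
) -> pd.DataFrame:
    """Greedy LD clumping of a candidate instrument table.

    Repeatedly promotes the most significant remaining candidate to index
    variant, then discards every remaining candidate on the same chromosome
    within ``window_kb`` kilobases (base-pair distance <= window_kb * 1000)
    whose squared correlation with the index is >= ``r2_threshold``.
    Candidates absent from the LD matrix are discarded: their independence
    cannot be certified.
    """
    if not (0 < r2_threshold <= 1):
        raise ParameterError("r2_threshold must lie in (0, 1]")
    if window_kb < 0:
        raise ParameterError("window_kb must be >= 0")
    ordered = candidates.sort_values(["pval", "chr", "pos"], kind="mergesort")
    kept_rows = []
    kept_index: list[tuple[str, str, int]] = []  # (snp, chr, pos)
    window_bp = window_kb * 1000.0
    for row in ordered.itertuples(index=False):
        if row.snp not in ld:
            logger.warning("clumping: %s absent from LD matrix; discarded", row.snp)
            continue
        conflict = False
        for snp, chrom, pos in kept_index:
            if row.chr != chrom or abs(row.pos - pos) > window_bp:
                continue
            if ld.r2(row.snp, snp) >= r2_threshold:
                conflict = True
                break
        if not conflict:
            kept_rows.append(row)
            kept_index.append((row.snp, row.chr, row.pos))
    return pd.DataFrame(kept_rows, columns=list(ordered.columns)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in _PALINDROMIC


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_limit: float = 0.42,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    For each exposure variant the outcome record with the same id is located.
    If the outcome's alleles are swapped relative to the exposure, the outcome
    beta sign is flipped and its allele frequency complemented.  Palindromic
    variants (A/T or C/G) whose effect-allele frequency is missing or falls
    inside the ambiguity band (limit, 1 - limit) are excluded, as are variants
    absent from the outcome or with irreconcilable alleles.  Excluded rows are
    retained in the output with ``excluded_reason`` set, so the harmonization
    log is complete.
    """
    if not (0 < palindromic_eaf_limit < 0.5):
        raise ParameterError("palindromic_eaf_limit must lie in (0, 0.5)")
    validate_sumstats_like(exposure)
    validate_sumstats(outcome)
    out_by_snp = {r.snp: r for r in outcome.itertuples(index=False)}

    records = []
    for row in exposure.itertuples(index=False):
        bx = getattr(row, "beta_exposure", None)
        sx = getattr(row, "se_exposure", None)
        if bx is None:
            bx, sx = row.beta, row.se
        rec = {
            "snp": row.snp, "chr": row.chr, "pos": row.pos,
            "ea": row.ea, "oa": row.oa,
            "beta_exposure": bx, "se_exposure": sx,
            "beta_outcome": np.nan, "se_outcome": np.nan,
            "eaf": row.eaf, "flipped": False, "excluded_reason": None,
        }
        out = out_by_snp.get(row.snp)
        if out is None:
            rec["excluded_reason"] = "missing_in_outcome"
            records.append(rec)
            continue
        if (out.ea, out.oa) == (row.ea, row.oa):
            beta_out, se_out, eaf_out, flipped = out.beta, out.se, out.eaf, False
        elif (out.ea, out.oa) == (row.oa, row.ea):
            beta_out, se_out, flipped = -out.beta, out.se, True
            eaf_out = 1.0 - out.eaf if pd.notna(out.eaf) else np.nan
        else:
            rec["excluded_reason"] = "allele_mismatch"
            records.append(rec)
            continue
        if _is_palindromic(str(row.ea), str(row.oa)):
            freq = rec["eaf"] if pd.notna(rec["eaf"]) else eaf_out
            ambiguous = (
                pd.isna(freq)
                or palindromic_eaf_limit < float(freq) < 1.0 - palindromic_eaf_limit
            )
            if ambiguous:
                rec["excluded_reason"] = "palindromic_ambiguous"
                records.append(rec)
                continue
        rec["beta_outcome"] = beta_out
        rec["se_outcome"] = se_out
        rec["flipped"] = flipped
        if pd.isna(rec["eaf"]):
            rec["eaf"] = eaf_out
        records.append(rec)
    harmonized = pd.DataFrame(records, columns=HARMONIZED_COLUMNS)
    if harmonized["snp"].duplicated().any():
        raise ParameterError("duplicate variant ids in exposure set")
    n_dropped = harmonized["excluded_reason"].notna().sum()
    if n_dropped:
        logger.info("harmonize: excluded %d of %d variants", n_dropped, len(harmonized))
    return harmonized


def validate_sumstats_like(df: pd.DataFrame) -> None:
    """Accept either a raw sumstats table or an already-harmonized set."""
    if {"beta_exposure", "se_exposure"}.issubset(df.columns):
        needed = {"snp", "chr", "pos", "ea", "oa", "eaf"}
        missing = needed - set(df.columns)
        if missing:
            raise ParameterError(f"harmonized exposure set missing columns: {sorted(missing)}")
    else:
        validate_sumstats(df)


def retained(harmonized: pd.DataFrame) -> pd.DataFrame:
    """The harmonized rows that survived every exclusion rule."""
    return harmonized[harmonized["excluded_reason"].isna()].reset_index(drop=True)


def write_harmonization_log(harmonized: pd.DataFrame, path) -> None:
    """Write the full harmonization table, exclusion reasons included, as TSV."""
    harmonized.to_csv(path, sep="\t", index=False)
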