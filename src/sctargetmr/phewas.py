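"""Phenome-wide pleiotropy screen for a candidate drug target.

A PheWAS table holds one row per (gene, trait) association across a large
trait panel.  The screen keeps rows for the target gene below a stringent
significance threshold (2e-8 by default, strict inequality), and the verdict
is ``clean`` when nothing beyond the disease under study comes up — i.e. the
target shows no evidence of horizontal pleiotropy or likely side effects.
"""

from __future__ import annotations

import pandas as pd

from .errors import ParameterError, ParseError

PHEWAS_COLUMNS = ["gene", "trait", "trait_class", "pval", "effect"]
TRAIT_CLASSES = {"binary", "quantitative"}

#: default multiple-testing threshold of the screen
DEFAULT_ALPHA = 2e-8


def validate_phewas(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHEWAS_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"PheWAS table missing columns: {missing}")
    if table.duplicated(subset=["gene", "trait"]).any():
        raise ParameterError("PheWAS table has duplicate (gene, trait) pairs")
    bad = ~table["trait_class"].isin(TRAIT_CLASSES)
    if bad.any():
        raise ParameterError(f"unknown trait_class values: {sorted(table.loc[bad, 'trait_class'].unique())}")
    p = table["pval"]
    if (p <= 0).any() or (p > 1).any():
        raise ParameterError("PheWAS p-values must lie in (0, 1]")
    return table


def read_phewas(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "trait": str, "trait_class": str})
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse PheWAS table: {exc}") from exc
    return validate_phewas(df)


def write_phewas(table: pd.DataFrame, path) -> None:
    validate_phewas(table)
    table.to_csv(path, sep="\t", index=False, columns=PHEWAS_COLUMNS)


def screen(table: pd.DataFrame, target: str, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Associations of ``target`` with ``pval < alpha``, most significant first.

    The inequality is strict: a record at exactly the threshold is excluded.
    """
    if not (0 < alpha <= 1):
        raise ParameterError("alpha must lie in (0, 1]")
    validate_phewas(table)
    hits = table[(table["gene"] == target) & (table["pval"] < alpha)]
    return hits.sort_values("pval", kind="mergesort").reset_index(drop=True)


def pleiotropy_verdict(significant: pd.DataFrame, disease_trait: str = "multiple sclerosis") -> str:
    """``clean`` when no off-target trait is significant, else ``flagged``.

    The disease under study is not an off-target signal: rows whose trait
    name contains ``disease_trait`` (case-insensitive substring) are ignored.
    """
    if significant.empty:
        return "clean"
    off_target = significant[
        ~significant["trait"].str.lower().str.contains(disease_trait.lower(), regex=False)
    ]
    return "clean" if off_target.empty else "flagged"
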