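"""Benchmarking against reference gene sets and replicate quality scoring.

Genes are ranked by Bayes Factor (descending) and swept top-down; at each
rank, precision and recall are computed over the reference genes only
(non-reference genes occupy rows but never count as true or false
positives).  FDR is defined as 1 - precision, row-wise.  The screen-level
performance summary is the F1 score taken at the table row whose BF is
nearest to, but greater than, the hit threshold (BF = 5 by convention).

Replicate quality is Cohen's D between the fold-change distributions of
guides targeting reference non-essential and essential genes: the
standardised separation a classifier has to work with.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "precision_recall",
    "f_measure",
    "cohens_d",
    "quality_report",
    "count_expression_false_positives",
]


def precision_recall(gene_bf: pd.Series, essential: set[str],
                     nonessential: set[str]) -> pd.DataFrame:
    """Rank-swept precision/recall/FDR table over all genes.

    Rows are sorted by BF descending (ties broken by gene name so the
    order is reproducible).  TP at a row counts reference-essential genes
    at or above it, FP reference-non-essential genes at or above it.
    Precision of a prefix containing no reference gene is defined as 1.0
    (no false discovery has been made yet).
    """
    essential, nonessential = set(essential), set(nonessential)
    table = gene_bf.rename("BF").rename_axis("GENE").reset_index()
    n_ess = int(table["GENE"].isin(essential).sum())
    n_non = int(table["GENE"].isin(nonessential).sum())
    if n_ess == 0 or n_non == 0:
        raise ValueError(
            f"need >= 1 gene from each reference set in the ranking; found "
            f"{n_ess} essential, {n_non} non-essential"
        )
    table = table.sort_values(["BF", "GENE"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    tp = table["GENE"].isin(essential).cumsum()
    fp = table["GENE"].isin(nonessential).cumsum()
    denom = (tp + fp).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(denom > 0, tp / np.maximum(denom, 1), 1.0)
    table["Precision"] = precision
    table["Recall"] = tp / n_ess
    table["FDR"] = 1.0 - table["Precision"]
    return table


def f_measure(pr_table: pd.DataFrame, bf_threshold: float = 5.0) -> float:
    """F1 score at the row whose BF is nearest to but above the threshold.

    A gene exactly at the threshold is rarely present, so the classifier
    is evaluated at the last rank still strictly above it.  Returns 0.0
    (with a warning) when no gene scores above the threshold.
    """
    above = pr_table[pr_table["BF"] > bf_threshold]
    if above.empty:
        log.warning("no gene with BF > %g; F-measure defined as 0", bf_threshold)
        return 0.0
    row = above.loc[above["BF"].idxmin()]
    p, r = float(row["Precision"]), float(row["Recall"])
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def cohens_d(fold_changes: pd.DataFrame, essential: set[str],
             nonessential: set[str], replicate: str) -> float:
    """Replicate quality score: standardised essential/non-essential split.

    D = (mean fc of non-essential reference guides - mean fc of essential
    reference guides) / pooled SD, with the two-group pooled SD
    sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).  Positive D means the
    essential guides drop out faster, as they should.
    """
    if replicate not in fold_changes.columns or replicate == "GENE":
        raise ValueError(f"unknown replicate {replicate!r}")
    genes = fold_changes["GENE"]
    ess_fc = fold_changes.loc[genes.isin(set(essential)), replicate].to_numpy()
    non_fc = fold_changes.loc[genes.isin(set(nonessential)), replicate].to_numpy()
    if ess_fc.size < 2 or non_fc.size < 2:
        raise ValueError(
            f"need >= 2 reference guides per class in replicate {replicate!r}; "
            f"found {ess_fc.size} essential, {non_fc.size} non-essential"
        )
    n1, n2 = non_fc.size, ess_fc.size
    s1, s2 = non_fc.std(ddof=1), ess_fc.std(ddof=1)
    pooled = math.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    if pooled == 0.0:
        raise ValueError("zero pooled standard deviation")
    return float((non_fc.mean() - ess_fc.mean()) / pooled)


def quality_report(fold_changes: pd.DataFrame, essential: set[str],
                   nonessential: set[str]) -> pd.DataFrame:
    """Cohen's D and reference guide counts for every replicate."""
    genes = fold_changes["GENE"]
    n_ess = int(genes.isin(set(essential)).sum())
    n_non = int(genes.isin(set(nonessential)).sum())
    rows = []
    for rep in (c for c in fold_changes.columns if c != "GENE"):
        rows.append({
            "REPLICATE": rep,
            "COHENS_D": cohens_d(fold_changes, essential, nonessential, rep),
            "N_ESS_GUIDES": n_ess,
            "N_NON_GUIDES": n_non,
        })
    return pd.DataFrame(rows).set_index("REPLICATE")


def count_expression_false_positives(hits: set[str], expression: pd.Series,
                                     cutoff: float = 1.0) -> int:
    """Hit genes whose log expression falls below the cutoff.

    A gene with essentially no mRNA cannot be essential, so such hits are
    audited as likely false positives.  Hits absent from the expression
    table are ignored (their count is logged).
    """
    hits = set(hits)
    known = hits & set(expression.index)
    missing = len(hits) - len(known)
    if missing:
        log.info("%d hit gene(s) absent from the expression table", missing)
    if not known:
        return 0
    return int((expression.loc[sorted(known)] < cutoff).sum())
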