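"""Correction of multi-targeting (off-target cleavage) BF inflation.

A guide that cuts the genome at extra loci depletes faster than its
on-target effect alone warrants: every double-strand break carries a
locus-independent fitness cost.  For guides whose only protein-coding
target is their intended gene, the excess Bayes Factor is additive in the
number of extra perfect-match loci and of 1-bp-mismatch loci:

    increment = (n_perfect - 1) * tp_perfect + n_1bp * tp_1bp

where each coefficient is the product of the per-cut toxicity and the
cleavage probability for that match class (only the products are
identifiable).  The coefficients are estimated by zero-intercept multiple
linear regression of observed BF increments -- guide BF minus the mean BF
of same-gene guides with no off-targets -- on the two locus counts, and
every guide's BF is then reduced by its profile-predicted increment.

Guides targeting more than one protein-coding gene perfectly, and
promiscuous guides (> 10 perfect or > 10 mismatched loci), are removed
from the library outright: their fitness effect confounds gene knockout
with off-target gene knockout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TARGET_MAP_COLUMNS, lookup_profiles

log = logging.getLogger(__name__)

__all__ = [
    "filter_guides",
    "compute_increments",
    "fit_offtarget_model",
    "apply_penalty",
    "OffTargetModel",
]

PROMISCUOUS_MAX_LOCI = 10


def _profiles(guides, target_map) -> pd.DataFrame:
    return lookup_profiles(guides, target_map)


def filter_guides(table: pd.DataFrame, target_map: pd.DataFrame | None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop multi-coding and promiscuous guides from a guide-indexed table.

    Returns ``(filtered_table, drop_report)`` where the report has one row
    per dropped guide with columns GENE and REASON ('multi-coding' for
    guides hitting > 1 protein-coding gene with perfect match,
    'promiscuous' for > 10 perfect-match or > 10 1-bp-mismatch loci).
    Genes losing all of their guides are warned about.
    """
    prof = _profiles(table.index, target_map)
    multi = prof["n_coding_perfect"] > 1
    promiscuous = (prof["n_perfect"] > PROMISCUOUS_MAX_LOCI) | (
        prof["n_1bp"] > PROMISCUOUS_MAX_LOCI)
    reason = pd.Series("", index=table.index, dtype=object)
    reason[promiscuous] = "promiscuous"
    reason[multi] = "multi-coding"  # takes precedence when both apply
    dropped = reason != ""
    report = pd.DataFrame({
        "GENE": table.loc[dropped, "GENE"] if "GENE" in table.columns else "",
        "REASON": reason[dropped],
    })
    report.index.name = "GUIDE"
    filtered = table.loc[~dropped]
    if "GENE" in table.columns and dropped.any():
        lost = set(table["GENE"].unique()) - set(filtered["GENE"].unique())
        for gene in sorted(lost):
            log.warning("all guides of gene %s dropped by the off-target filter",
                        gene)
    return filtered, report


def compute_increments(guide_bf: pd.Series, genes: pd.Series,
                       target_map: pd.DataFrame | None) -> pd.DataFrame:
    """BF-increment observations for the off-target regression.

    Eligible guides hit exactly one protein-coding gene with perfect match,
    none with 1-bp mismatch, and have at least one extra locus (perfect or
    mismatched); their gene must retain >= 1 clean guide (profile
    (1, 0, 1, 0)).  The response is guide BF minus the mean BF of the
    gene's clean guides; the predictors are (n_perfect - 1, n_1bp).
    Empty output is allowed.
    """
    prof = _profiles(guide_bf.index, target_map)
    clean = (
        (prof["n_perfect"] == 1) & (prof["n_1bp"] == 0)
        & (prof["n_coding_perfect"] == 1) & (prof["n_coding_1bp"] == 0)
    )
    eligible = (
        (prof["n_coding_perfect"] == 1) & (prof["n_coding_1bp"] == 0)
        & ((prof["n_perfect"] > 1) | (prof["n_1bp"] > 0))
    )
    clean_mean = guide_bf[clean].groupby(genes[clean]).mean()
    rows = []
    for guide in guide_bf.index[eligible]:
        gene = genes.loc[guide]
        if gene not in clean_mean.index:
            continue
        rows.append({
            "GUIDE": guide,
            "GENE": gene,
            "increment": float(guide_bf.loc[guide] - clean_mean.loc[gene]),
            "extra_perfect": int(prof.loc[guide, "n_perfect"] - 1),
            "n_1bp": int(prof.loc[guide, "n_1bp"]),
        })
    out = pd.DataFrame(rows, columns=["GUIDE", "GENE", "increment",
                                      "extra_perfect", "n_1bp"])
    return out.set_index("GUIDE")


@dataclass
class OffTargetModel:
    """Fitted per-locus BF increments (log2-BF units per extra locus)."""

    tp_perfect: float
    tp_1bp: float
    n_obs: int
    residual_sd: float
    raw_tp_perfect: float  # pre-clamp estimates, diagnostic
    raw_tp_1bp: float
    intercept: float | None = None  # diagnostic only; never used in the penalty

    def penalty(self, profiles: pd.DataFrame) -> pd.Series:
        """Profile-predicted BF inflation for each guide."""
        return (profiles["n_perfect"] - 1) * self.tp_perfect \
            + profiles["n_1bp"] * self.tp_1bp

    def summary(self) -> str:
        lines = [
            "Off-target BF increment model (zero intercept)",
            f"  tp_perfect : {self.tp_perfect:10.4f}  (per extra perfect-match locus)",
            f"  tp_1bp     : {self.tp_1bp:10.4f}  (per 1-bp-mismatch locus)",
            f"  n_obs      : {self.n_obs:10d}",
            f"  resid. SD  : {self.residual_sd:10.4f}",
        ]
        if self.intercept is not None:
            lines.append(f"  intercept  : {self.intercept:10.4f}  (diagnostic)")
        return "\n".join(lines)


def fit_offtarget_model(observations: pd.DataFrame, clamp: bool = True,
                        with_intercept_diagnostic: bool = False
                        ) -> OffTargetModel:
    """Zero-intercept least-squares fit of increments on locus counts.

    Requires >= 3 observations spanning >= 2 distinct predictor
    combinations with a full-rank design.  Negative coefficients are
    clamped to 0 with a warning (a DNA-cleavage penalty cannot be
    negative) unless ``clamp=False``.
    """
    if len(observations) < 3:
        raise ValueError(
            f"need >= 3 increment observations, got {len(observations)}; "
            "skip the multi-target correction"
        )
    X = observations[["extra_perfect", "n_1bp"]].to_numpy(dtype=float)
    y = observations["increment"].to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError(
            "all observations share one predictor combination; cannot fit "
            "the off-target model -- skip the correction"
        )
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError(
            "collinear off-target predictors; cannot separate tp_perfect "
            "from tp_1bp -- skip the correction"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(1, len(y) - 2)
    resid_sd = float(np.sqrt((resid ** 2).sum() / dof))
    raw_p, raw_1 = float(beta[0]), float(beta[1])
    tp_p, tp_1 = raw_p, raw_1
    if clamp:
        if tp_p < 0:
            log.warning("negative tp_perfect (%.4f) clamped to 0", tp_p)
            tp_p = 0.0
        if tp_1 < 0:
            log.warning("negative tp_1bp (%.4f) clamped to 0", tp_1)
            tp_1 = 0.0
    intercept = None
    if with_intercept_diagnostic:
        Xi = np.column_stack([X, np.ones(len(y))])
        bi, _, _, _ = np.linalg.lstsq(Xi, y, rcond=None)
        intercept = float(bi[2])
    return OffTargetModel(tp_perfect=tp_p, tp_1bp=tp_1, n_obs=len(y),
                          residual_sd=resid_sd, raw_tp_perfect=raw_p,
                          raw_tp_1bp=raw_1, intercept=intercept)


def apply_penalty(guide_bf: pd.Series, genes: pd.Series,
                  target_map: pd.DataFrame | None, model: OffTargetModel
                  ) -> tuple[pd.Series, pd.Series]:
    """Subtract each guide's predicted off-target inflation from its BF.

    Clean guides (and guides absent from the map) are unchanged.  Returns
    ``(corrected_guide_bf, corrected_gene_bf)`` with gene BFs re-summed
    from the corrected guide BFs.
    """
    prof = _profiles(guide_bf.index, target_map)
    corrected = guide_bf - model.penalty(prof)
    corrected.name = guide_bf.name
    gene_bf = corrected.groupby(genes).sum()
    gene_bf.index.name = "GENE"
    gene_bf.name = "BF"
    return corrected, gene_bf
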