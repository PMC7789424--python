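"""Readers and writers for the tab-separated formats used by the pipeline.

All tables are UTF-8 TSV with a header row.  Read-count and fold-change
tables have the guide id in column 1 and the gene symbol in column 2;
every remaining column is a sample (read counts) or a replicate (fold
changes).  Gene symbols are taken verbatim -- symbol harmonisation is a
user preprocessing responsibility.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "read_read_counts",
    "read_fold_changes",
    "read_gene_list",
    "read_guide_target_map",
    "read_expression",
    "write_table",
    "CLEAN_PROFILE",
    "TARGET_MAP_COLUMNS",
]

#: Guide-target map column order: perfect-match loci, 1-bp-mismatch loci,
#: protein-coding genes hit with perfect match, and with 1-bp mismatch.
TARGET_MAP_COLUMNS = ["n_perfect", "n_1bp", "n_coding_perfect", "n_coding_1bp"]

#: Profile assumed for guides absent from the map: one perfect-match site
#: (the intended one), no mismatched sites, one coding gene hit.
CLEAN_PROFILE = (1, 0, 1, 0)


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})


def _guide_gene_table(df: pd.DataFrame, path, kind: str,
                      numeric_kind: str, min_numeric: int = 1) -> pd.DataFrame:
    if df.shape[1] < 2 + min_numeric:
        raise ValueError(
            f"{path}: {kind} table needs guide, gene and >= {min_numeric} "
            f"{numeric_kind} columns; found {df.shape[1]} columns"
        )
    guide_col, gene_col = df.columns[:2]
    dup = df[guide_col][df[guide_col].duplicated()].unique()
    if dup.size:
        raise ValueError(f"{path}: duplicate guide ids: {', '.join(map(str, dup))}")
    if df[gene_col].isna().any():
        bad = df.loc[df[gene_col].isna(), guide_col].tolist()
        raise ValueError(f"{path}: missing gene symbol for guides {bad}")
    out = df.set_index(guide_col)
    out.index.name = "GUIDE"
    out = out.rename(columns={gene_col: "GENE"})
    for col in out.columns[1:]:
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any():
            row = out.index[vals.isna()][0]
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            )
        out[col] = vals
    return out


def read_read_counts(path) -> pd.DataFrame:
    """Read a guide-level read-count table.

    Returns a DataFrame indexed by guide id with a 'GENE' column followed
    by one integer column per sample, in file order.
    """
    df = _guide_gene_table(_read_tsv(path), path, "read-count", "sample",
                           min_numeric=2)
    for col in df.columns[1:]:
        vals = df[col]
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ValueError(f"{path}: negative count in column {col!r}, row {row!r}")
        if not np.allclose(vals, np.round(vals)):
            row = df.index[~np.isclose(vals, np.round(vals))][0]
            raise ValueError(
                f"{path}: non-integer count in column {col!r}, row {row!r}"
            )
        df[col] = vals.astype(np.int64)
    return df


def read_fold_changes(path) -> pd.DataFrame:
    """Read a guide-level log2 fold-change table.

    Any header names are accepted; every column after guide and gene is
    treated as one replicate.
    """
    df = _guide_gene_table(_read_tsv(path), path, "fold-change", "replicate")
    for col in df.columns[1:]:
        df[col] = df[col].astype(float)
        if not np.isfinite(df[col]).all():
            row = df.index[~np.isfinite(df[col])][0]
            raise ValueError(
                f"{path}: non-finite fold change in column {col!r}, row {row!r}"
            )
    return df


def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line gene list (optional 'GENE' header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    genes = [g for g in genes if g]
    if genes and genes[0].upper() in {"GENE", "GENES", "SYMBOL"}:
        genes = genes[1:]
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return set(genes)


def read_guide_target_map(path) -> pd.DataFrame:
    """Read the guide -> off-target locus-count map.

    Expected columns: guide id, then n_perfect, n_1bp, n_coding_perfect,
    n_coding_1bp.  Guides absent from the map are treated downstream as
    having the clean profile ``CLEAN_PROFILE``.
    """
    df = _read_tsv(path)
    if df.shape[1] < 5:
        raise ValueError(f"{path}: target map needs 5 columns, found {df.shape[1]}")
    guide_col = df.columns[0]
    dup = df[guide_col][df[guide_col].duplicated()].unique()
    if dup.size:
        raise ValueError(f"{path}: duplicate guide ids: {', '.join(map(str, dup))}")
    out = df.set_index(guide_col).iloc[:, :4]
    out.columns = TARGET_MAP_COLUMNS
    out.index.name = "GUIDE"
    for col in TARGET_MAP_COLUMNS:
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals.dropna(), np.round(vals.dropna())):
            raise ValueError(f"{path}: non-integer value in column {col!r}")
        if (vals < 0).any():
            raise ValueError(f"{path}: negative count in column {col!r}")
        out[col] = vals.astype(np.int64)
    bad = out.index[out["n_coding_perfect"] > out["n_perfect"]]
    if bad.size:
        raise ValueError(
            f"{path}: n_coding_perfect > n_perfect for guides {list(bad[:5])}"
        )
    bad = out.index[out["n_perfect"] < 1]
    if bad.size:
        raise ValueError(
            f"{path}: n_perfect must be >= 1 (the intended site) for guides "
            f"{list(bad[:5])}"
        )
    return out


def read_expression(path) -> pd.Series:
    """Read a gene -> log-TPM expression table (2 columns, header row)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expression table needs 2 columns")
    s = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="coerce").values,
        index=df.iloc[:, 0].astype(str).values, name="LOG_TPM",
    )
    if s.isna().any():
        raise ValueError(f"{path}: non-numeric expression value")
    if s.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene symbols in expression table")
    s.index.name = "GENE"
    return s


def write_table(df: pd.DataFrame | pd.Series, path, float_format: str = "%.17g"):
    """Write a table as TSV, preserving index (guide/gene) and column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(df, pd.Series):
        df = df.to_frame()
    df.to_csv(path, sep="\t", float_format=float_format)
    return path


def lookup_profiles(guides, target_map: pd.DataFrame | None) -> pd.DataFrame:
    """Per-guide off-target profile, defaulting absent guides to clean."""
    idx = pd.Index(guides, name="GUIDE")
    base = pd.DataFrame(
        np.tile(np.array(CLEAN_PROFILE, dtype=np.int64), (len(idx), 1)),
        index=idx, columns=TARGET_MAP_COLUMNS,
    )
    if target_map is not None:
        common = idx.intersection(target_map.index)
        base.loc[common, TARGET_MAP_COLUMNS] = target_map.loc[
            common, TARGET_MAP_COLUMNS
        ].astype(np.int64)
    return base
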