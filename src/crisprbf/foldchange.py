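"""Guide-level log2 fold changes from raw read counts.

Each sample column gets a pseudocount added to every raw count and is then
scaled to a fixed library size (10 million reads by default), so depth
differences between samples cancel.  The fold change of a guide in an
endpoint sample is log2(normalised endpoint) - log2(normalised control);
multiple control columns are normalised then averaged before the ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["compute_fold_change", "normalize_counts"]

DEFAULT_PSEUDOCOUNT = 5.0
LIBRARY_SIZE = 10_000_000.0


def normalize_counts(counts: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                     library_size: float = LIBRARY_SIZE) -> pd.DataFrame:
    """Pseudocount-adjusted counts scaled so each sample sums to `library_size`."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    sample_cols = [c for c in counts.columns if c != "GENE"]
    raw = counts[sample_cols].astype(float) + pseudocount
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"sample column(s) with zero total reads: {bad}")
    return raw / totals * library_size


def compute_fold_change(counts: pd.DataFrame, control_samples: list[str] | str,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        library_size: float = LIBRARY_SIZE) -> pd.DataFrame:
    """Log2 fold change of every endpoint sample versus the control(s).

    Parameters
    ----------
    counts
        Read-count table indexed by guide id with a 'GENE' column followed
        by sample columns (see :func:`crisprbf.io.read_read_counts`).
    control_samples
        Name(s) of the plasmid/T0 column(s).  Several controls are
        normalised and arithmetically averaged.
    pseudocount
        Added to every raw count before normalisation.  With pseudocount 0
        any zero count would produce an infinite fold change, so zero
        counts then raise instead.

    Returns a table indexed by guide with 'GENE' and one log2 fold-change
    column per endpoint sample, in input column order.
    """
    if isinstance(control_samples, str):
        control_samples = [control_samples]
    if not control_samples:
        raise ValueError("at least one control sample is required")
    sample_cols = [c for c in counts.columns if c != "GENE"]
    missing = [c for c in control_samples if c not in sample_cols]
    if missing:
        raise ValueError(f"control column(s) not in table: {missing}")
    endpoints = [c for c in sample_cols if c not in control_samples]
    if not endpoints:
        raise ValueError("no endpoint sample columns left after removing controls")

    norm = normalize_counts(counts, pseudocount=pseudocount,
                            library_size=library_size)
    control = norm[control_samples].mean(axis=1)
    if pseudocount == 0 and ((norm[endpoints] == 0).any().any() or (control == 0).any()):
        raise ValueError(
            "zero counts with pseudocount 0 give infinite fold changes; "
            "use a positive pseudocount"
        )
    zero_everywhere = (counts[sample_cols] == 0).all(axis=1)
    if zero_everywhere.any():
        log.warning("%d guide(s) have zero reads in every sample",
                    int(zero_everywhere.sum()))

    fc = pd.DataFrame(index=counts.index)
    fc["GENE"] = counts["GENE"]
    log2_control = np.log2(control)
    for col in endpoints:
        fc[col] = np.log2(norm[col]) - log2_control
    return fc
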