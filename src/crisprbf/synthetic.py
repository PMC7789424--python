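"""Seeded generator of synthetic CRISPR knockout fitness screens.

The generator emulates the data a pooled-library dropout screen produces:
a guide x sample read-count table with a T0/plasmid control column, a
guide -> off-target locus-count map, disjoint reference gene sets sampled
from the truth classes, truth labels, and a gene-expression table for
false-positive auditing.

Each guide carries a true log2 fold change: the class effect (essential
genes deplete by `essential_shift`) plus additive per-locus off-target
depletion mirroring the locus-independent cleavage model used by the
multi-target correction.  Off-target severity is configured on the
Bayes-Factor scale (the units the correction estimates) and converted to
fold-change units through the equal-variance Gaussian log-ratio slope
|shift| / (sigma^2 ln 2) summed over replicates.  Control counts are
log-normal around the configured depth -- depth spread and fold-change
noise stay independently tunable -- and endpoint counts are
control x 2^(true fc + per-replicate Gaussian noise), rounded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import cohens_d
from .io import TARGET_MAP_COLUMNS

log = logging.getLogger(__name__)

__all__ = ["ScreenConfig", "SyntheticScreen", "generate_screen",
           "degrade_replicate", "noise_for_target_d"]


@dataclass
class ScreenConfig:
    """Study conditions for one synthetic screen.

    Defaults describe a mid-size, good-quality screen: 1000 genes x 4
    guides, 2 replicates, essential genes depleting by 3 log2 units
    against unit fold-change noise (replicate Cohen's D ~ 3), 500 reads
    per guide at T0, and an Avana-like share of multi-targeting guides
    whose per-locus BF increments default to 3.5 (extra perfect match)
    and 1.4 (1-bp mismatch).
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    n_replicates: int = 2
    fraction_essential: float = 0.2
    essential_shift: float = -3.0          # log2 fc of essential knockouts
    noise_sd_essential: float = 1.0        # per-replicate fc noise, log2 units
    noise_sd_nonessential: float = 1.0
    mean_reads_per_guide: float = 500.0    # T0 depth
    depth_log_sd: float = 0.5              # sd of ln(control reads)
    offtarget_fraction: float = 0.15       # guides carrying any off-target locus
    offtarget_fraction_nonexpressed: float | None = None
    bf_per_perfect: float = 3.5            # BF increment per extra perfect locus
    bf_per_1bp: float = 1.4                # BF increment per 1-bp-mismatch locus
    max_extra_perfect: int = 9
    max_1bp: int = 10
    multicoding_fraction: float = 0.02     # guides hitting a 2nd coding gene
    promiscuous_fraction: float = 0.01     # guides with > 10 perfect loci
    coding_1bp_fraction: float = 0.02      # off-target guides with a coding 1-bp hit
    fraction_nonexpressed: float = 0.1     # of non-essential genes, log TPM < 1
    ref_fraction_essential: float = 0.8    # truth genes sampled into references
    ref_fraction_nonessential: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_essential", "offtarget_fraction",
                     "multicoding_fraction", "promiscuous_fraction",
                     "coding_1bp_fraction", "fraction_nonexpressed",
                     "ref_fraction_essential", "ref_fraction_nonessential"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 2 or self.guides_per_gene < 1 or self.n_replicates < 1:
            raise ValueError("n_genes >= 2, guides_per_gene >= 1, "
                             "n_replicates >= 1 required")
        if self.mean_reads_per_guide <= 0:
            raise ValueError("mean_reads_per_guide must be > 0")
        if self.noise_sd_essential < 0 or self.noise_sd_nonessential < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def fc_per_perfect(self) -> float:
        """Off-target depletion (log2 fc units) per extra perfect locus."""
        return self.offtarget_fc_increments()[0]

    @property
    def fc_per_1bp(self) -> float:
        return self.offtarget_fc_increments()[1]

    def _locus_count_pmf(self):
        """Joint pmf of (extra perfect, 1-bp) locus counts per retained guide.

        Capped-geometric marginals, independent, with the all-zero cell of
        off-target guides moved to one mismatched locus; mixed with the
        clean (0, 0) profile at 1 - offtarget_fraction.  Multi-coding and
        promiscuous guides are excluded (they are filtered before
        training), which leaves this base distribution unchanged because
        those flags are drawn independently.
        """
        def capped_geometric(p, cap):
            k = np.arange(cap + 1)
            pmf = p * (1 - p) ** k
            pmf[cap] = (1 - p) ** cap
            return pmf

        pe = capped_geometric(0.45, self.max_extra_perfect)
        p1 = capped_geometric(0.35, self.max_1bp)
        joint = np.outer(pe, p1)
        joint[0, 1] += joint[0, 0]
        joint[0, 0] = 0.0
        joint *= self.offtarget_fraction
        joint[0, 0] = 1.0 - self.offtarget_fraction
        e = np.arange(self.max_extra_perfect + 1)[:, None]
        n = np.arange(self.max_1bp + 1)[None, :]
        return joint, e, n

    def _training_sizes(self) -> tuple[float, float]:
        # approximate per-class training guide counts under 10-fold
        # cross-validation (~90% of the reference guides)
        n_ess_genes = int(round(self.fraction_essential * self.n_genes))
        n_nonref_genes = self.n_genes - n_ess_genes
        n_non = max(2.0, self.ref_fraction_nonessential
                    * (1 - self.fraction_nonexpressed) * n_nonref_genes
                    * self.guides_per_gene * 0.9)
        n_ess = max(2.0, self.ref_fraction_essential * n_ess_genes
                    * self.guides_per_gene * 0.9)
        return n_ess, n_non

    def _expected_line_slope(self, dp: float, d1: float) -> float:
        """Expected fitted log-ratio slope for given per-locus depletions.

        Both class fold-change distributions are known Gaussian mixtures
        (class mean, minus the off-target depletion of each locus-count
        cell, plus Gaussian noise), and a Gaussian KDE is that mixture
        widened by the bandwidth.  This evaluates the two expected KDE
        curves on a grid, applies the same stable-region rule the
        classifier uses, and returns the OLS slope of the log ratio over
        that region -- the noise-free expectation of what the classifier
        fits.
        """
        from scipy.stats import norm

        from .density import (calibrate_threshold, fit_ratio_line,
                              stable_region_from_curves)

        joint, e, n = self._locus_count_pmf()
        offsets = (-dp * e - d1 * n).ravel()
        weights = joint.ravel()
        n_ess_train, n_non_train = self._training_sizes()

        grid = np.arange(-12.0, 6.0 + 1e-9, 0.01)

        def mixture_density(mu, sd, n_train):
            var = sd ** 2 + float(weights @ offsets ** 2
                                  - (weights @ offsets) ** 2)
            h = 0.9 * math.sqrt(max(var, 1e-12)) * n_train ** -0.2
            width = math.sqrt(sd ** 2 + h ** 2)
            keep = weights > 0
            comp = norm.pdf(grid[None, :], loc=(mu + offsets[keep])[:, None],
                            scale=width)
            return weights[keep] @ comp

        f_ess = mixture_density(self.essential_shift, self.noise_sd_essential,
                                n_ess_train)
        f_non = mixture_density(0.0, self.noise_sd_nonessential, n_non_train)
        floor = 2.0 ** -30
        ratio = np.log2(np.maximum(f_ess, floor)) - np.log2(
            np.maximum(f_non, floor))
        theta_non = calibrate_threshold(int(n_non_train))
        theta_ess = calibrate_threshold(int(n_ess_train))
        lo, hi = stable_region_from_curves(grid, f_non, ratio, theta_non,
                                           ess_density=f_ess,
                                           theta_ess=theta_ess)
        slope, _ = fit_ratio_line(grid, ratio, lo, hi)
        return slope

    def offtarget_fc_increments(self) -> tuple[float, float]:
        """Per-locus fold-change depletions matching the BF-scale targets.

        The screen-level BF response to a fold-change shift is
        n_replicates times the fitted log-ratio slope, but that slope
        itself flattens as the injected depletions widen the training
        distributions, so the conversion is solved as a fixed point on
        the expected fitted slope (see :meth:`_expected_line_slope`).
        """
        if self.essential_shift == 0 or (self.bf_per_perfect == 0
                                         and self.bf_per_1bp == 0):
            return 0.0, 0.0
        if self.noise_sd_essential == 0 and self.noise_sd_nonessential == 0:
            return 0.0, 0.0
        cached = getattr(self, "_ot_increment_cache", None)
        if cached is not None:
            return cached
        # the two depletions keep the ratio of the BF targets, so the
        # fixed point is one-dimensional in t = fc per extra perfect locus
        scale = max(self.bf_per_perfect, self.bf_per_1bp)
        rp = self.bf_per_perfect / scale
        r1 = self.bf_per_1bp / scale

        slope0 = self._expected_line_slope(0.0, 0.0)

        def excess(t: float) -> float:
            # t minus the depletion the BF targets require at the slope
            # realised when t is injected; a root is a self-consistent t
            slope = self._expected_line_slope(t * rp, t * r1)
            if slope >= 0:
                return -math.inf
            return t - scale / (abs(slope) * self.n_replicates)

        # the smallest root is the physical solution; larger roots exist
        # where massive depletion has flattened the BF response to near
        # zero, and are rejected by the slope sanity check below
        t_max = 2.0 * abs(self.essential_shift)
        n_scan = 400
        lo, hi = 0.0, None
        for step in range(1, n_scan + 1):
            t = t_max * step / n_scan
            if excess(t) >= 0:
                hi = t
                break
            lo = t
        unattainable = ValueError(
            "off-target BF increments are too large for this screen "
            "configuration: the depletion they require inflates the "
            "fold-change variance faster than the BF response grows; "
            "lower bf_per_perfect/bf_per_1bp or offtarget_fraction"
        )
        if hi is None:
            raise unattainable
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if excess(mid) >= 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-10:
                break
        t = hi
        if abs(self._expected_line_slope(t * rp, t * r1)) < 0.5 * abs(slope0):
            raise unattainable
        result = (t * rp, t * r1)
        self._ot_increment_cache = result
        return result


@dataclass
class SyntheticScreen:
    """Generator output bundle."""

    counts: pd.DataFrame          # read-count table (GENE, T0, R1..Rk)
    target_map: pd.DataFrame      # guide -> off-target locus counts
    essential_ref: set            # reference essential genes
    nonessential_ref: set         # reference non-essential genes
    truth: pd.DataFrame           # gene -> essential / expressed flags
    expression: pd.Series         # gene -> log TPM
    true_fc: pd.Series = field(default=None)  # per-guide true log2 fc
    config: ScreenConfig = field(default=None)

    @property
    def control_sample(self) -> str:
        return self.counts.columns[1]

    @property
    def replicate_samples(self) -> list[str]:
        return list(self.counts.columns[2:])


def generate_screen(config: ScreenConfig | None = None, **overrides
                    ) -> SyntheticScreen:
    """Generate one synthetic screen; bitwise deterministic given the seed."""
    cfg = config if config is not None else ScreenConfig(**overrides)
    if config is not None and overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)

    genes = np.array([f"G{i:04d}" for i in range(cfg.n_genes)])
    perm = rng.permutation(cfg.n_genes)
    n_ess = int(round(cfg.fraction_essential * cfg.n_genes))
    essential_genes = set(genes[perm[:n_ess]])
    n_nonexp = int(round(cfg.fraction_nonexpressed * (cfg.n_genes - n_ess)))
    nonexpressed_genes = set(genes[perm[n_ess:n_ess + n_nonexp]])

    if cfg.ref_fraction_essential > 0 and n_ess < 2:
        raise ValueError(
            "reference sets requested but fewer than 2 essential truth genes; "
            "raise fraction_essential"
        )

    gpg = cfg.guides_per_gene
    guide_gene = np.repeat(genes, gpg)
    guide_ids = np.array([f"{g}_g{j + 1}" for g in genes for j in range(gpg)])
    n_guides = guide_ids.size
    is_ess = np.isin(guide_gene, list(essential_genes))
    is_nonexp_gene = np.isin(guide_gene, list(nonexpressed_genes))

    # --- off-target profiles -------------------------------------------
    ot_frac = np.full(n_guides, cfg.offtarget_fraction)
    if cfg.offtarget_fraction_nonexpressed is not None:
        ot_frac[is_nonexp_gene] = cfg.offtarget_fraction_nonexpressed
    has_ot = rng.random(n_guides) < ot_frac
    geo_p = rng.geometric(0.45, n_guides) - 1
    geo_1 = rng.geometric(0.35, n_guides) - 1
    extra_perfect = np.where(has_ot, np.minimum(geo_p, cfg.max_extra_perfect), 0)
    n_1bp = np.where(has_ot, np.minimum(geo_1, cfg.max_1bp), 0)
    empty = has_ot & (extra_perfect == 0) & (n_1bp == 0)
    n_1bp[empty] = 1

    multicoding = rng.random(n_guides) < cfg.multicoding_fraction
    extra_perfect = np.where(multicoding, np.maximum(extra_perfect, 1),
                             extra_perfect)
    promiscuous = rng.random(n_guides) < cfg.promiscuous_fraction
    prom_loci = 11 + rng.integers(0, 5, n_guides)
    n_perfect = 1 + extra_perfect
    n_perfect = np.where(promiscuous, prom_loci, n_perfect)
    extra_perfect = n_perfect - 1
    coding_1bp = ((n_1bp > 0) & (rng.random(n_guides) < cfg.coding_1bp_fraction)
                  ).astype(np.int64)
    n_coding_perfect = np.where(multicoding, 2, 1)
    off_gene_ess = rng.random(n_guides) < cfg.fraction_essential

    target_map = pd.DataFrame({
        "n_perfect": n_perfect.astype(np.int64),
        "n_1bp": n_1bp.astype(np.int64),
        "n_coding_perfect": n_coding_perfect.astype(np.int64),
        "n_coding_1bp": coding_1bp,
    }, index=pd.Index(guide_ids, name="GUIDE"))[TARGET_MAP_COLUMNS]

    # --- true fold changes and counts ----------------------------------
    true_fc = (
        cfg.essential_shift * is_ess
        + cfg.essential_shift * (multicoding & off_gene_ess)
        - cfg.fc_per_perfect * extra_perfect
        - cfg.fc_per_1bp * n_1bp
    ).astype(float)

    mu_ln = math.log(cfg.mean_reads_per_guide) - 0.5 * cfg.depth_log_sd ** 2
    control = np.maximum(
        1, np.round(rng.lognormal(mu_ln, cfg.depth_log_sd, n_guides))
    ).astype(np.int64)

    counts = pd.DataFrame({"GENE": guide_gene},
                          index=pd.Index(guide_ids, name="GUIDE"))
    counts["T0"] = control
    noise_sd = np.where(is_ess, cfg.noise_sd_essential,
                        cfg.noise_sd_nonessential)
    for r in range(cfg.n_replicates):
        eps = rng.normal(0.0, 1.0, n_guides) * noise_sd
        endpoint = np.round(control * np.power(2.0, true_fc + eps))
        counts[f"R{r + 1}"] = np.maximum(0, endpoint).astype(np.int64)

    # --- expression table ----------------------------------------------
    expr = np.empty(cfg.n_genes)
    uni = rng.uniform(0.0, 0.9, cfg.n_genes)
    hi = rng.uniform(2.0, 8.0, cfg.n_genes)
    nonexp_mask = np.isin(genes, list(nonexpressed_genes))
    expr = np.where(nonexp_mask, uni, hi)
    expression = pd.Series(expr, index=pd.Index(genes, name="GENE"),
                           name="LOG_TPM")

    # --- reference sets (disjoint samples of the truth classes) --------
    ess_sorted = sorted(essential_genes)
    nonref_pool = sorted(set(genes) - essential_genes - nonexpressed_genes)
    n_ess_ref = int(round(cfg.ref_fraction_essential * len(ess_sorted)))
    n_non_ref = int(round(cfg.ref_fraction_nonessential * len(nonref_pool)))
    essential_ref = set(rng.choice(ess_sorted, size=n_ess_ref, replace=False)) \
        if n_ess_ref else set()
    nonessential_ref = set(rng.choice(nonref_pool, size=n_non_ref,
                                      replace=False)) if n_non_ref else set()

    truth = pd.DataFrame({
        "essential": np.isin(genes, list(essential_genes)),
        "expressed": ~nonexp_mask,
    }, index=pd.Index(genes, name="GENE"))

    return SyntheticScreen(
        counts=counts, target_map=target_map, essential_ref=essential_ref,
        nonessential_ref=nonessential_ref, truth=truth, expression=expression,
        true_fc=pd.Series(true_fc, index=pd.Index(guide_ids, name="GUIDE"),
                          name="TRUE_FC"),
        config=cfg,
    )


def degrade_replicate(fold_changes: pd.DataFrame, replicate: str,
                      noise_sd: float, seed: int = 0) -> pd.DataFrame:
    """Add Gaussian fold-change noise to one replicate column only."""
    if replicate not in fold_changes.columns or replicate == "GENE":
        raise ValueError(f"unknown replicate {replicate!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out = fold_changes.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out[replicate] = out[replicate] + rng.normal(0.0, noise_sd,
                                                     len(out))
    return out


def noise_for_target_d(fold_changes: pd.DataFrame, replicate: str,
                       essential: set[str], nonessential: set[str],
                       target_d: float, seed: int = 0, tol: float = 0.02,
                       max_iter: int = 60) -> tuple[float, float]:
    """Noise SD that degrades a replicate to a target Cohen's D.

    Bisection on the noise SD, holding the noise draw (seed) fixed so the
    realised D is a continuous, decreasing function of the SD.  Returns
    ``(noise_sd, achieved_d)``.
    """
    d0 = cohens_d(fold_changes, essential, nonessential, replicate)
    if d0 <= target_d:
        return 0.0, d0

    def realised(sd: float) -> float:
        deg = degrade_replicate(fold_changes, replicate, sd, seed=seed)
        return cohens_d(deg, essential, nonessential, replicate)

    lo, hi = 0.0, 1.0
    while realised(hi) > target_d:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("could not bracket the target quality score")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d = realised(mid)
        if abs(d - target_d) < tol:
            return mid, d
        if d > target_d:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid, realised(mid)
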