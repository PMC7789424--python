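"""Kernel density models and the log-likelihood-ratio machinery.

The essentiality score of a guide is the log2 ratio of two class-conditional
fold-change densities -- one trained on guides targeting known essential
genes, one on guides targeting known non-essential genes.  Both densities
are Gaussian-kernel KDEs evaluated on a shared fold-change grid.  Because
the raw log ratio is unstable wherever either training sample is sparse,
scoring uses a straight line fitted to the log ratio inside a "stable
region" of well-supported fold changes and extrapolated outside it.

The stable region is bounded below by the fold change at which the
non-essential density first reaches a density threshold theta, and above by
the first local minimum of the log ratio to the right of that bound.  The
threshold adapts to training-set size through a log-linear decay so that
small (sub-genome-scale) libraries do not lose their entire left tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityModel",
    "RatioModel",
    "train_density",
    "make_grid",
    "log_ratio",
    "find_stable_region",
    "stable_region_from_curves",
    "calibrate_threshold",
    "derive_threshold_decay",
    "fit_ratio_line",
    "guide_bf",
    "fit_ratio_model",
]

#: Default evaluation grid bounds and step, in log2 fold-change units.
GRID_LO = -10.0
GRID_HI = 2.0
GRID_STEP = 0.01

#: Densities are floored at this value before taking logs, so the raw
#: ratio stays finite far outside the data; scoring uses the fitted line,
#: not the floored ratio.
DENSITY_FLOOR = 2.0 ** -30

#: Density-threshold anchor: theta = 2^-7 for a training set of
#: ANCHOR_N_TRAIN non-essential guides (genome-scale reference size).
ANCHOR_LOG2_THETA = -7.0
ANCHOR_N_TRAIN = 10_000

#: Log-linear decay rate of log2(theta) per unit ln(n_train) below the
#: anchor.  Derived once by `derive_threshold_decay` (seed 0, 50
#: subsamples per proportion) on the default synthetic screen's
#: non-essential reference fold changes; see docs/methods.md.
DEFAULT_THRESHOLD_DECAY = 0.31

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, 0.9 min(sd, IQR/1.349) n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance training sample: bandwidth undefined")
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


@dataclass
class DensityModel:
    """Gaussian-kernel density estimate of a fold-change training sample."""

    points: np.ndarray
    bandwidth: float
    grid: np.ndarray
    _grid_density: np.ndarray | None = field(default=None, repr=False)

    def evaluate(self, query: np.ndarray | float) -> np.ndarray | float:
        """Density at `query`: the mean of Gaussian pdfs centred on the
        training points, each with sd = bandwidth."""
        q = np.atleast_1d(np.asarray(query, dtype=float))
        h = self.bandwidth
        out = np.empty(q.size)
        # chunked so a genome-scale sample x dense grid never materialises
        # more than ~8M doubles at once
        step = max(1, int(8_000_000 / max(1, self.points.size)))
        for i in range(0, q.size, step):
            z = (q[i:i + step, None] - self.points[None, :]) / h
            out[i:i + step] = np.exp(-0.5 * z * z).sum(axis=1)
        out /= self.points.size * h * _SQRT_2PI
        if np.isscalar(query) or np.asarray(query).ndim == 0:
            return float(out[0])
        return out

    @property
    def grid_density(self) -> np.ndarray:
        if self._grid_density is None:
            self._grid_density = self.evaluate(self.grid)
        return self._grid_density


def make_grid(*samples: np.ndarray, lo: float = GRID_LO, hi: float = GRID_HI,
              step: float = GRID_STEP) -> np.ndarray:
    """Fold-change evaluation grid, extended when the data exceed it.

    Grid points are integer multiples of `step` so that two grids built
    from overlapping data share their common points exactly.
    """
    for s in samples:
        s = np.asarray(s, dtype=float)
        if s.size:
            lo = min(lo, float(np.floor(s.min() / step) * step) - step)
            hi = max(hi, float(np.ceil(s.max() / step) * step) + step)
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def train_density(fold_changes: np.ndarray, grid: np.ndarray | None = None,
                  bandwidth: float | None = None) -> DensityModel:
    """Train a Gaussian KDE on guide-level fold changes.

    Raises ``ValueError`` for fewer than two points or a zero-variance
    sample (Silverman bandwidth undefined).
    """
    x = np.asarray(fold_changes, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need >= 2 training fold changes, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite training fold changes")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if grid is None:
        grid = make_grid(x)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return DensityModel(points=x, bandwidth=float(bandwidth), grid=grid)


def log_ratio(ess: DensityModel, non: DensityModel,
              floor: float = DENSITY_FLOOR) -> np.ndarray:
    """log2(essential density / non-essential density) on the shared grid."""
    if ess.grid.shape != non.grid.shape or not np.array_equal(ess.grid, non.grid):
        raise ValueError("essential and non-essential models must share a grid")
    fe = np.maximum(ess.grid_density, floor)
    fn = np.maximum(non.grid_density, floor)
    return np.log2(fe) - np.log2(fn)


def calibrate_threshold(n_train: int, decay: float = DEFAULT_THRESHOLD_DECAY,
                        anchor_n: int = ANCHOR_N_TRAIN,
                        anchor_log2_theta: float = ANCHOR_LOG2_THETA) -> float:
    """Density threshold theta for the lower stable-region bound.

    theta = 2^anchor_log2_theta for n_train >= anchor_n; below the anchor,
    log2(theta) decays linearly in ln(n_train) at rate `decay`, so smaller
    training sets use lower thresholds and keep usable left tails.
    Monotone non-decreasing in n_train for decay >= 0.
    """
    if n_train < 2:
        raise ValueError("n_train must be >= 2")
    if n_train >= anchor_n:
        return 2.0 ** anchor_log2_theta
    log2_theta = anchor_log2_theta + decay * (math.log(n_train) - math.log(anchor_n))
    return 2.0 ** log2_theta


def derive_threshold_decay(samples: np.ndarray,
                           proportions=(0.5, 0.25, 0.1, 0.05, 0.01),
                           n_rep: int = 50, seed: int = 0,
                           anchor_log2_theta: float = ANCHOR_LOG2_THETA,
                           collapse_log2: float = -20.0):
    """Re-derive the threshold decay rate by the downsampling procedure.

    From the full non-essential training sample, locate the original left
    bound x_L0 (leftmost grid point where the full density reaches the
    anchor threshold).  For each downsampling proportion, subsample without
    replacement `n_rep` times, retrain the KDE, and record the median
    density at x_L0.  The decay rate is the OLS slope of log2(median
    density) on ln(subsample size): it measures how fast tail support
    vanishes as the library shrinks.  Proportions whose median density has
    collapsed below `collapse_log2` (the tail usually holds no points at
    all, so the density is floor-dominated and no longer log-linear in n)
    are excluded from the fit.

    Returns ``(decay, details)`` where details is a dict with the fitted
    intercept, x_L0, and the per-proportion medians.
    """
    x = np.asarray(samples, dtype=float).ravel()
    full = train_density(x)
    theta0 = 2.0 ** anchor_log2_theta
    idx = np.nonzero(full.grid_density >= theta0)[0]
    if idx.size == 0:
        raise ValueError("full-sample density never reaches the anchor threshold")
    x_l0 = float(full.grid[idx[0]])
    rng = np.random.default_rng(seed)
    sizes, med_log2 = [], []
    for p in proportions:
        m = max(2, int(round(p * x.size)))
        dens = []
        for _ in range(n_rep):
            sub = rng.choice(x, size=m, replace=False)
            try:
                d = train_density(sub).evaluate(x_l0)
            except ValueError:  # degenerate subsample
                continue
            dens.append(max(float(d), DENSITY_FLOOR))
        if dens:
            sizes.append(m)
            med_log2.append(math.log2(float(np.median(dens))))
    usable = [(m, v) for m, v in zip(sizes, med_log2) if v > collapse_log2]
    if len(usable) < 2:
        raise ValueError("not enough usable downsampling proportions")
    ln_m = np.log(np.asarray([m for m, _ in usable], dtype=float))
    vals = np.asarray([v for _, v in usable])
    slope, intercept = np.polyfit(ln_m, vals, 1)
    decay = max(0.0, float(slope))
    return decay, {
        "intercept": float(intercept),
        "x_l0": x_l0,
        "sizes": sizes,
        "median_log2_density": med_log2,
        "n_used": len(usable),
    }


def find_stable_region(non: DensityModel, ratio: np.ndarray, theta: float,
                       ess: DensityModel | None = None,
                       theta_ess: float | None = None) -> tuple[float, float]:
    """Bounds of the fold-change region where the log ratio is trustworthy.

    Lower bound: leftmost grid point where the non-essential density
    reaches `theta` (scanning left to right).  Upper bound: the minimum of
    the log ratio over the grid points (at or right of the lower bound)
    where both training densities are above threshold -- the point where
    the ratio bottoms out before data sparsity makes it turn back up or
    plunge.  If the ratio is still falling at the right edge of the
    supported range, that edge is the upper bound.

    When `ess` is omitted the supported range is judged on the
    non-essential density alone.
    """
    return stable_region_from_curves(
        non.grid, non.grid_density, np.asarray(ratio, dtype=float), theta,
        ess_density=None if ess is None else ess.grid_density,
        theta_ess=theta_ess,
    )


def stable_region_from_curves(grid: np.ndarray, non_density: np.ndarray,
                              ratio: np.ndarray, theta: float,
                              ess_density: np.ndarray | None = None,
                              theta_ess: float | None = None
                              ) -> tuple[float, float]:
    """Curve-level implementation of :func:`find_stable_region`."""
    grid = np.asarray(grid, dtype=float)
    if ratio.shape != grid.shape or non_density.shape != grid.shape:
        raise ValueError("ratio grid does not match the density grid")
    above = np.nonzero(non_density >= theta)[0]
    if above.size == 0:
        raise ValueError(
            "non-essential density never reaches the threshold; training "
            "data are degenerate or theta is too high"
        )
    i_lo = int(above[0])
    supported = non_density >= theta
    if ess_density is not None:
        supported &= ess_density >= (theta if theta_ess is None else theta_ess)
    supported[:i_lo] = False
    idx = np.nonzero(supported)[0]
    if idx.size == 0:
        idx = np.array([i_lo])
    i_sup = int(idx.max())
    if i_sup <= i_lo:
        i_sup = ratio.size - 1
    window = np.arange(i_lo, i_sup + 1)
    i_hi = int(window[np.argmin(ratio[window])])
    if i_hi <= i_lo:
        i_hi = i_sup
    return float(grid[i_lo]), float(grid[i_hi])


def fit_ratio_line(grid: np.ndarray, ratio: np.ndarray, fc_lo: float,
                   fc_hi: float) -> tuple[float, float]:
    """OLS line (slope, intercept) of the log ratio over [fc_lo, fc_hi]."""
    grid = np.asarray(grid, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    mask = (grid >= fc_lo) & (grid <= fc_hi)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 grid points inside the stable region")
    slope, intercept = np.polyfit(grid[mask], ratio[mask], 1)
    return float(slope), float(intercept)


@dataclass
class RatioModel:
    """Per-replicate fitted log-likelihood-ratio function.

    Carries the KDE grid and raw log2 ratio, the stable-region bounds, the
    density threshold used for the lower bound, and the fitted line used
    for scoring.  `max_residual` records the worst |line - raw ratio|
    inside the stable region as a linearity diagnostic.
    """

    grid: np.ndarray
    log2_ratio: np.ndarray
    fc_lower: float
    fc_upper: float
    theta: float
    slope: float
    intercept: float
    max_residual: float
    n_train_essential: int = 0
    n_train_nonessential: int = 0

    def score(self, fc, mode: str = "extrapolate"):
        """Guide-level log2 Bayes Factor at fold change `fc`.

        mode 'extrapolate': the fitted line everywhere (default).
        mode 'raw-inside': raw grid ratio (interpolated) inside the stable
        region, the line outside it.
        mode 'truncate': the line evaluated at fc clipped into the stable
        region (legacy truncated scoring; caps the dynamic range).
        """
        fc_arr = np.atleast_1d(np.asarray(fc, dtype=float))
        if mode == "extrapolate":
            out = self.slope * fc_arr + self.intercept
        elif mode == "truncate":
            out = self.slope * np.clip(fc_arr, self.fc_lower, self.fc_upper) \
                + self.intercept
        elif mode == "raw-inside":
            out = self.slope * fc_arr + self.intercept
            inside = (fc_arr >= self.fc_lower) & (fc_arr <= self.fc_upper)
            if inside.any():
                out[inside] = np.interp(fc_arr[inside], self.grid, self.log2_ratio)
        else:
            raise ValueError(f"unknown scoring mode {mode!r}")
        if np.isscalar(fc) or np.asarray(fc).ndim == 0:
            return float(out[0])
        return out


def guide_bf(fc, model: RatioModel, mode: str = "extrapolate"):
    """Functional alias for :meth:`RatioModel.score`."""
    return model.score(fc, mode=mode)


def fit_ratio_model(essential_fc: np.ndarray, nonessential_fc: np.ndarray,
                    grid: np.ndarray | None = None,
                    decay: float = DEFAULT_THRESHOLD_DECAY) -> RatioModel:
    """Train both densities and fit the full ratio model for one replicate."""
    ess_fc = np.asarray(essential_fc, dtype=float).ravel()
    non_fc = np.asarray(nonessential_fc, dtype=float).ravel()
    if grid is None:
        grid = make_grid(ess_fc, non_fc)
    ess = train_density(ess_fc, grid=grid)
    non = train_density(non_fc, grid=grid)
    ratio = log_ratio(ess, non)
    theta = calibrate_threshold(non_fc.size, decay=decay)
    theta_ess = calibrate_threshold(ess_fc.size, decay=decay)
    fc_lo, fc_hi = find_stable_region(non, ratio, theta, ess=ess,
                                      theta_ess=theta_ess)
    slope, intercept = fit_ratio_line(grid, ratio, fc_lo, fc_hi)
    mask = (grid >= fc_lo) & (grid <= fc_hi)
    resid = np.abs(slope * grid[mask] + intercept - ratio[mask])
    return RatioModel(
        grid=grid, log2_ratio=ratio, fc_lower=fc_lo, fc_upper=fc_hi,
        theta=theta, slope=slope, intercept=intercept,
        max_residual=float(resid.max()),
        n_train_essential=ess_fc.size, n_train_nonessential=non_fc.size,
    )
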