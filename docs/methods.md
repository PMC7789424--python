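# Methods

## Model

A pooled CRISPR knockout fitness screen yields, per guide g and replicate
r, a log2 fold change x_gr of endpoint versus control abundance. The
classifier treats gene essentiality as a two-model selection problem: the
fold changes of guides targeting a gene were drawn either from the
distribution characteristic of essential-gene knockouts or from that of
non-essential-gene knockouts. Both class-conditional densities are
estimated per replicate by Gaussian-kernel KDE on the fold changes of
guides targeting curated reference gene sets (core-essential and
non-essential). The guide-level log2 Bayes Factor is the log ratio of the
two densities at the observed fold change; replicate-level guide BFs are
summed to screen-level guide BFs, and a gene's BF is the sum over its
guides. Summation treats guides and replicates as independent evidence;
correlated artefacts (copy-number amplification, batch effects) must be
corrected upstream (e.g. CRISPRcleanR fold changes can be fed directly to
the `bf` stage).

### Stable region and linear extrapolation

The raw log ratio is only trustworthy where both training densities are
supported by data. The stable region is bounded below at the leftmost
grid point where the non-essential density reaches a threshold theta, and
above at the minimum of the log ratio over the grid points where both
densities exceed their thresholds. Within that window the log ratio of
two similar-width distributions is close to linear, so an OLS line is
fitted there and used for scoring everywhere ("extrapolate", the
default). This makes the score a continuous, monotone function of fold
change, rescues information in the tails, and extends the dynamic range
in both directions (positive-selection outliers get strongly negative
BFs). Two alternatives are kept for comparison: `raw-inside` (the raw
grid ratio inside the region, the line outside) and `truncate` (fold
changes clamped into the region before scoring, reproducing the
truncated behaviour of earlier classifiers).

The upper bound is implemented as the argmin of the ratio over the
jointly supported window rather than a literal "first local minimum"
scan: KDE curves carry micro-wiggles of order 1e-3 that a literal scan
mistakes for minima a few grid steps after the lower bound, collapsing
the fit window, while beyond the essential density's support the floored
ratio plunges and would corrupt the fit. On idealised monotone-then-
rising ratio curves the two definitions coincide. When the ratio is
still falling at the right edge of the supported window, that edge is
the bound.

### Threshold calibration

theta is anchored at 2^-7 for a genome-scale training set (anchored at
n = 10^4 training guides) and decays log-linearly in ln(n) below the
anchor: log2 theta(n) = -7 + 0.31·(ln n − ln 10^4), constant above. The
decay rate was fixed once by the documented downsampling procedure on the
default synthetic screen's non-essential reference fold changes (seed 0):
locate the full-sample left bound x_L0 at theta = 2^-7, subsample the
training guides at 50/25/10/5/1% (50 draws per proportion), record the
median KDE density at x_L0, and fit log2(density) against ln(subsample
size), excluding proportions whose tail has emptied entirely (median
below 2^-20; the density there is floor-dominated and no longer
log-linear in n). The median across draws is used rather than the
maximum: at small subsample sizes the maximum is dominated by single
lucky points whose kernel contribution scales as 1/(n·h), which inverts
the monotonicity the calibration is meant to capture. The derived rate
varies by roughly ±0.15 across procedure seeds; `derive_threshold_decay`
lets users re-derive it for their own library.

### Resampling

Cross-validation (default): reference genes are shuffled (seeded) and
dealt into 10 class-stratified folds. For each fold and replicate, the
densities are trained on the other nine folds' reference guides; the
held-out reference genes are scored only by their own fold's model
(avoiding self-training circularity), while non-reference genes are
scored by every fold's model and averaged (`fold_aggregate="mean"`;
`"sum"` would scale BFs by the fold count and is available for
comparison). Bootstrap: each iteration resamples each reference class
with replacement (guides of a drawn gene entering the training set once
per draw), scores all guides, and guide BFs are averaged over iterations
(default 1000). Both modes are bitwise deterministic given the seed. A
replicate whose reference fold changes have zero variance is skipped
with a warning.

### KDE details

Gaussian kernel with Silverman's bandwidth 0.9·min(sd, IQR/1.349)·n^-1/5,
evaluated on a fold-change grid from −10 to +2 log2 units at step 0.01,
extended outward when data exceed it (grid points are multiples of the
step so overlapping grids align exactly). The kernel sum is evaluated
directly (mean of Gaussian pdfs centred on the training points), which
keeps fixed-bandwidth semantics exact for testing. Densities are floored
at 2^-30 before logs so the raw ratio stays finite off-support; scoring
uses the fitted line, not the floored ratio. Fewer than two training
points, or zero variance, is an error.

## Multi-target correction

The fitness cost of a guide decomposes additively into on-target knockout
plus a locus-independent DNA-cleavage cost per cut site. For guides whose
only protein-coding target is their own gene (perfect or 1-bp-mismatch),
the excess BF over the mean of the gene's clean guides (no off-target
loci at all) follows

    increment = (n_perfect − 1)·tp_perfect + n_1bp·tp_1bp

with no constant term, so the per-locus increments are estimated by
zero-intercept least squares of observed increments on the two locus
counts (an `--intercept` diagnostic reports a fitted constant without
using it). The model needs at least three observations spanning two
distinct, non-collinear predictor combinations; negative coefficients are
clamped to zero with a warning, since a cleavage cost cannot be negative.
Increments are computed from screen-level (replicate-summed) guide BFs;
the penalty is applied to the final screen-level guide BFs of every
retained guide — including those with coding 1-bp off-targets, which are
excluded from estimation but still suffer the cleavage cost — and gene
BFs are re-summed. Guides perfectly hitting more than one protein-coding
gene, and promiscuous guides (> 10 perfect-match or > 10 1-bp-mismatch
loci), are removed from the library before any training, because their
dropout confounds the target gene with off-target gene knockouts.

## Benchmarking and quality

Genes are ranked by BF descending (ties broken by name for
reproducibility) and swept top-down; only reference genes count toward
TP/FP/FN, and a prefix containing no reference gene has precision defined
as 1.0. FDR = 1 − precision row-wise. The screen summary statistic is F1
at the row whose BF is nearest above 5. Replicate quality is Cohen's D
between non-essential and essential reference guide fold changes with the
two-group pooled SD, sqrt(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2)); positive D
means essentials drop out faster. An expression audit counts hit genes
with log TPM below 1.0 — genes with no mRNA cannot be essential, so such
hits are likely false positives.

## Synthetic screens

The generator emulates the data a dropout screen produces under the
classifier's own assumptions. Defaults (the conditions used throughout
the tests): 1000 genes × 4 guides, 2 replicates, 20% essential genes
depleting by −3 log2 units, per-replicate per-class fold-change noise SD
1.0 (replicate Cohen's D ≈ 2.4 after off-target smear — a good screen),
T0 depth log-normal with mean 500 reads/guide and ln-scale SD 0.5
(counts are log-normal rather than Poisson so depth spread and
fold-change noise stay independently tunable), 15% of guides carrying
off-target loci with capped-geometric locus counts (an Avana-like
multi-targeting share), 2% multi-coding and 1% promiscuous guides, 10%
of non-essential genes non-expressed (log TPM < 1), and reference sets
sampled as 80% of each truth class (non-expressed genes excluded from
the non-essential reference, as reference non-essentials are
expressed-but-dispensable by construction).

Off-target severity is configured on the BF scale — per-locus increments
default to 3.5 (extra perfect match) and 1.4 (1-bp mismatch) — and
converted to fold-change depletions through a self-consistent fixed
point: both class densities are known Gaussian mixtures once the
depletions are fixed, so the expected fitted line slope can be computed
analytically (same stable-region rule and OLS the classifier uses), and
the depletion is the smallest value whose realised screen-level BF
response reproduces the targets. A naive single-Gaussian conversion
under-recovers by ~20% because the injected depletions themselves widen
the training densities and flatten the slope. For small screens (or very
large targets) no self-consistent solution exists — the required
depletion inflates variance faster than the BF response grows — and the
generator raises rather than silently injecting a different effect size;
test fixtures at 80–150 genes therefore use milder increments.

`degrade_replicate` adds seeded Gaussian noise to one replicate's fold
changes, and `noise_for_target_d` bisects the noise SD (noise draw held
fixed) to hit a target Cohen's D, e.g. turning a D > 2 replicate into a
D ≈ 1.1 outlier.

What the generator does not emulate: copy-number amplification artefacts,
guide-efficiency variation (no right-hand null component in the
essential class), batch structure, PCR jackpotting, or sequence-level
effects. Tests passing on these screens therefore demonstrate the
correctness and calibration of the algorithms under their stated
assumptions, not robustness to every real-data pathology.

## Numerical choices and limitations

* Fold changes: pseudocount 5 added to raw counts before scaling each
  sample to 10^7 reads; multiple control columns are normalised then
  averaged. Pseudocount 0 with zero counts is an error rather than an
  infinite fold change.
* Problem sizes: the default test/benchmark screen is 1000 genes — large
  enough that reference folds are stable and off-target estimation has
  ~600 observations, small enough that the full pipeline (including a
  200-iteration bootstrap) runs in about a minute.
* The bootstrap keeps only the first few fitted ratio models per
  replicate for audit; all scores are accumulated exactly.
* Genes present in both reference lists are an error at model
  construction, not silently resolved.
* The penalty stage is fixed at "after resampling, before gene
  summation"; estimating the correction inside each resampling iteration
  is a possible refinement but would couple the off-target model to fold
  membership.
* Gene symbols are taken verbatim; harmonising them to current official
  symbols is the caller's responsibility.
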