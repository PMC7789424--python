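"""The Bayes Factor gene-essentiality classifier.

:class:`BayesFactorModel` holds a guide-level fold-change table and the
two reference gene sets; :meth:`~BayesFactorModel.fit` trains per-replicate
fold-change density models under either 10-fold cross-validation (default)
or bootstrap resampling of the reference genes, scores every guide with
the fitted log-likelihood-ratio line, and aggregates

    replicate-level guide BF  --sum over replicates-->  screen-level guide BF
    screen-level guide BF     --sum over guides----->   gene-level BF

into a :class:`BayesFactorResults` object.  Positive BF: the guide/gene
fold-change data support the essential model; BF >= 5 is the conventional
hit threshold.  When a guide->off-target map is supplied, the multi-target
correction of :mod:`crisprbf.multitarget` is estimated from the
screen-level guide BFs and applied before gene-level summation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import multitarget as mt
from .density import DEFAULT_THRESHOLD_DECAY, RatioModel, fit_ratio_model, make_grid
from .evaluation import f_measure, precision_recall

log = logging.getLogger(__name__)

__all__ = ["BayesFactorModel", "BayesFactorResults", "run_classifier"]

HIT_THRESHOLD = 5.0


def _check_references(genes: pd.Series, essential: set, nonessential: set):
    overlap = set(essential) & set(nonessential)
    if overlap:
        raise ValueError(
            f"genes in both reference sets: {sorted(overlap)[:5]}"
        )
    present = set(genes.unique())
    ess = sorted(present & set(essential))
    non = sorted(present & set(nonessential))
    if len(ess) < 2 or len(non) < 2:
        raise ValueError(
            f"need >= 2 reference genes of each class in the screen; found "
            f"{len(ess)} essential, {len(non)} non-essential"
        )
    return ess, non


def _fold_assignment(genes: list[str], n_folds: int, rng: np.random.Generator
                     ) -> dict[str, int]:
    order = list(rng.permutation(sorted(genes)))
    return {g: i % n_folds for i, g in enumerate(order)}


class BayesFactorModel:
    """Gene-essentiality model for one screen.

    Parameters
    ----------
    fold_changes
        DataFrame indexed by guide id with a 'GENE' column and one log2
        fold-change column per replicate.
    essential, nonessential
        Reference gene sets (e.g. CEGv2 / NEG roles).  Must be disjoint;
        at least two genes of each class must be present in the screen.
    scoring
        'extrapolate' (fitted line everywhere, default), 'raw-inside'
        (raw KDE log ratio inside the stable region) or 'truncate'
        (fold changes clipped into the stable region before scoring).
    fold_aggregate
        How a non-reference guide's per-fold BFs are combined within one
        replicate: 'mean' (default) or 'sum'.
    threshold_decay
        Decay rate of the stable-region density threshold with training
        size; see :func:`crisprbf.density.calibrate_threshold`.
    """

    def __init__(self, fold_changes: pd.DataFrame, essential: set[str],
                 nonessential: set[str], scoring: str = "extrapolate",
                 fold_aggregate: str = "mean",
                 threshold_decay: float = DEFAULT_THRESHOLD_DECAY):
        if "GENE" not in fold_changes.columns:
            raise ValueError("fold-change table must carry a 'GENE' column")
        if fold_aggregate not in {"mean", "sum"}:
            raise ValueError("fold_aggregate must be 'mean' or 'sum'")
        self.fold_changes = fold_changes
        self.replicates = [c for c in fold_changes.columns if c != "GENE"]
        if not self.replicates:
            raise ValueError("fold-change table has no replicate columns")
        self.genes = fold_changes["GENE"]
        self.essential = set(essential)
        self.nonessential = set(nonessential)
        self.scoring = scoring
        self.fold_aggregate = fold_aggregate
        self.threshold_decay = threshold_decay
        self._ess_present, self._non_present = _check_references(
            self.genes, self.essential, self.nonessential)

    @classmethod
    def from_read_counts(cls, counts: pd.DataFrame, control_samples,
                         essential, nonessential, pseudocount: float = 5.0,
                         **kwargs) -> "BayesFactorModel":
        """Build the model straight from a read-count table."""
        from .foldchange import compute_fold_change
        fc = compute_fold_change(counts, control_samples, pseudocount=pseudocount)
        return cls(fc, essential, nonessential, **kwargs)

    # -- resampling -----------------------------------------------------

    def _replicate_usable(self, rep: str) -> bool:
        ref_genes = set(self._ess_present) | set(self._non_present)
        fcs = self.fold_changes.loc[self.genes.isin(ref_genes), rep]
        if float(np.std(fcs)) == 0.0:
            log.warning("replicate %s has zero variance in reference fold "
                        "changes; skipped", rep)
            return False
        return True

    def _guides_of(self, gene_list) -> pd.Index:
        return self.fold_changes.index[self.genes.isin(set(gene_list))]

    def fit(self, method: str = "cv", n_folds: int = 10,
            n_iterations: int = 1000, seed: int = 0,
            target_map: pd.DataFrame | None = None) -> "BayesFactorResults":
        """Fit the classifier and score every gene.

        method 'cv': reference genes are split into `n_folds` folds,
        stratified by class; each fold's reference genes are scored by a
        model trained on the other folds, while non-reference genes are
        scored in every fold and averaged.  method 'bootstrap': each of
        `n_iterations` rounds trains on a with-replacement resample of
        the reference genes (per class) and scores all genes; guide BFs
        are averaged over rounds.  Deterministic given `seed`.
        """
        if method not in {"cv", "bootstrap"}:
            raise ValueError("method must be 'cv' or 'bootstrap'")
        fc = self.fold_changes
        if target_map is not None:
            fc, drop_report = mt.filter_guides(fc, target_map)
            _check_references(fc["GENE"], self.essential, self.nonessential)
        else:
            drop_report = None
        genes = fc["GENE"]
        reps = [r for r in self.replicates if self._replicate_usable(r)]
        if not reps:
            raise ValueError("no usable replicates (all zero-variance)")

        if method == "cv":
            if n_folds < 2:
                raise ValueError("n_folds must be >= 2")
            if n_folds > min(len(self._ess_present), len(self._non_present)):
                raise ValueError(
                    f"n_folds={n_folds} exceeds the smaller reference-set "
                    f"size ({min(len(self._ess_present), len(self._non_present))})"
                )
            rep_bf, models = self._fit_cv(fc, genes, reps, n_folds, seed)
        else:
            if n_iterations < 1:
                raise ValueError("n_iterations must be >= 1")
            rep_bf, models = self._fit_bootstrap(fc, genes, reps, n_iterations,
                                                 seed)

        guide_bf = rep_bf.sum(axis=1)
        guide_bf.name = "BF"
        offtarget_model = None
        increments = None
        uncorrected_guide_bf = guide_bf
        if target_map is not None:
            increments = mt.compute_increments(guide_bf, genes, target_map)
            try:
                offtarget_model = mt.fit_offtarget_model(increments)
            except ValueError as exc:
                log.warning("off-target model not fitted (%s); penalty skipped",
                            exc)
            if offtarget_model is not None:
                guide_bf, _ = mt.apply_penalty(guide_bf, genes, target_map,
                                               offtarget_model)
        gene_bf = guide_bf.groupby(genes).sum()
        gene_bf.index.name = "GENE"
        gene_bf.name = "BF"
        return BayesFactorResults(
            model=self, method=method, seed=seed,
            replicate_bf=rep_bf, guide_bf=guide_bf, gene_bf=gene_bf,
            gene_labels=genes, ratio_models=models,
            target_map=target_map, drop_report=drop_report,
            increments=increments, offtarget_model=offtarget_model,
            uncorrected_guide_bf=uncorrected_guide_bf,
        )

    def _fit_one(self, fc: pd.DataFrame, rep: str, train_ess_guides: pd.Index,
                 train_non_guides: pd.Index, grid: np.ndarray) -> RatioModel:
        return fit_ratio_model(
            fc.loc[train_ess_guides, rep].to_numpy(),
            fc.loc[train_non_guides, rep].to_numpy(),
            grid=grid, decay=self.threshold_decay,
        )

    def _fit_cv(self, fc, genes, reps, n_folds, seed):
        rng = np.random.default_rng(seed)
        folds_ess = _fold_assignment(self._ess_present, n_folds, rng)
        folds_non = _fold_assignment(self._non_present, n_folds, rng)
        fold_of = {**folds_ess, **folds_non}
        ref_genes = set(fold_of)
        is_ref = genes.isin(ref_genes)
        nonref_guides = fc.index[~is_ref]
        grid = make_grid(*[fc[r].to_numpy() for r in reps])

        sums = pd.DataFrame(0.0, index=fc.index, columns=reps)
        counts = pd.DataFrame(0, index=fc.index, columns=reps)
        models: dict[str, list[RatioModel]] = {r: [] for r in reps}
        gene_fold = genes.map(fold_of)
        for rep in reps:
            fc_rep = fc[rep]
            for k in range(n_folds):
                heldout = is_ref & (gene_fold == k)
                train_ess = fc.index[genes.isin(
                    {g for g, f in folds_ess.items() if f != k})]
                train_non = fc.index[genes.isin(
                    {g for g, f in folds_non.items() if f != k})]
                rm = self._fit_one(fc, rep, train_ess, train_non, grid)
                models[rep].append(rm)
                test = fc.index[heldout].append(nonref_guides)
                sums.loc[test, rep] += rm.score(fc_rep.loc[test].to_numpy(),
                                                mode=self.scoring)
                counts.loc[test, rep] += 1
        return self._aggregate_folds(sums, counts), models

    def _fit_bootstrap(self, fc, genes, reps, n_iterations, seed):
        rng = np.random.default_rng(seed)
        grid = make_grid(*[fc[r].to_numpy() for r in reps])
        sums = pd.DataFrame(0.0, index=fc.index, columns=reps)
        counts = pd.DataFrame(0, index=fc.index, columns=reps)
        models: dict[str, list[RatioModel]] = {r: [] for r in reps}
        ess_sorted = sorted(self._ess_present)
        non_sorted = sorted(self._non_present)
        ess_guide_lists = {g: self._guides_of([g]).intersection(fc.index)
                           for g in ess_sorted}
        non_guide_lists = {g: self._guides_of([g]).intersection(fc.index)
                           for g in non_sorted}
        for _ in range(n_iterations):
            ess_sample = rng.choice(ess_sorted, size=len(ess_sorted), replace=True)
            non_sample = rng.choice(non_sorted, size=len(non_sorted), replace=True)
            ess_idx = np.concatenate(
                [ess_guide_lists[g].to_numpy() for g in ess_sample])
            non_idx = np.concatenate(
                [non_guide_lists[g].to_numpy() for g in non_sample])
            for rep in reps:
                rm = self._fit_one(fc, rep, pd.Index(ess_idx), pd.Index(non_idx),
                                   grid)
                if len(models[rep]) < 5:  # keep a few for audit
                    models[rep].append(rm)
                sums[rep] += rm.score(fc[rep].to_numpy(), mode=self.scoring)
                counts[rep] += 1
        return self._aggregate_folds(sums, counts), models

    def _aggregate_folds(self, sums: pd.DataFrame, counts: pd.DataFrame
                         ) -> pd.DataFrame:
        if self.fold_aggregate == "sum":
            return sums
        with np.errstate(invalid="ignore"):
            out = sums / counts.where(counts > 0)
        if out.isna().any().any():
            log.warning("%d guide(s) never scored; BF set to 0",
                        int(out.isna().any(axis=1).sum()))
            out = out.fillna(0.0)
        return out


@dataclass
class BayesFactorResults:
    """Fitted guide- and gene-level Bayes Factors plus audit trail.

    Attributes
    ----------
    replicate_bf : DataFrame
        Replicate-level guide BFs (guides x replicates).
    guide_bf : Series
        Screen-level guide BFs (sum over replicates; multi-target
        corrected when a target map was supplied).
    gene_bf : Series
        Gene-level BFs (sum of the gene's guide BFs).
    ratio_models : dict
        Per-replicate fitted :class:`~crisprbf.density.RatioModel` objects
        (all folds for cv; the first few iterations for bootstrap).
    offtarget_model : OffTargetModel or None
        Fitted per-locus BF increments when a target map was supplied.
    uncorrected_guide_bf : Series
        Screen-level guide BFs before the multi-target penalty.
    """

    model: BayesFactorModel
    method: str
    seed: int
    replicate_bf: pd.DataFrame
    guide_bf: pd.Series
    gene_bf: pd.Series
    gene_labels: pd.Series
    ratio_models: dict
    target_map: pd.DataFrame | None = None
    drop_report: pd.DataFrame | None = None
    increments: pd.DataFrame | None = None
    offtarget_model: mt.OffTargetModel | None = None
    uncorrected_guide_bf: pd.Series | None = None
    _pr_cache: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def uncorrected_gene_bf(self) -> pd.Series:
        s = self.uncorrected_guide_bf.groupby(self.gene_labels).sum()
        s.index.name, s.name = "GENE", "BF"
        return s

    def hit_genes(self, threshold: float = HIT_THRESHOLD) -> set[str]:
        return set(self.gene_bf.index[self.gene_bf >= threshold])

    def precision_recall(self) -> pd.DataFrame:
        if self._pr_cache is None:
            self._pr_cache = precision_recall(
                self.gene_bf, self.model.essential, self.model.nonessential)
        return self._pr_cache

    def f_measure(self, bf_threshold: float = HIT_THRESHOLD) -> float:
        return f_measure(self.precision_recall(), bf_threshold)

    def guide_table(self) -> pd.DataFrame:
        """Guide-level output: GENE, per-replicate BFs, screen BF."""
        out = pd.DataFrame({"GENE": self.gene_labels.loc[self.guide_bf.index]})
        for rep in self.replicate_bf.columns:
            out[f"BF_{rep}"] = self.replicate_bf[rep]
        out["BF"] = self.guide_bf
        return out

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary in the statsmodels tradition."""
        m = self.model
        n_hits = len(self.hit_genes())
        lines = [
            "Bayes Factor essentiality classifier",
            "=" * 52,
            f"Guides: {len(self.guide_bf):>7d}    Genes: {len(self.gene_bf):>6d}"
            f"    Replicates: {len(self.replicate_bf.columns)}",
            f"Reference essential/non-essential present: "
            f"{len(m._ess_present)}/{len(m._non_present)}",
            f"Resampling: {self.method} (seed {self.seed})    "
            f"Scoring: {m.scoring}",
            f"Hits (BF >= {HIT_THRESHOLD:g}): {n_hits}    "
            f"F1(BF={HIT_THRESHOLD:g}): {self.f_measure():.3f}",
            f"Gene BF range: [{self.gene_bf.min():.1f}, {self.gene_bf.max():.1f}]",
        ]
        if self.offtarget_model is not None:
            lines += ["-" * 52] + self.offtarget_model.summary().splitlines()
        lines.append("-" * 52)
        lines.append(f"Top {top} genes by BF:")
        for gene, bf in self.gene_bf.sort_values(ascending=False).head(top).items():
            lines.append(f"  {gene:<16s} {bf:10.2f}")
        return "\n".join(lines)


def run_classifier(fold_changes: pd.DataFrame, essential: set[str],
                   nonessential: set[str], method: str = "cv",
                   n_folds: int = 10, n_iterations: int = 1000,
                   seed: int = 0, target_map: pd.DataFrame | None = None,
                   **model_kwargs) -> BayesFactorResults:
    """One-call functional interface over the model/results objects."""
    model = BayesFactorModel(fold_changes, essential, nonessential,
                             **model_kwargs)
    return model.fit(method=method, n_folds=n_folds, n_iterations=n_iterations,
                     seed=seed, target_map=target_map)
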