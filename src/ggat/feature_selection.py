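"""Hybrid gene-feature selection: differential-expression filter, then RFE.

The pipeline has two stages.  The *primary* stage computes a per-gene
difference table (log2 fold change, log2 CPM, Welch p-value, BH-adjusted FDR)
between the two sample groups and keeps genes with fold change >= ``fc_threshold``
(two-sided on the log scale) and p-value below ``p_threshold``.  The *exact*
stage ranks the surviving genes by recursive feature elimination with an
L2-regularized linear classifier and picks the number of genes to keep by
stratified cross-validation with a one-standard-error parsimony rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSampleError, InsufficientReplicatesError, ValidationError
from .expression_io import LabeledExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DifferenceList",
    "SelectionResult",
    "compute_cpm",
    "compute_difference_list",
    "primary_select",
    "rfe_rank",
    "select_optimal_n",
    "hybrid_select",
]

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class DifferenceList:
    """Per-gene differential statistics between two sample groups."""

    gene_ids: list[str]
    logFC: np.ndarray      # log2 fold change, group 1 over group 0
    logCPM: np.ndarray     # log2 of overall mean CPM
    p_value: np.ndarray    # Welch two-sample t-test on log2(CPM + pseudocount)
    fdr: np.ndarray        # Benjamini-Hochberg adjusted p-values

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("logFC", "logCPM", "p_value", "fdr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValidationError(f"{name} length {arr.shape} != {n} genes")
        for name in ("p_value", "fdr"):
            arr = getattr(self, name)
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError(f"{name} outside [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "logFC": self.logFC,
                "logCPM": self.logCPM,
                "PValue": self.p_value,
                "FDR": self.fdr,
            }
        )


@dataclass
class SelectionResult:
    """Outcome of the exact selection stage."""

    kept_gene_ids: list[str]
    ranking: list[str]           # all candidate genes, best first
    optimal_n: int
    cv_scores: np.ndarray        # mean CV accuracy for N = 1..len(ranking)
    difference_list: DifferenceList | None = None
    primary_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.optimal_n < 1:
            raise ValidationError("optimal_n must be >= 1")
        if self.kept_gene_ids != self.ranking[: self.optimal_n]:
            raise ValidationError("kept_gene_ids must be the top optimal_n of ranking")


def compute_cpm(
    X: LabeledExpressionMatrix | np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """Counts-per-million: rescale each sample's counts to sum to 1e6.

    ``pseudocount`` is added after scaling so that subsequent log transforms
    are finite for zero counts.
    """
    values = X.values if isinstance(X, LabeledExpressionMatrix) else np.asarray(X, float)
    if (values < 0).any():
        raise ValidationError("CPM requires non-negative counts")
    totals = values.sum(axis=1)
    if (totals == 0).any():
        bad = int(np.flatnonzero(totals == 0)[0])
        raise DegenerateSampleError(f"sample {bad} has all-zero counts")
    return values / totals[:, None] * 1e6 + pseudocount


def compute_difference_list(
    X: LabeledExpressionMatrix,
    group_labels: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DifferenceList:
    """Differential table between group 1 and group 0 on the CPM scale.

    logFC is the difference of log2 group-mean CPM (pseudocount-stabilized);
    p-values come from Welch's unequal-variance t-test on log2(CPM+pc); FDR is
    Benjamini-Hochberg over all genes.
    """
    y = np.asarray(X.labels if group_labels is None else group_labels, dtype=int)
    groups = np.unique(y)
    if groups.size != 2:
        raise ValidationError(f"expected exactly two groups, got {groups.size}")
    g0, g1 = (y == groups[0]), (y == groups[1])
    if g0.sum() < 2 or g1.sum() < 2:
        raise InsufficientReplicatesError(
            f"need >=2 samples per group, got {int(g0.sum())} and {int(g1.sum())}"
        )

    cpm = compute_cpm(X, pseudocount=0.0)
    log_cpm = np.log2(cpm + pseudocount)
    logFC = np.log2(cpm[g1].mean(axis=0) + pseudocount) - np.log2(
        cpm[g0].mean(axis=0) + pseudocount
    )
    logCPM = np.log2(cpm.mean(axis=0) + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes yield nan p-values
        _, p = stats.ttest_ind(log_cpm[g1], log_cpm[g0], equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # no variance => no evidence
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return DifferenceList(list(X.gene_ids), logFC, logCPM, p, fdr)


def primary_select(
    dml: DifferenceList,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> list[str]:
    """Keep genes with fold change >= ``fc_threshold`` (either direction) and
    ``p_value < p_threshold``; order follows the input gene order."""
    if fc_threshold < 1:
        raise ValidationError("fc_threshold must be >= 1")
    keep = (np.abs(dml.logFC) >= np.log2(fc_threshold)) & (dml.p_value < p_threshold)
    kept = [g for g, k in zip(dml.gene_ids, keep) if k]
    if not kept:
        warnings.warn("primary selection kept no genes", stacklevel=2)
    logger.info("primary_select: kept %d of %d genes", len(kept), len(dml.gene_ids))
    return kept


def _base_estimator(seed: int) -> LogisticRegression:
    # L2-penalized linear model (sklearn default); |coef| is the RFE importance.
    return LogisticRegression(C=1.0, max_iter=2000, random_state=seed)


def rfe_rank(
    X: LabeledExpressionMatrix,
    step: int = 1,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> list[str]:
    """Full recursive-feature-elimination ranking, best gene first.

    At each round an L2 linear classifier is fitted on the surviving genes and
    the ``step`` genes with smallest mean absolute coefficient are removed;
    rank 1 is the last survivor.  Ties (e.g. identical columns) break by
    column index so the ranking is a strict permutation.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    cols = list(range(X.n_genes)) if gene_ids is None else [
        X.gene_ids.index(g) for g in gene_ids
    ]
    if len(cols) < 2:
        raise ValidationError("RFE needs at least two genes")
    values, y = X.values[:, cols], X.labels

    surviving = list(range(len(cols)))
    eliminated: list[int] = []  # in elimination order, worst first
    est = _base_estimator(seed)
    while len(surviving) > 1:
        k = min(step, len(surviving) - 1)
        if k < step:
            warnings.warn("RFE step clamped near the end of elimination", stacklevel=2)
        est.fit(values[:, surviving], y)
        importance = np.abs(est.coef_).mean(axis=0)
        # ties eliminate the higher index first, so equal-importance genes
        # end up ranked in index order
        tie_break = -np.arange(len(surviving))
        worst = np.lexsort((tie_break, importance))[:k]
        for j in sorted(worst, reverse=True):
            eliminated.append(surviving.pop(j))
    order = surviving + eliminated[::-1]  # best first
    return [X.gene_ids[cols[j]] for j in order]


def select_optimal_n(
    ranking: list[str],
    X: LabeledExpressionMatrix,
    labels: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Choose how many top-ranked genes to keep by stratified k-fold CV.

    The mean CV accuracy of the RFE base model on the top-N genes is computed
    for every N; ``optimal_n`` is the smallest N whose mean score is within
    one standard error of the best mean score (parsimony rule).
    """
    y = np.asarray(X.labels if labels is None else labels, dtype=int)
    missing = [g for g in ranking if g not in X.gene_ids]
    if missing:
        raise ValidationError(f"ranking names genes absent from the matrix: {missing[:3]}")
    min_class = int(np.unique(y, return_counts=True)[1].min())
    folds = min(cv_folds, min_class)
    if folds < cv_folds:
        warnings.warn(
            f"cv_folds reduced from {cv_folds} to {folds} (smallest class size)",
            stacklevel=2,
        )
    col = {g: i for i, g in enumerate(X.gene_ids)}
    idx = [col[g] for g in ranking]

    means = np.empty(len(ranking))
    sems = np.empty(len(ranking))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for n in range(1, len(ranking) + 1):
        scores = cross_val_score(
            _base_estimator(seed), X.values[:, idx[:n]], y, cv=cv, scoring="accuracy"
        )
        means[n - 1] = scores.mean()
        sems[n - 1] = scores.std(ddof=1) / np.sqrt(folds)

    best = int(np.argmax(means))
    cutoff = means[best] - sems[best]
    optimal_n = int(np.flatnonzero(means >= cutoff)[0]) + 1
    logger.info(
        "select_optimal_n: best mean %.3f at N=%d, one-SE choice N=%d",
        means[best], best + 1, optimal_n,
    )
    return SelectionResult(
        kept_gene_ids=ranking[:optimal_n],
        ranking=list(ranking),
        optimal_n=optimal_n,
        cv_scores=means,
    )


def hybrid_select(
    X: LabeledExpressionMatrix,
    labels: np.ndarray | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    step: int = 1,
    cv_folds: int = 10,
    seed: int = 0,
    max_rfe_genes: int | None = None,
) -> SelectionResult:
    """Run the full two-stage selection: difference filter, then RFE + CV.

    Multi-class inputs run the primary filter one-vs-rest and take the union.
    If the primary filter keeps fewer than two genes, the exact stage falls
    back to ranking the whole gene set (with a warning).  ``max_rfe_genes``
    optionally caps the number of genes entering RFE (top by p-value) to bound
    the quadratic cost of the elimination loop.
    """
    y = np.asarray(X.labels if labels is None else labels, dtype=int)
    classes = np.unique(y)
    if classes.size == 2:
        dml = compute_difference_list(X, y, pseudocount)
        primary = primary_select(dml, fc_threshold, p_threshold)
    else:
        per_class = []
        for c in classes:
            d = compute_difference_list(X, (y == c).astype(int), pseudocount)
            per_class.append(set(primary_select(d, fc_threshold, p_threshold)))
        union = set().union(*per_class)
        dml = compute_difference_list(
            X, (y == classes[0]).astype(int), pseudocount
        )  # reported table uses class0-vs-rest
        primary = [g for g in X.gene_ids if g in union]

    if len(primary) < 2:
        warnings.warn(
            "primary stage kept <2 genes; falling back to the unfiltered gene set",
            stacklevel=2,
        )
        primary = list(X.gene_ids)
    if max_rfe_genes is not None and len(primary) > max_rfe_genes:
        p_of = dict(zip(dml.gene_ids, dml.p_value))
        primary = sorted(primary, key=lambda g: p_of.get(g, 1.0))[:max_rfe_genes]
        primary = [g for g in X.gene_ids if g in set(primary)]

    ranking = rfe_rank(X, step=step, seed=seed, gene_ids=primary)
    result = select_optimal_n(ranking, X, y, cv_folds=cv_folds, seed=seed)
    result.difference_list = dml
    result.primary_gene_ids = primary
    return result
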