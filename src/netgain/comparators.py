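"""Comparison feature selectors: Relief-F, Random Forest, Lasso.

These provide the per-gene importance panel the network methods are judged
against. Relief-F is implemented here in its deterministic all-anchors
variant for continuous attributes; Random Forest and Lasso delegate to
scikit-learn. All three expose the same (dataset -> per-gene scores)
surface, so their scores flow into the significance module unchanged
(Lasso's exact zeros are usually read directly as not-selected instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .dataset import ExpressionDataset

__all__ = [
    "ImportanceScores",
    "relieff_scores",
    "random_forest_importance",
    "lasso_select",
]


@dataclass
class ImportanceScores:
    """One real-valued importance score per gene."""

    scores: np.ndarray
    gene_ids: list[str]
    method: str
    params: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.gene_ids, name=self.method)

    @property
    def selected_genes(self) -> set[str]:
        """Genes with nonzero score; meaningful for lasso (exact zeros)."""
        return {g for g, s in zip(self.gene_ids, self.scores) if s != 0}


def relieff_scores(data: ExpressionDataset, k_neighbors: int = 10) -> ImportanceScores:
    """Relief-F for continuous attributes, deterministic all-anchors form.

    Every sample serves as an anchor. Its k nearest hits (same class) and
    k nearest misses (other class) are found by Euclidean distance over
    z-scored genes. Each gene's score accumulates the mean attribute
    difference to misses minus the mean difference to hits, with the
    attribute difference normalized by the gene's value range; the total is
    divided by the anchor count. Genes whose expression separates the
    classes score high; constant genes score exactly zero.
    """
    data.require_binary()
    y = np.asarray(data.phenotype, dtype=int)
    counts = np.bincount(y, minlength=2)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if counts.min() < k_neighbors + 1:
        raise ValueError(
            f"k_neighbors={k_neighbors} too large for class sizes {counts.tolist()} "
            "(each class needs at least k+1 samples)"
        )
    x = data.matrix.T  # samples x genes
    rng_range = np.ptp(x, axis=0)
    rng_range[rng_range == 0] = 1.0
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    # full pairwise distances; M is small in this setting
    d2 = np.sum((xs[:, None, :] - xs[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    m, n = x.shape
    scores = np.zeros(n)
    for a in range(m):
        same = np.flatnonzero(y == y[a])
        same = same[same != a]
        other = np.flatnonzero(y != y[a])
        hits = same[np.argsort(d2[a, same], kind="stable")[:k_neighbors]]
        misses = other[np.argsort(d2[a, other], kind="stable")[:k_neighbors]]
        diff_hit = np.abs(x[a] - x[hits]) / rng_range
        diff_miss = np.abs(x[a] - x[misses]) / rng_range
        scores += diff_miss.mean(axis=0) - diff_hit.mean(axis=0)
    scores /= m
    return ImportanceScores(
        scores=scores,
        gene_ids=list(data.gene_ids),
        method="relieff",
        params={"k_neighbors": k_neighbors},
    )


def random_forest_importance(
    data: ExpressionDataset,
    n_trees: int = 5000,
    seed: int | None = None,
    importance: str = "permutation",
    n_repeats: int = 5,
) -> ImportanceScores:
    """Random Forest variable importance for a binary phenotype.

    ``importance='permutation'`` (default) scores each gene by the accuracy
    drop when its values are permuted, averaged over ``n_repeats`` shuffles;
    ``'impurity'`` uses the forest's mean decrease in impurity, which is
    much cheaper and rank-compatible in practice. Fully seeded.
    """
    data.require_binary()
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if importance not in ("permutation", "impurity"):
        raise ValueError(f"unknown importance kind {importance!r}")
    y = np.asarray(data.phenotype, dtype=int)
    x = data.matrix.T
    rs = None if seed is None else seed % (2**32)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=rs, n_jobs=1
    ).fit(x, y)
    if importance == "impurity":
        scores = forest.feature_importances_
    else:
        res = permutation_importance(
            forest, x, y, n_repeats=n_repeats, random_state=rs, n_jobs=1
        )
        scores = res.importances_mean
    return ImportanceScores(
        scores=np.asarray(scores, dtype=float),
        gene_ids=list(data.gene_ids),
        method="random_forest",
        params={"n_trees": n_trees, "importance": importance, "seed": seed},
    )


def lasso_select(
    data: ExpressionDataset,
    seed: int | None = None,
    n_folds: int = 10,
    n_penalties: int = 20,
) -> ImportanceScores:
    """L1-penalized logistic regression with cross-validated penalty.

    Genes are z-scored; the penalty is chosen by stratified ``n_folds``-fold
    cross-validation at minimum deviance (log loss). Scores are the absolute
    coefficients at the selected penalty; exact zeros mean not selected.
    Main-effect terms only — no interaction features.
    """
    data.require_binary()
    y = np.asarray(data.phenotype, dtype=int)
    x = data.matrix.T
    xs = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    n_folds = min(n_folds, int(np.bincount(y).min()))
    rs = None if seed is None else seed % (2**32)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
    model = LogisticRegressionCV(
        Cs=n_penalties,
        cv=cv,
        l1_ratios=(1.0,),
        solver="saga",
        scoring="neg_log_loss",
        max_iter=5000,
        tol=1e-3,
        random_state=rs,
        use_legacy_attributes=False,
    ).fit(xs, y)
    return ImportanceScores(
        scores=np.abs(model.coef_.ravel()),
        gene_ids=list(data.gene_ids),
        method="lasso",
        params={"n_folds": n_folds, "C": float(np.ravel(model.C_)[0]), "seed": seed},
    )
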