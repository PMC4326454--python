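"""Core in-memory container for expression data with phenotype labels.

The matrix is gene-by-sample (genes as rows), the orientation used by most
microarray text exports. The phenotype is binary case/control (1/0) for
logistic models and the Fisher z-test, or real-valued for quantitative
traits under the Gaussian family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression matrix with sample phenotypes.

    Parameters
    ----------
    matrix : ndarray, shape (n_genes, n_samples)
        Real-valued expression, no missing values.
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    phenotype : ndarray, shape (n_samples,)
        Binary 0/1 case-control status or real-valued outcome.
    covariates : DataFrame or None
        Optional per-sample covariates (e.g. sex), indexed like ``sample_ids``.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    phenotype: np.ndarray
    covariates: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_genes, n_samples = self.matrix.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample ids")
        if self.phenotype.shape != (n_samples,):
            raise ValueError("phenotype length must equal sample count")
        if not np.all(np.isfinite(self.matrix)):
            bad = np.argwhere(~np.isfinite(self.matrix))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.covariates is not None and len(self.covariates) != n_samples:
            raise ValueError("covariate rows must equal sample count")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def is_binary(self) -> bool:
        """True when the phenotype takes only the values 0 and 1."""
        vals = np.unique(self.phenotype)
        return vals.size <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}

    def require_binary(self) -> None:
        vals = set(np.unique(np.asarray(self.phenotype, dtype=float)))
        if vals != {0.0, 1.0}:
            raise ValueError(
                "binary case/control phenotype with both classes required; "
                f"found values {sorted(vals)}"
            )

    def group_indices(self, group: int) -> np.ndarray:
        """Column indices of samples in phenotype group 0 or 1."""
        if group not in (0, 1):
            raise ValueError("group must be 0 or 1")
        return np.flatnonzero(np.asarray(self.phenotype, dtype=float) == group)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            matrix=self.matrix.copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            phenotype=self.phenotype.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
        )

    def subset_genes(self, indices: np.ndarray) -> "ExpressionDataset":
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[indices],
            gene_ids=[self.gene_ids[i] for i in indices],
            sample_ids=list(self.sample_ids),
            phenotype=self.phenotype.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
        )

    def with_phenotype(self, phenotype: np.ndarray) -> "ExpressionDataset":
        """Same expression and covariates, replaced phenotype vector."""
        out = self.copy()
        out.phenotype = np.asarray(phenotype)
        if out.phenotype.shape != (self.n_samples,):
            raise ValueError("phenotype length must equal sample count")
        return out
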