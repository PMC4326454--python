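"""Readers and writers for the on-disk formats.

All tabular formats are tab-separated, '.' decimal, UTF-8, LF — fixed
dialects so files diff bit-stably. Expression travels as a gene-by-sample
TSV (gene ids in the first column, sample ids in the header); phenotype as
a two-column TSV (sample_id, value) with optional extra covariate columns,
reconciled to the expression by sample id rather than by position.
Networks export as a full-matrix TSV, GraphML (weight edge attribute,
main-effect node attribute) or SIF with a weight sidecar.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .gain import GainMatrix, _batched_logistic_irls, _batched_ols, _standardize_rows

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "attach_phenotype",
    "read_gain",
    "write_gain",
    "export_network",
    "filter_top_probes",
    "write_simulation",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Parse a gene-by-sample TSV into a DataFrame (genes as rows).

    Rejects duplicate gene ids, ragged rows, and any missing or
    non-numeric cell, naming the offending gene and sample.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    if frame.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {frame.index[g]!r}, "
            f"sample {frame.columns[s]!r}"
        )
    return numeric


def write_expression(data: ExpressionDataset | pd.DataFrame, path: str | Path) -> None:
    if isinstance(data, ExpressionDataset):
        frame = pd.DataFrame(data.matrix, index=data.gene_ids, columns=data.sample_ids)
    else:
        frame = data
    frame.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Two-column-plus TSV: sample_id, phenotype, then covariate columns."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] < 1:
        raise ValueError(f"{path}: phenotype file needs at least two columns")
    if frame.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return frame


def write_phenotype(data: ExpressionDataset, path: str | Path) -> None:
    frame = pd.DataFrame({"phenotype": data.phenotype}, index=pd.Index(data.sample_ids, name="sample_id"))
    if data.covariates is not None:
        frame = pd.concat([frame, data.covariates.set_axis(frame.index)], axis=1)
    frame.to_csv(path, sep="\t", lineterminator="\n")


def attach_phenotype(expression: pd.DataFrame, phenotype: pd.DataFrame) -> ExpressionDataset:
    """Join an expression frame with a phenotype frame by sample id."""
    missing = [s for s in expression.columns if s not in phenotype.index]
    if missing:
        raise ValueError(f"samples missing from phenotype file: {missing}")
    pheno = phenotype.loc[list(expression.columns)]
    covariates = pheno.iloc[:, 1:] if pheno.shape[1] > 1 else None
    return ExpressionDataset(
        matrix=expression.to_numpy(dtype=float),
        gene_ids=list(expression.index),
        sample_ids=list(expression.columns),
        phenotype=pheno.iloc[:, 0].to_numpy(),
        covariates=None if covariates is None else covariates.reset_index(drop=True),
    )


def read_gain(path: str | Path, method: str = "unknown", signed: bool | None = None) -> GainMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: matrix header and first column disagree")
    w = frame.to_numpy(dtype=float)
    if signed is None:
        off = w.copy()
        np.fill_diagonal(off, 0.0)
        signed = bool((off < 0).any())
    return GainMatrix(weights=w, gene_ids=list(frame.index), method=method, signed=signed)


def write_gain(gain: GainMatrix, path: str | Path) -> None:
    gain.to_frame().to_csv(path, sep="\t", lineterminator="\n", float_format="%.12g")


def _gain_graph(gain: GainMatrix) -> nx.Graph:
    g = nx.Graph()
    for gid, main in zip(gain.gene_ids, np.diag(gain.weights)):
        g.add_node(gid, main_effect=float(main))
    n = gain.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            w = gain.weights[i, j]
            if w != 0:
                g.add_edge(gain.gene_ids[i], gain.gene_ids[j], weight=float(w))
    return g


def export_network(gain: GainMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write the interaction network as ``tsv``, ``graphml`` or ``sif``.

    SIF lines read ``gene1 pp gene2``; edge weights go to a ``.weights.tsv``
    sidecar next to the SIF file.
    """
    path = Path(path)
    if fmt == "tsv":
        write_gain(gain, path)
    elif fmt == "graphml":
        nx.write_graphml(_gain_graph(gain), path)
    elif fmt == "sif":
        graph = _gain_graph(gain)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for u, v in graph.edges:
                fh.write(f"{u}\tpp\t{v}\n")
        sidecar = path.with_suffix(path.suffix + ".weights.tsv")
        with open(sidecar, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene1\tgene2\tweight\n")
            for u, v, d in graph.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['weight']:.12g}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def filter_top_probes(data: ExpressionDataset, k: int, family: str | None = None) -> ExpressionDataset:
    """Keep the k genes with smallest single-gene GLM p-values.

    The single-gene model is outcome ~ intercept + gene (logistic for a
    binary phenotype, least squares otherwise), matching the family of the
    downstream analysis. Ties break deterministically by gene id. This is
    a light convenience filter; it is not cross-validated.
    """
    if not 0 < k <= data.n_genes:
        raise ValueError(f"k must be in [1, {data.n_genes}], got {k}")
    if family is None:
        family = "binomial" if data.is_binary else "gaussian"
    g = _standardize_rows(data.matrix)
    n, m = g.shape
    x = np.empty((n, m, 2))
    x[:, :, 0] = 1.0
    x[:, :, 1] = g
    y = np.asarray(data.phenotype, dtype=float)
    if family == "binomial":
        data.require_binary()
        beta, se, _ = _batched_logistic_irls(x, y)
        z = beta[:, 1] / se[:, 1]
        pvals = 2 * stats.norm.sf(np.abs(z))
    else:
        beta, se, _ = _batched_ols(x, y)
        t = beta[:, 1] / se[:, 1]
        pvals = 2 * stats.t.sf(np.abs(t), df=max(m - 2, 1))
    order = sorted(range(n), key=lambda i: (pvals[i], data.gene_ids[i]))
    keep = np.array(sorted(order[:k]))
    return data.subset_genes(keep)


def write_simulation(sim, out_prefix: str | Path) -> dict[str, Path]:
    """Write a simulated dataset: expression, phenotype, truth, topology."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": prefix.with_name(prefix.name + ".expr.tsv"),
        "phenotype": prefix.with_name(prefix.name + ".pheno.tsv"),
        "truth": prefix.with_name(prefix.name + ".truth.txt"),
        "graphml": prefix.with_name(prefix.name + ".topology.graphml"),
        "sif": prefix.with_name(prefix.name + ".topology.sif"),
    }
    write_expression(sim.expression, paths["expression"])
    write_phenotype(sim.expression, paths["phenotype"])
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        for idx in sorted(sim.truth):
            fh.write(f"{sim.expression.gene_ids[idx]}\n")
    graph = nx.from_numpy_array(sim.topology.adjacency)
    graph = nx.relabel_nodes(graph, dict(enumerate(sim.expression.gene_ids)))
    nx.write_graphml(graph, paths["graphml"])
    with open(paths["sif"], "w", encoding="utf-8", newline="\n") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\tpp\t{v}\n")
    return paths
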