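"""Replicate simulation study: TPR/FPR of each method against ground truth.

Runs the full benchmarking loop: simulate a case-control dataset with an
embedded differential co-expression (or main-effect) signal, score genes
with each method, call significance by permutation and/or Gaussian
mixture, and score the calls against the simulation truth. Within a
replicate every method sees the same simulated dataset (a paired design
that sharpens method contrasts).

Methods
-------
``dcgain_cinc`` / ``regain_cinc``
    GAIN matrix construction followed by CINC centrality.
``relieff`` / ``random_forest``
    Importance scores fed to the same significance procedures.
``lasso``
    Nonzero coefficients at the cross-validated penalty are read directly
    as the selected set (recorded under procedure ``selection`` and
    compared alongside both procedures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparators
from .centrality import cinc
from .gain import dcgain, regain
from .netsim import SimulationConfig, TopologyKind, simulate_dataset
from .significance import gmm_calls, permutation_calls

logger = logging.getLogger(__name__)

__all__ = ["StudyCondition", "tpr_fpr", "make_score_fn", "run_replicate_study", "summarize"]

SCORE_METHODS = ("dcgain_cinc", "regain_cinc", "relieff", "random_forest")
ALL_METHODS = SCORE_METHODS + ("lasso",)


def tpr_fpr(called: set[int], truth: set[int], n_genes: int) -> tuple[float, float]:
    """True/false positive rates of a called gene set against truth.

    TPR = |called ∩ truth| / |truth|; FPR = |called \\ truth| / (N − |truth|).
    """
    if not truth:
        raise ValueError("truth set is empty; TPR undefined")
    if not truth <= set(range(n_genes)):
        raise ValueError("truth contains indices outside the gene range")
    called = set(called)
    tp = len(called & truth)
    fp = len(called - truth)
    return tp / len(truth), fp / (n_genes - len(truth))


def _calls_to_indices(gene_ids: list[str], significant: np.ndarray) -> set[int]:
    return {i for i, s in enumerate(significant) if s}


@dataclass
class StudyCondition:
    """One cell of the simulation grid."""

    mode: str = "interaction"  # or "main_effect"
    kind: TopologyKind = TopologyKind.SCALE_FREE
    n_genes: int = 100
    n_samples: int = 40
    n_targets: int = 10
    noise: float = 0.05
    fold_change: float = 2.0
    topology_params: dict = field(default_factory=dict)

    def label(self) -> str:
        cond = self.noise if self.mode == "interaction" else self.fold_change
        return f"{self.mode}:{TopologyKind(self.kind).value}:{cond}:M{self.n_samples}"


def make_score_fn(
    method: str,
    gamma: float = 0.85,
    relieff_k: int = 10,
    rf_trees: int = 100,
    rf_importance: str = "impurity",
):
    """Build the (dataset, seed) -> per-gene scores function for a method."""
    if method == "dcgain_cinc":
        return lambda ds, seed: cinc(dcgain(ds), gamma=gamma).scores
    if method == "regain_cinc":
        return lambda ds, seed: cinc(regain(ds), gamma=gamma).scores
    if method == "relieff":
        return lambda ds, seed: comparators.relieff_scores(ds, k_neighbors=relieff_k).scores
    if method == "random_forest":
        return lambda ds, seed: comparators.random_forest_importance(
            ds, n_trees=rf_trees, seed=seed, importance=rf_importance
        ).scores
    raise ValueError(f"unknown score method {method!r}")


def run_replicate_study(
    conditions: list[StudyCondition],
    methods: tuple[str, ...] = ALL_METHODS,
    procedures: tuple[str, ...] = ("permutation", "gmm"),
    n_replicates: int = 20,
    seed: int = 0,
    m_perm: int = 50,
    percentile: float = 95.0,
    gamma: float = 0.85,
    relieff_k: int = 10,
    rf_trees: int = 100,
    rf_importance: str = "impurity",
) -> pd.DataFrame:
    """Run the simulation benchmark and return one row per evaluation.

    Every (condition, replicate) simulates one dataset reused by all
    methods. Score-based methods are scored once; permutation significance
    reruns the scorer on ``m_perm`` label-shuffled copies, and the mixture
    procedure reuses the same observed scores. Failures are recorded as
    NaN rows with the error message so a study never dies mid-grid.
    Fully deterministic given ``seed``.
    """
    records = []
    root = np.random.SeedSequence(seed)
    for c_idx, cond in enumerate(conditions):
        cond_ss = np.random.SeedSequence([seed, c_idx])
        rep_seeds = cond_ss.spawn(n_replicates)
        for r, rep_ss in enumerate(rep_seeds):
            sim_seed, *method_seeds = [
                int(s.generate_state(1)[0] % (2**31)) for s in rep_ss.spawn(len(methods) + 1)
            ]
            config = SimulationConfig(
                n_genes=cond.n_genes,
                n_samples=cond.n_samples,
                n_targets=cond.n_targets,
                noise=cond.noise,
                fold_change=cond.fold_change,
                kind=cond.kind,
                topology_params=dict(cond.topology_params),
                seed=sim_seed,
            )
            sim = simulate_dataset(config, mode=cond.mode)
            for method, mseed in zip(methods, method_seeds):
                for rec in _evaluate_method(
                    method, sim.expression, sim.truth, cond, r, mseed,
                    procedures, m_perm, percentile, gamma, relieff_k,
                    rf_trees, rf_importance,
                ):
                    records.append(rec)
    return pd.DataFrame.from_records(records)


def _evaluate_method(
    method, data, truth, cond, replicate, seed,
    procedures, m_perm, percentile, gamma, relieff_k, rf_trees, rf_importance,
):
    base = {
        "method": method,
        "mode": cond.mode,
        "topology": TopologyKind(cond.kind).value,
        "condition": cond.noise if cond.mode == "interaction" else cond.fold_change,
        "n_samples": cond.n_samples,
        "replicate": replicate,
    }
    n = data.n_genes
    out = []
    try:
        if method == "lasso":
            sel = comparators.lasso_select(data, seed=seed)
            called = {i for i, s in enumerate(sel.scores) if s != 0}
            tpr, fpr = tpr_fpr(called, truth, n)
            out.append(base | {"procedure": "selection", "tpr": tpr, "fpr": fpr})
            return out
        score_fn = make_score_fn(method, gamma, relieff_k, rf_trees, rf_importance)
        perm = None
        if "permutation" in procedures:
            perm = permutation_calls(
                score_fn, data, m_perm=m_perm, percentile=percentile, seed=seed
            )
            called = _calls_to_indices(perm.gene_ids, perm.significant)
            tpr, fpr = tpr_fpr(called, truth, n)
            out.append(base | {"procedure": "permutation", "tpr": tpr, "fpr": fpr})
        if "gmm" in procedures:
            scores = perm.scores if perm is not None else np.asarray(score_fn(data, seed))
            gmm = gmm_calls(scores, gene_ids=list(data.gene_ids), seed=seed)
            called = _calls_to_indices(gmm.gene_ids, gmm.significant)
            tpr, fpr = tpr_fpr(called, truth, n)
            out.append(base | {"procedure": "gmm", "tpr": tpr, "fpr": fpr})
    except Exception as exc:  # noqa: BLE001 - study must survive cell failures
        logger.error("method %s failed on replicate %d: %s", method, replicate, exc)
        out.append(base | {"procedure": "error", "tpr": np.nan, "fpr": np.nan,
                           "error": str(exc)})
    return out


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Mean TPR/FPR per (mode, topology, condition, M, method, procedure)."""
    keys = ["mode", "topology", "condition", "n_samples", "method", "procedure"]
    return (
        records.groupby(keys, dropna=False)[["tpr", "fpr"]]
        .agg(["mean", "count"])
        .reset_index()
    )
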