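"""Network-based case-control expression simulator with ground truth.

Builds datasets whose control-group co-expression follows a prescribed
network topology (scale-free via preferential attachment, or Erdős–Rényi),
then creates differential co-expression by "random attacks": permuting the
case-group values of randomly chosen target genes. The attack preserves
each target's case-group mean exactly (it permutes a multiset), so no main
effect is introduced — only the wiring between the target and its network
neighbours is disrupted in cases. A separate main-effect mode adds a
log2-scale fold-change shift to target genes in cases instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np

from .dataset import ExpressionDataset

__all__ = [
    "TopologyKind",
    "NetworkTopology",
    "SimulationConfig",
    "SimulatedDataset",
    "generate_topology",
    "generate_base_expression",
    "apply_differential_coexpression",
    "apply_main_effects",
    "simulate_dataset",
]


class TopologyKind(str, Enum):
    SCALE_FREE = "scale_free"
    ERDOS_RENYI = "erdos_renyi"


@dataclass
class NetworkTopology:
    """Undirected binary adjacency on N genes plus its generating family."""

    adjacency: np.ndarray
    kind: TopologyKind
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(int)

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class SimulationConfig:
    """Parameters of one simulated case-control dataset."""

    n_genes: int = 100
    n_samples: int = 40
    n_targets: int | None = None  # default ceil(0.10 * n_genes)
    noise: float = 0.05
    fold_change: float = 2.0
    log2_sd: float = 0.7
    kind: TopologyKind = TopologyKind.SCALE_FREE
    topology_params: dict = field(default_factory=dict)
    chain: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = TopologyKind(self.kind)
        if self.n_targets is None:
            self.n_targets = int(np.ceil(0.10 * self.n_genes))
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.n_samples < 4 or self.n_samples % 2:
            raise ValueError("sample count must be even and >= 4")
        if not 0 < self.n_targets < self.n_genes:
            raise ValueError("n_targets must be in (0, n_genes)")
        if self.noise <= 0:
            raise ValueError("noise must be positive")
        if self.fold_change < 1:
            raise ValueError("fold change must be >= 1")


@dataclass
class SimulatedDataset:
    """Simulated expression plus the ground truth needed for evaluation."""

    expression: ExpressionDataset
    topology: NetworkTopology
    truth: set[int]
    config: SimulationConfig | None = None


def generate_topology(
    kind: TopologyKind | str,
    n_genes: int,
    *,
    m_attach: int = 1,
    edge_prob: float | None = None,
    seed: int | None = None,
) -> NetworkTopology:
    """Generate a binary undirected network of the requested family.

    Scale-free graphs come from Barabási–Albert preferential attachment
    with ``m_attach`` edges per new node (connected by construction).
    Erdős–Rényi graphs use an independent uniform edge probability
    ``edge_prob``; when omitted, ``edge_prob`` is chosen to match the
    expected edge count of the scale-free graph at the same size
    (m_attach·(N − m_attach) edges), so topology comparisons hold edge
    density roughly constant.
    """
    kind = TopologyKind(kind)
    if n_genes < 2:
        raise ValueError("need at least 2 nodes")
    if kind is TopologyKind.SCALE_FREE:
        if m_attach < 1:
            raise ValueError("attachment count must be >= 1")
        if m_attach >= n_genes:
            raise ValueError("attachment count must be below the node count")
        g = nx.barabasi_albert_graph(n_genes, m_attach, seed=seed)
        params = {"m_attach": m_attach}
    elif kind is TopologyKind.ERDOS_RENYI:
        if edge_prob is None:
            n_edges_sf = m_attach * (n_genes - m_attach)
            edge_prob = n_edges_sf / (n_genes * (n_genes - 1) / 2)
        if not 0 <= edge_prob <= 1:
            raise ValueError("edge probability must lie in [0, 1]")
        g = nx.gnp_random_graph(n_genes, edge_prob, seed=seed)
        params = {"edge_prob": edge_prob}
    else:  # pragma: no cover - TopologyKind() already rejects unknown names
        raise ValueError(f"unknown topology kind {kind!r}")
    adjacency = nx.to_numpy_array(g, nodelist=range(n_genes), dtype=int)
    return NetworkTopology(adjacency=adjacency, kind=kind, params=params)


def generate_base_expression(
    topology: NetworkTopology,
    n_samples: int,
    noise: float,
    seed: int | None = None,
    *,
    chain: bool = True,
) -> ExpressionDataset:
    """Build the baseline matrix whose correlation follows the topology.

    The matrix starts as independent standard Gaussian rows. Iterating genes
    in index order, each still-unmodified neighbour j of gene i is replaced
    by gene i's row plus Gaussian(0, noise) draws; a gene is modified at most
    once. With unit-variance sources this yields an edge-wise correlation of
    1/sqrt(1 + noise^2) between a copy and its source. The same structure is
    imposed on all samples, so there is no group difference yet.

    ``chain=False`` restricts copy sources to genes that were never
    themselves modified, preventing correlation decay along network paths.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if noise <= 0:
        raise ValueError("noise must be positive")
    rng = np.random.default_rng(seed)
    n = topology.n_genes
    x = rng.standard_normal((n, n_samples))
    modified = np.zeros(n, dtype=bool)
    adj = topology.adjacency
    for i in range(n):
        if not chain and modified[i]:
            continue
        for j in np.flatnonzero(adj[i]):
            if j == i or modified[j]:
                continue
            x[j] = x[i] + rng.normal(0.0, noise, size=n_samples)
            modified[j] = True
    # Balanced split fixed up front; labels travel with sample ids so
    # column order is never load-bearing downstream.
    half = n_samples // 2
    phenotype = np.concatenate([np.ones(half, dtype=int), np.zeros(n_samples - half, dtype=int)])
    return ExpressionDataset(
        matrix=x,
        gene_ids=[f"g{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        phenotype=phenotype,
    )


def _choose_targets(n_genes: int, n_targets: int, rng: np.random.Generator) -> np.ndarray:
    if not 0 <= n_targets < n_genes:
        raise ValueError("n_targets must satisfy 0 <= n_targets < n_genes")
    return np.sort(rng.choice(n_genes, size=n_targets, replace=False))


def apply_differential_coexpression(
    base: ExpressionDataset,
    topology: NetworkTopology,
    n_targets: int,
    seed: int | None = None,
    config: SimulationConfig | None = None,
) -> SimulatedDataset:
    """Random-attack the case group to create differential co-expression.

    For each of ``n_targets`` randomly chosen genes, the values in case
    columns are randomly permuted in place. The permutation preserves the
    case-group mean (same multiset of values) but destroys the pairing with
    every neighbour, so the target's edges survive only in controls.
    ``n_targets=0`` is a no-op with empty truth.
    """
    if base.n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    data = base.copy()
    cases = data.group_indices(1)
    targets = _choose_targets(base.n_genes, n_targets, rng)
    for g in targets:
        data.matrix[g, cases] = rng.permutation(data.matrix[g, cases])
    return SimulatedDataset(
        expression=data, topology=topology, truth=set(int(t) for t in targets), config=config
    )


def apply_main_effects(
    base: ExpressionDataset,
    topology: NetworkTopology,
    n_targets: int,
    fold_change: float,
    log2_sd: float = 0.7,
    seed: int | None = None,
    config: SimulationConfig | None = None,
) -> SimulatedDataset:
    """Add log2-scale fold-change shifts to target genes in the case group.

    The matrix is interpreted as log2 intensities: every gene row is scaled
    to a per-gene standard deviation of ``log2_sd`` (0.7 by default, a
    realistic spread for moderately-to-highly expressed genes), a positive
    scaling that leaves all correlations untouched. Target genes then gain
    an additive ``log2(fold_change)`` in case columns, giving a standardized
    effect size of log2(FC)/log2_sd per target.
    """
    if fold_change < 1:
        raise ValueError("fold change must be >= 1")
    rng = np.random.default_rng(seed)
    data = base.copy()
    sd = data.matrix.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    data.matrix = data.matrix / sd * log2_sd
    cases = data.group_indices(1)
    targets = _choose_targets(base.n_genes, n_targets, rng)
    shift = np.log2(fold_change)
    for g in targets:
        data.matrix[g, cases] += shift
    return SimulatedDataset(
        expression=data, topology=topology, truth=set(int(t) for t in targets), config=config
    )


def simulate_dataset(
    config: SimulationConfig,
    mode: str = "interaction",
) -> SimulatedDataset:
    """One-call simulation: topology, base expression, then the chosen attack.

    ``mode`` is ``"interaction"`` (differential co-expression via case-group
    permutation) or ``"main_effect"`` (fold-change shift). Seeds for the
    three stages are derived from ``config.seed`` so a config is fully
    reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    s_topo, s_base, s_attack = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    topology = generate_topology(
        config.kind,
        config.n_genes,
        seed=s_topo,
        **config.topology_params,
    )
    base = generate_base_expression(
        topology, config.n_samples, config.noise, seed=s_base, chain=config.chain
    )
    if mode == "interaction":
        return apply_differential_coexpression(
            base, topology, config.n_targets, seed=s_attack, config=config
        )
    if mode == "main_effect":
        return apply_main_effects(
            base,
            topology,
            config.n_targets,
            config.fold_change,
            config.log2_sd,
            seed=s_attack,
            config=config,
        )
    raise ValueError(f"unknown simulation mode {mode!r}")
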