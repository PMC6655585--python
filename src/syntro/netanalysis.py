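"""Carbon-source syntrophy network and core-periphery structure.

Nodes are carbon sources; edges are weighted by the pair syntrophic
potential. The display threshold (default 0.55) only filters which edges
are *shown*; structural analysis always runs on the full weighted
network. Core-periphery detection maximizes the Pearson correlation
between the observed weights and the ideal two-role pattern (core-core
and core-periphery ties present, periphery-periphery absent) by greedy
label flipping from many seeded random restarts; nodes whose weight
pattern contradicts both roles (stronger ties to the periphery than to
the core) are reported as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import SyntroError
from .stats import PotentialTable

__all__ = [
    "CarbonNetwork",
    "CorePartition",
    "build_network",
    "core_periphery",
    "assortativity",
]


@dataclass
class CarbonNetwork:
    """Complete weighted carbon-source network (self-loops included)."""

    nodes: list[str]
    weights: dict[tuple[str, str], float]  # keys sorted, includes (c, c)
    display_threshold: float = 0.55

    def __post_init__(self) -> None:
        for key, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise SyntroError(f"edge weight {w} for {key} outside [0, 1]")
            if tuple(sorted(key)) != tuple(key):
                raise SyntroError(f"weight key {key} not sorted")

    def weight(self, a: str, b: str) -> float:
        return self.weights.get(tuple(sorted((a, b))), 0.0)

    def graph(self, include_self_loops: bool = False) -> nx.Graph:
        """Full weighted graph (zero-weight pairs omitted)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.weights.items():
            if a == b and not include_self_loops:
                continue
            if w > 0.0:
                g.add_edge(a, b, weight=w)
        return g

    def thresholded_graph(self, threshold: float | None = None) -> nx.Graph:
        """Display graph: only edges strictly above the threshold weight."""
        t = self.display_threshold if threshold is None else threshold
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.weights.items():
            if a != b and w > t:
                g.add_edge(a, b, weight=w)
        return g


def build_network(table: PotentialTable, display_threshold: float = 0.55) -> CarbonNetwork:
    """Carbon-source network weighted by the pair syntrophic potential."""
    nodes = sorted({c for key in table.sp_bar for c in key})
    return CarbonNetwork(
        nodes=nodes,
        weights={tuple(key): w for key, w in table.sp_bar.items()},
        display_threshold=display_threshold,
    )


@dataclass
class CorePartition:
    core: frozenset[str]
    periphery: frozenset[str]
    outliers: frozenset[str]
    score: float
    degenerate: bool = False  # equal-weight network: no meaningful partition

    def role(self, node: str) -> str:
        if node in self.core:
            return "core"
        if node in self.periphery:
            return "periphery"
        if node in self.outliers:
            return "outlier"
        raise KeyError(node)


def _pattern_correlation(W: np.ndarray, core_mask: np.ndarray, iu: tuple) -> float:
    """Pearson correlation between off-diagonal weights and the ideal
    core-periphery pattern (1 unless both endpoints are periphery)."""
    ideal = (core_mask[:, None] | core_mask[None, :]).astype(float)
    x = W[iu]
    y = ideal[iu]
    if np.ptp(y) == 0.0:  # all-core or single-node degenerate labeling
        return -np.inf
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / denom) if denom > 0 else -np.inf


def core_periphery(
    network: CarbonNetwork,
    n_restarts: int = 50,
    seed: int = 0,
    outlier_tol: float = 0.1,
) -> CorePartition:
    """Two-role partition maximizing the ideal-pattern correlation.

    Greedy single-node label flips from ``n_restarts`` seeded random
    starts. After the fit, a node whose mean weight to the periphery
    exceeds its mean weight to the core by more than ``outlier_tol`` fits
    neither role (the ideal pattern gives every node core ties at least as
    strong as periphery ties) and is moved to ``outliers``. A network with
    (numerically) identical weights everywhere has no structure to fit and
    is returned with ``degenerate=True``.
    """
    nodes = list(network.nodes)
    n = len(nodes)
    if n < 3:
        raise SyntroError("core-periphery detection needs at least 3 nodes")
    W = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            W[a, b] = W[b, a] = network.weight(nodes[a], nodes[b])
    iu = np.triu_indices(n, k=1)
    if np.ptp(W[iu]) < 1e-12:
        return CorePartition(
            core=frozenset(),
            periphery=frozenset(nodes),
            outliers=frozenset(),
            score=float("nan"),
            degenerate=True,
        )

    rng = np.random.default_rng(seed)
    best_mask = None
    best_score = -np.inf
    for _ in range(n_restarts):
        mask = rng.random(n) < 0.5
        score = _pattern_correlation(W, mask, iu)
        improved = True
        while improved:
            improved = False
            for v in rng.permutation(n):
                mask[v] = ~mask[v]
                trial = _pattern_correlation(W, mask, iu)
                if trial > score:
                    score = trial
                    improved = True
                else:
                    mask[v] = ~mask[v]
        if score > best_score:
            best_score = score
            best_mask = mask.copy()

    core = {nodes[i] for i in range(n) if best_mask[i]}
    periphery = {nodes[i] for i in range(n) if not best_mask[i]}
    outliers = set()
    if core and periphery:
        for i, v in enumerate(nodes):
            others_core = [W[i, j] for j in range(n) if j != i and best_mask[j]]
            others_peri = [W[i, j] for j in range(n) if j != i and not best_mask[j]]
            if not others_core or not others_peri:
                continue
            if np.mean(others_peri) > np.mean(others_core) + outlier_tol:
                outliers.add(v)
    return CorePartition(
        core=frozenset(core - outliers),
        periphery=frozenset(periphery - outliers),
        outliers=frozenset(outliers),
        score=best_score,
    )


def assortativity(network: CarbonNetwork) -> float:
    """Weighted degree assortativity of the full network (self-loops
    excluded); NaN flags an undefined value (e.g. a regular uniform
    network with zero degree variance)."""
    g = network.graph(include_self_loops=False)
    if g.number_of_edges() == 0:
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = nx.degree_assortativity_coefficient(g, weight="weight")
    return float(r)
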