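"""Per-cell coactivation networks weighted by uniqueness.

Each cell's active genes form a fully connected coactivation network with
C(N, 2) edges.  Edges observed in more than a small fraction of the whole
cell population (prevalence) are removed, leaving the gene pairs that are
uniquely coactive in that cell.  Network shape is summarised by Freeman
degree centralization,

    C = sum_i (d_max - d_i) / ((N - 1)(N - 2)),

which is 1 for a star (hub-partner topology) and 0 for any degree-regular
graph, and compared between mature and immature cells with a two-sided
two-sample t-test across a sweep of prevalence thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from coactive.coactivation import MaturityGroups

DEFAULT_THRESHOLDS = (0.005, 0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass
class EdgePrevalence:
    """Population prevalence of pairwise coactivation.

    ``counts[j, k]`` is the number of cells in which genes j and k are both
    active (diagonal zeroed; no self-edges); prevalence = counts / n_cells.
    """

    genes: list[str]
    counts: np.ndarray
    n_cells: int

    def prevalence(self, gene_a: str, gene_b: str) -> float:
        j, k = self.genes.index(gene_a), self.genes.index(gene_b)
        return self.counts[j, k] / self.n_cells


@dataclass
class CellNetwork:
    cell: str
    graph: nx.Graph
    centralization: float  # NaN when fewer than 3 nodes
    group: str = "other"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CentralizationComparison:
    threshold: float
    min_nodes: int
    n_mature: int
    n_immature: int
    mean_mature: float
    mean_immature: float
    t_statistic: float
    p_value: float
    available: bool


def edge_prevalence(binary: pd.DataFrame) -> EdgePrevalence:
    """Coactivation counts for every gene pair across all cells.

    ``binary`` is genes x cells with 0/1 entries (NaN treated as inactive).
    """
    if binary.shape[1] < 1:
        raise ValueError("need at least one cell")
    B = np.nan_to_num(binary.to_numpy(dtype=float))
    counts = (B @ B.T).astype(np.int64)
    np.fill_diagonal(counts, 0)
    return EdgePrevalence(
        genes=list(binary.index), counts=counts, n_cells=binary.shape[1]
    )


def build_cell_network(
    binary: pd.DataFrame,
    cell: str,
    prevalence: EdgePrevalence,
    threshold: float = 0.01,
    group: str = "other",
) -> CellNetwork:
    """One cell's uniqueness-filtered coactivation network.

    Nodes are the cell's active genes; starting from the full clique, an edge
    is removed when its population prevalence is strictly greater than
    ``threshold`` ("more than" the cutoff).  Isolated nodes remain in the
    node set.  A cell with no active genes yields an empty network.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    col = binary[cell].to_numpy(dtype=float)
    active_idx = np.flatnonzero(col == 1)
    genes = [binary.index[i] for i in active_idx]
    g = nx.Graph()
    g.add_nodes_from(genes)
    if active_idx.size >= 2:
        sub = prevalence.counts[np.ix_(active_idx, active_idx)] / prevalence.n_cells
        jj, kk = np.triu_indices(active_idx.size, k=1)
        keep = sub[jj, kk] <= threshold
        g.add_edges_from((genes[j], genes[k]) for j, k in zip(jj[keep], kk[keep]))
    return CellNetwork(
        cell=cell, graph=g, centralization=degree_centralization(g), group=group
    )


def degree_centralization(network: CellNetwork | nx.Graph) -> float:
    """Freeman degree centralization; NaN for networks with fewer than 3 nodes."""
    g = network.graph if isinstance(network, CellNetwork) else network
    n = g.number_of_nodes()
    if n < 3:
        return float("nan")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def build_all_networks(
    binary: pd.DataFrame,
    prevalence: EdgePrevalence,
    threshold: float = 0.01,
    groups: MaturityGroups | None = None,
) -> list[CellNetwork]:
    """Networks for every cell, tagged with maturity group when supplied."""
    labels: dict[str, str] = {}
    if groups is not None:
        labels.update({c: "mature" for c in groups.mature_cells})
        labels.update({c: "immature" for c in groups.immature_cells})
    return [
        build_cell_network(
            binary, cell, prevalence, threshold, group=labels.get(cell, "other")
        )
        for cell in binary.columns
    ]


def compare_group_centralization(
    binary: pd.DataFrame,
    groups: MaturityGroups,
    thresholds=DEFAULT_THRESHOLDS,
    min_nodes: int = 5,
    prevalence: EdgePrevalence | None = None,
    pooled: bool = False,
) -> list[CentralizationComparison]:
    """Mature-vs-immature centralization contrast across a threshold sweep.

    At each prevalence threshold, networks with at least ``min_nodes`` nodes
    are kept and a two-sided two-sample t-test (Welch by default; set
    ``pooled`` for equal-variance) compares centralization between the
    groups.  A threshold where either group has fewer than 2 eligible
    networks is marked unavailable.
    """
    if prevalence is None:
        prevalence = edge_prevalence(binary)
    results = []
    for thr in thresholds:
        per_group: dict[str, list[float]] = {"mature": [], "immature": []}
        for group_name, cells in (
            ("mature", groups.mature_cells),
            ("immature", groups.immature_cells),
        ):
            for cell in cells:
                net = build_cell_network(binary, cell, prevalence, thr, group_name)
                if net.n_nodes >= min_nodes and np.isfinite(net.centralization):
                    per_group[group_name].append(net.centralization)
        m, i = per_group["mature"], per_group["immature"]
        if len(m) >= 2 and len(i) >= 2:
            t, p = stats.ttest_ind(m, i, equal_var=pooled)
            available = True
        else:
            t, p, available = float("nan"), float("nan"), False
        results.append(
            CentralizationComparison(
                threshold=thr,
                min_nodes=min_nodes,
                n_mature=len(m),
                n_immature=len(i),
                mean_mature=float(np.mean(m)) if m else float("nan"),
                mean_immature=float(np.mean(i)) if i else float("nan"),
                t_statistic=float(t),
                p_value=float(p),
                available=available,
            )
        )
    return results
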