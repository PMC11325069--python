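"""Binary undirected networks from node time-series at a prescribed density.

Edges are the top off-diagonal Pearson correlations (signed, positive tail),
keeping exactly floor(N*K/2) node pairs so that every subject's network has
the same edge count. The target mean degree K is derived from the density
exponent S through K = N**(1/S), i.e. S = log(N)/log(K).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "BinaryNetwork",
    "correlation_matrix",
    "degree_for_s",
    "threshold_to_density",
    "build_network",
]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph stored as a lexicographically sorted
    (E, 2) array of node pairs with i < j."""

    n_nodes: int
    edges: np.ndarray
    target_mean_degree: float
    s_value: Optional[float] = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size and np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must satisfy i < j (no self-loops)")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        A[self.edges[:, 0], self.edges[:, 1]] = True
        A[self.edges[:, 1], self.edges[:, 0]] = True
        return A

    def to_files(self, edge_path: str | Path, sidecar_path: str | Path) -> None:
        np.savetxt(edge_path, self.edges, fmt="%d", delimiter="\t",
                   header="node_i\tnode_j", comments="")
        meta = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "target_mean_degree": self.target_mean_degree,
            "s_value": self.s_value,
            "realized_mean_degree": self.mean_degree,
            "realized_density": self.n_edges / (self.n_nodes * (self.n_nodes - 1) / 2),
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_files(cls, edge_path: str | Path, sidecar_path: str | Path) -> "BinaryNetwork":
        meta = json.loads(Path(sidecar_path).read_text())
        edges = np.loadtxt(edge_path, dtype=np.int64, delimiter="\t", skiprows=1, ndmin=2)
        return cls(meta["n_nodes"], edges, meta["target_mean_degree"], meta["s_value"])


def correlation_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of rows (nodes)."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("timeseries must be 2-D with at least 3 timepoints")
    sd = ts.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant time-series for nodes {constant.tolist()}")
    return np.corrcoef(ts)


def degree_for_s(n_nodes: int, s_value: float) -> float:
    """Invert S = log(N)/log(K): the mean degree K achieving exponent S."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if s_value <= 0:
        raise ValueError("s_value must be positive")
    return float(n_nodes) ** (1.0 / s_value)


def threshold_to_density(
    corr_matrix: np.ndarray,
    k_target: float,
    s_value: Optional[float] = None,
) -> BinaryNetwork:
    """Keep the floor(N*K/2) largest off-diagonal correlations as edges.

    Ties are broken by lexicographic (i, j) pair order so the edge set is a
    deterministic function of the correlation matrix.
    """
    C = np.asarray(corr_matrix, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    if not 0 < k_target < n - 1:
        raise ValueError(f"k_target must lie in (0, {n - 1})")
    n_keep = int(np.floor(n * k_target / 2.0))
    iu, ju = np.triu_indices(n, k=1)
    if n_keep < 1 or n_keep > iu.size:
        raise ValueError("k_target infeasible for this node count")
    vals = C[iu, ju]
    # top-n_keep by value; ties at the cutoff resolved in lexicographic (i, j)
    # order (iu/ju from triu_indices are already lexicographically sorted)
    if n_keep < vals.size:
        cut = np.partition(vals, vals.size - n_keep)[vals.size - n_keep]
        sure = vals > cut
        short = n_keep - int(sure.sum())
        keep = sure
        if short > 0:
            tied = np.flatnonzero(vals == cut)
            keep = sure.copy()
            keep[tied[:short]] = True
    else:
        keep = np.ones(vals.size, dtype=bool)
    edges = np.column_stack((iu[keep], ju[keep]))
    return BinaryNetwork(n, edges, float(k_target), s_value)


def build_network(timeseries: np.ndarray, s_value: float = 2.5) -> BinaryNetwork:
    """Correlate rows and threshold to the density implied by exponent S."""
    C = correlation_matrix(timeseries)
    k = degree_for_s(C.shape[0], s_value)
    return threshold_to_density(C, k, s_value=s_value)
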