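"""Binary network construction by cumulative thresholding, plus ER nulls.

Weighted NMI matrices are converted into binary graphs by retaining the
top fraction kappa (the network *cost* or density) of the strongest
off-diagonal weights: the floor(kappa * N(N-1)/2) largest upper-triangle
entries become edges. Sweeping kappa from 0.01 to 0.50 in steps of 0.01
yields 50 nested binary networks per weighted matrix, so that group
comparisons at fixed cost are blind to overall strength differences
(rescaling the weights by any positive constant changes nothing).

The random-graph null is the exact-edge-count Erdos-Renyi model G(n, M)
with M matched to the cost under comparison, sampled in seeded ensembles
of 66 graphs (one per trial network).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_COST_GRID",
    "default_cost_grid",
    "BinaryNetwork",
    "NetworkEnsemble",
    "edge_ranking",
    "cumulative_threshold",
    "threshold_sweep",
    "er_random_graphs",
    "to_edge_list",
    "save_ensemble",
    "load_ensemble",
]


def default_cost_grid() -> np.ndarray:
    """The standard density grid: 0.01 to 0.50 inclusive, step 0.01."""
    return np.round(np.arange(1, 51) * 0.01, 2)


DEFAULT_COST_GRID = default_cost_grid()


@dataclass
class BinaryNetwork:
    """Symmetric boolean adjacency with its nominal cost kappa."""

    adjacency: np.ndarray
    cost: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(a != a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("no self-loops allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)


@dataclass
class NetworkEnsemble:
    """Binary networks indexed by cost over a grid.

    For cumulative-threshold ensembles the edge sets are nested: the
    network at a smaller cost is a subgraph of the network at any larger
    cost (shared ranking).
    """

    costs: np.ndarray
    networks: list[BinaryNetwork]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.costs) != len(self.networks):
            raise ValueError("costs and networks disagree in length")

    def at(self, cost: float) -> BinaryNetwork:
        i = int(np.argmin(np.abs(np.asarray(self.costs) - cost)))
        return self.networks[i]


def edge_ranking(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges ranked by descending weight.

    Ties are broken lexicographically by (i, j), deterministically.
    Returns (rows, cols) index arrays of length N(N-1)/2.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    # lexsort keys: last key is primary. Sort by -weight, then i, then j.
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def cumulative_threshold(weights: np.ndarray, kappa: float) -> BinaryNetwork:
    """Binary network keeping the floor(kappa * N(N-1)/2) strongest edges."""
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("cost must lie in [0, 1]")
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    rows, cols = edge_ranking(w)
    m = int(np.floor(kappa * n * (n - 1) / 2 + 1e-9))
    adj = np.zeros((n, n), dtype=bool)
    adj[rows[:m], cols[:m]] = True
    adj |= adj.T
    return BinaryNetwork(adj, float(kappa))


def threshold_sweep(
    weights: np.ndarray, grid: np.ndarray | None = None
) -> NetworkEnsemble:
    """Nested binary networks across the cost grid (one shared ranking)."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if grid is None:
        grid = default_cost_grid()
    grid = np.asarray(grid, dtype=float)
    rows, cols = edge_ranking(w)
    n_pairs = n * (n - 1) // 2
    nets = []
    adj = np.zeros((n, n), dtype=bool)
    prev_m = 0
    for kappa in grid:
        m = int(np.floor(kappa * n_pairs + 1e-9))
        if m < prev_m:
            raise ValueError("cost grid must be non-decreasing")
        adj[rows[prev_m:m], cols[prev_m:m]] = True
        adj[cols[prev_m:m], rows[prev_m:m]] = True
        prev_m = m
        nets.append(BinaryNetwork(adj.copy(), float(kappa)))
    return NetworkEnsemble(np.asarray(grid), nets)


def er_random_graphs(
    n_nodes: int,
    kappa: float,
    n_graphs: int = 66,
    seed: int | None = 0,
) -> NetworkEnsemble:
    """Seeded ensemble of G(n, M) graphs with M = floor(kappa * n(n-1)/2).

    Edges are chosen uniformly without replacement, so every graph has
    exactly the matched edge count (fixed-density null).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    n_pairs = iu.size
    m = int(np.floor(kappa * n_pairs + 1e-9))
    nets = []
    for _ in range(n_graphs):
        pick = rng.choice(n_pairs, size=m, replace=False)
        adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        adj[iu[pick], ju[pick]] = True
        adj |= adj.T
        nets.append(BinaryNetwork(adj, float(kappa)))
    return NetworkEnsemble(np.full(n_graphs, float(kappa)), nets, source="er")


def to_edge_list(net: BinaryNetwork) -> np.ndarray:
    """Two-column array of 0-based sensor indices, one row per edge."""
    iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
    return np.column_stack([iu, ju])


def save_ensemble(ensemble: NetworkEnsemble, path, group: str = "ensemble") -> None:
    """Cache an ensemble as bit-packed adjacency in an HDF5 container."""
    import h5py

    n = ensemble.networks[0].n_nodes
    packed = np.stack(
        [np.packbits(net.adjacency, axis=None) for net in ensemble.networks]
    )
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("packed", data=packed, compression="gzip")
        g.create_dataset("costs", data=np.asarray(ensemble.costs, dtype=float))
        g.attrs["n_nodes"] = n
        g.attrs["source"] = ensemble.source


def load_ensemble(path, group: str = "ensemble") -> NetworkEnsemble:
    """Read a bit-packed ensemble back from HDF5."""
    import h5py

    with h5py.File(path, "r") as f:
        g = f[group]
        n = int(g.attrs["n_nodes"])
        costs = g["costs"][...]
        packed = g["packed"][...]
        source = g.attrs.get("source", "")
    nets = []
    for row, cost in zip(packed, costs):
        adj = np.unpackbits(row)[: n * n].reshape(n, n).astype(bool)
        nets.append(BinaryNetwork(adj, float(cost)))
    return NetworkEnsemble(costs, nets, source=source)
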