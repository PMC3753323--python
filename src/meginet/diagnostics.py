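"""Binary graph diagnostics over the density sweep.

Twelve diagnostics summarize each binary network: global and local
efficiency, betweenness centrality, clustering coefficient, modularity,
hierarchy, synchronizability, assortativity, robustness to targeted and
random attack, Rent's exponent, and mean connection distance. Path
length is computed alongside them. Evaluating every diagnostic at every
cost of a nested ensemble and averaging over the trial networks yields
one diagnostic-versus-cost curve per subject and network kind; the
cost-efficiency collapses the global-efficiency curve into
``max_kappa (E_glob(kappa) - kappa)``.

Conventions for fragmented graphs (the low-cost networks always are):
path length averages over connected ordered pairs only, global
efficiency uses 1/inf = 0 for disconnected pairs, and diagnostics whose
preconditions fail (e.g. assortativity on a regular graph) are reported
as missing (NaN), never as zero.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigvalsh

from .networks import BinaryNetwork, NetworkEnsemble
from .synthetic import SensorLayout

__all__ = [
    "DIAGNOSTICS",
    "CV_DIAGNOSTICS",
    "DiagnosticsConfig",
    "basic_metrics",
    "betweenness_centrality",
    "modularity",
    "hierarchy_exponent",
    "synchronizability",
    "robustness",
    "mean_connection_distance",
    "rent_exponent",
    "cost_efficiency",
    "CostEfficiencyResult",
    "all_diagnostics",
    "evaluate_ensembles",
]

#: The 12 diagnostics of the group-comparison grid, in report order.
DIAGNOSTICS = (
    "global_efficiency",
    "betweenness",
    "clustering",
    "local_efficiency",
    "modularity",
    "hierarchy",
    "synchronizability",
    "assortativity",
    "robustness_targeted",
    "robustness_random",
    "rent_exponent",
    "mean_connection_distance",
)

#: Diagnostics retained for the temporal-variability (CV) analysis:
#: hierarchy and assortativity are excluded because their values sit near
#: zero, making the CV ill-conditioned.
CV_DIAGNOSTICS = tuple(
    d for d in DIAGNOSTICS if d not in ("hierarchy", "assortativity")
)


@dataclass
class DiagnosticsConfig:
    """Tunable evaluation settings (defaults match the analysis design)."""

    modularity_restarts: int = 10
    n_attack_orders: int = 20
    rent_boxes: int = 5000
    rent_min_boxes: int = 30
    synchronizability: str = "ratio"  # 'ratio' = lam2/lam_max; 'eigratio' inverse
    wavelet: str = "d4"


def _adj(a) -> np.ndarray:
    if isinstance(a, BinaryNetwork):
        return a.adjacency
    return np.asarray(a, dtype=bool)


def _degrees(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1).astype(int)


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest paths via boolean matrix BFS.

    Dense-matrix breadth-first expansion beats sparse-graph routines on
    the small, dense graphs this pipeline produces.
    """
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj] = 1.0
    reach = adj | np.eye(n, dtype=bool)
    k = 1
    while True:
        new_reach = (reach.astype(np.uint8) @ adj.astype(np.uint8)) > 0
        new_reach |= reach
        newly = new_reach & ~reach
        if not newly.any():
            return d
        k += 1
        d[newly] = k
        reach = new_reach


def _component_labels(adj: np.ndarray) -> np.ndarray:
    """Connected-component label per node (dense BFS)."""
    n = adj.shape[0]
    labels = np.full(n, -1, dtype=int)
    current = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        member = np.zeros(n, dtype=bool)
        member[start] = True
        frontier = member.copy()
        while frontier.any():
            nxt = adj[frontier].any(axis=0) & ~member
            member |= nxt
            frontier = nxt
        labels[member] = current
        current += 1
    return labels


def _local_clustering(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(float)
    tri = np.einsum("ij,jk,ki->i", a, a, a)
    k = _degrees(adj)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return c


def _global_efficiency_from_dist(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def betweenness_centrality(a) -> np.ndarray:
    """Normalized betweenness via Brandes' algorithm (unweighted).

    Normalization divides each node's value by (n-1)(n-2)/2 so a star
    hub scores 1, matching the usual undirected convention.
    """
    adj = _adj(a)
    n = adj.shape[0]
    nbrs = [np.flatnonzero(adj[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair counted twice
    if n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def basic_metrics(a) -> dict[str, float]:
    """L, C, E_glob, E_loc, mean betweenness, and assortativity.

    Requires at least one edge. Assortativity is NaN when the degree
    variance over edge endpoints is zero (regular graphs).
    """
    adj = _adj(a)
    n = adj.shape[0]
    if adj.sum() == 0:
        raise ValueError("graph has no edges")
    d = _distance_matrix(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    path_length = float(d[finite].mean()) if finite.any() else np.nan
    e_glob = _global_efficiency_from_dist(d)
    c = _local_clustering(adj)
    # local efficiency: global efficiency of each neighborhood subgraph
    e_loc_terms = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        e_loc_terms[i] = _global_efficiency_from_dist(_distance_matrix(sub))
    bc = betweenness_centrality(adj)
    # degree-degree Pearson correlation over edge endpoint pairs
    iu, ju = np.nonzero(np.triu(adj, k=1))
    k = _degrees(adj)
    x = np.concatenate([k[iu], k[ju]]).astype(float)
    y = np.concatenate([k[ju], k[iu]]).astype(float)
    if x.std() == 0 or y.std() == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return {
        "path_length": path_length,
        "clustering": float(c.mean()),
        "global_efficiency": e_glob,
        "local_efficiency": float(e_loc_terms.mean()),
        "betweenness": float(bc.mean()),
        "assortativity": r,
    }


def _partition_q(adj: np.ndarray, labels: np.ndarray) -> float:
    m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    k = _degrees(adj).astype(float)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = adj[np.ix_(mask, mask)].sum() / 2.0
        d_c = k[mask].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def _greedy_partition(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """CNM-style agglomeration with randomized tie-breaking."""
    n = adj.shape[0]
    m = adj.sum() / 2.0
    labels = np.arange(n)
    if m == 0:
        return labels
    # community-level edge fractions and degree fractions
    comms = list(range(n))
    e = adj.astype(float) / (2.0 * m)
    a = _degrees(adj) / (2.0 * m)
    e = e.copy()
    a = a.astype(float).copy()
    alive = np.ones(n, dtype=bool)
    while alive.sum() > 1:
        idx = np.flatnonzero(alive)
        ee = e[np.ix_(idx, idx)]
        aa = a[idx]
        dq = 2.0 * (ee - np.outer(aa, aa))
        np.fill_diagonal(dq, -np.inf)
        dq = dq + rng.uniform(0, 1e-12, dq.shape)  # random tie-break
        best = np.unravel_index(np.argmax(dq), dq.shape)
        if dq[best] <= 0:
            break
        u, v = idx[best[0]], idx[best[1]]
        e[u, :] += e[v, :]
        e[:, u] += e[:, v]
        e[u, u] += 0.0
        a[u] += a[v]
        alive[v] = False
        labels[labels == labels[v]] = labels[u]
    return labels


def _refine_partition(
    adj: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Single-node moves to any community (or a new one) until no gain.

    Move gains are evaluated incrementally: relocating node i (degree
    k_i) from community c to d changes Q by
    ``(k_id - k_ic') / m - k_i (dtot_d - dtot_c') / (2 m^2)`` where c' is
    c without i, k_iX counts edges from i into X, and dtot_X is the total
    degree of X.
    """
    labels = np.unique(labels, return_inverse=True)[1]
    n = adj.shape[0]
    k = _degrees(adj).astype(float)
    m = adj.sum() / 2.0
    n_lab = n + 1  # reserve room for fresh singleton communities
    dtot = np.zeros(2 * n_lab)
    np.add.at(dtot, labels, k)
    nbrs = [np.flatnonzero(adj[i]) for i in range(n)]
    improved = True
    guard = 0
    while improved and guard < 50:
        improved = False
        guard += 1
        for i in rng.permutation(n):
            c = labels[i]
            nb_labels = labels[nbrs[i]]
            k_ic = float(np.count_nonzero(nb_labels == c))
            dtot_c_wo = dtot[c] - k[i]
            base_loss = -k_ic / m + k[i] * dtot_c_wo / (2.0 * m * m)
            cand = np.unique(nb_labels)
            best_gain, best_d = 0.0, c
            for d in cand:
                if d == c:
                    continue
                k_id = float(np.count_nonzero(nb_labels == d))
                gain = base_loss + k_id / m - k[i] * dtot[d] / (2.0 * m * m)
                if gain > best_gain + 1e-12:
                    best_gain, best_d = gain, d
            # moving to a fresh singleton community
            gain = base_loss
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_d = int(np.max(labels)) + 1
                if best_d >= dtot.size:
                    dtot = np.concatenate([dtot, np.zeros(n_lab)])
            if best_d != c:
                dtot[c] -= k[i]
                dtot[best_d] += k[i]
                labels[i] = best_d
                improved = True
    return labels


def _merge_communities(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Merge community pairs while any merge increases Q."""
    labels = np.unique(labels, return_inverse=True)[1]
    m = adj.sum() / 2.0
    improved = True
    while improved and np.max(labels) > 0:
        improved = False
        n_c = int(np.max(labels)) + 1
        onehot = labels[:, None] == np.arange(n_c)[None, :]
        e = onehot.T.astype(float) @ adj @ onehot.astype(float) / (2.0 * m)
        a_frac = (_degrees(adj) @ onehot) / (2.0 * m)
        dq = 2.0 * (e - np.outer(a_frac, a_frac))
        np.fill_diagonal(dq, -np.inf)
        u, v = np.unravel_index(np.argmax(dq), dq.shape)
        if dq[u, v] > 1e-12:
            labels[labels == v] = u
            labels = np.unique(labels, return_inverse=True)[1]
            improved = True
    return labels


def modularity(a, seed: int = 0, restarts: int = 10) -> float:
    """Newman modularity Q of the best partition found.

    Greedy agglomerative optimization followed by alternating single-node
    moves and community-pair merges until neither improves, restarted
    ``restarts`` times with seeded random tie-breaking; the best Q is
    reported. Empty graphs give NaN.
    """
    adj = _adj(a)
    if adj.sum() == 0:
        return np.nan
    rng = np.random.default_rng(seed)
    best = -np.inf
    for start in range(max(restarts, 1)):
        if start % 2 == 0:
            labels = _greedy_partition(adj, rng)
        else:
            labels = np.arange(adj.shape[0])  # singleton start
        for _ in range(10):
            q0 = _partition_q(adj, labels)
            labels = _refine_partition(adj, labels, rng)
            labels = _merge_communities(adj, labels)
            if _partition_q(adj, labels) <= q0 + 1e-12:
                break
        best = max(best, _partition_q(adj, labels))
    return float(best)


def hierarchy_exponent(a) -> float:
    """beta = -slope of log mean clustering vs log degree over degree classes.

    Uses degree classes with k >= 2 and positive mean clustering. A
    single usable class (e.g. a k-regular graph) has a flat profile and
    returns 0; no usable class returns NaN.
    """
    adj = _adj(a)
    k = _degrees(adj)
    c = _local_clustering(adj)
    ks, cs = [], []
    for kk in np.unique(k):
        if kk < 2:
            continue
        mean_c = c[k == kk].mean()
        if mean_c > 0:
            ks.append(kk)
            cs.append(mean_c)
    if not ks:
        return np.nan
    if len(ks) == 1:
        return 0.0
    slope = np.polyfit(np.log(ks), np.log(cs), 1)[0]
    return float(-slope)


def synchronizability(a, convention: str = "ratio") -> float:
    """Laplacian spectral ratio of the largest connected component.

    'ratio' (default): lambda_2 / lambda_max, in (0, 1], higher = more
    synchronizable. 'eigratio': the reciprocal lambda_max / lambda_2.
    NaN when the largest component has fewer than 3 nodes.
    """
    adj = _adj(a)
    comp = _component_labels(adj)
    sizes = np.bincount(comp)
    giant = np.argmax(sizes)
    if sizes[giant] < 3:
        return np.nan
    mask = comp == giant
    sub = adj[np.ix_(mask, mask)].astype(float)
    lap = np.diag(sub.sum(axis=1)) - sub
    eig = eigvalsh(lap)
    lam2, lam_max = eig[1], eig[-1]
    if convention == "ratio":
        return float(lam2 / lam_max)
    if convention == "eigratio":
        return float(lam_max / lam2) if lam2 > 0 else np.nan
    raise ValueError(f"unknown synchronizability convention {convention!r}")


def _largest_cc_fraction(rows: list[int], active: int, n: int) -> float:
    """Largest connected component among ``active`` bitmask nodes."""
    best = 0
    remaining = active
    while remaining:
        seed_bit = remaining & -remaining
        comp = seed_bit
        frontier = seed_bit
        while frontier:
            nxt = 0
            f = frontier
            while f:
                b = f & -f
                f ^= b
                nxt |= rows[b.bit_length() - 1]
            nxt &= active & ~comp
            comp |= nxt
            frontier = nxt
        best = max(best, bin(comp).count("1"))
        remaining &= ~comp
    return best / n


def _attack_curve(adj: np.ndarray, order: np.ndarray) -> float:
    """Mean largest-CC fraction over removal steps 0..N-1 (the attack AUC)."""
    n = adj.shape[0]
    rows = []
    for i in range(n):
        v = 0
        for j in np.flatnonzero(adj[i]):
            v |= 1 << int(j)
        rows.append(v)
    active = (1 << n) - 1
    total = _largest_cc_fraction(rows, active, n)
    for step in range(n - 1):
        active &= ~(1 << int(order[step]))
        total += _largest_cc_fraction(rows, active, n)
    return total / n


def robustness(
    a, mode: str, seed: int = 0, n_orders: int = 20
) -> float:
    """Attack-tolerance AUC in [0, 1].

    Nodes are removed one at a time; the largest-component fraction is
    recorded intact and after each of the first N-1 removals, and the AUC
    is the mean of those N values. 'targeted' removes the highest-degree
    node at each step (ties by lowest index, degrees recomputed);
    'random' averages the AUC over ``n_orders`` seeded uniform removal
    orders.
    """
    adj = _adj(a)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if mode == "targeted":
        order = np.empty(n - 1, dtype=int)
        work = adj.copy()
        active = np.ones(n, dtype=bool)
        for step in range(n - 1):
            deg = work.sum(axis=1)
            deg[~active] = -1
            victim = int(np.argmax(deg))  # argmax takes the lowest index on ties
            order[step] = victim
            active[victim] = False
            work[victim, :] = False
            work[:, victim] = False
        return _attack_curve(adj, order)
    if mode == "random":
        rng = np.random.default_rng(seed)
        aucs = [
            _attack_curve(adj, rng.permutation(n)[: n - 1])
            for _ in range(n_orders)
        ]
        return float(np.mean(aucs))
    raise ValueError(f"unknown attack mode {mode!r}")


def mean_connection_distance(a, layout: SensorLayout | np.ndarray) -> float:
    """Mean Euclidean layout distance between the endpoints of all edges."""
    adj = _adj(a)
    pos = layout.positions if isinstance(layout, SensorLayout) else np.asarray(layout, float)
    if pos.shape[0] != adj.shape[0]:
        raise ValueError("layout does not cover all nodes")
    iu, ju = np.nonzero(np.triu(adj, k=1))
    if iu.size == 0:
        raise ValueError("graph has no edges")
    d = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    return float(d.mean())


def rent_exponent(
    a,
    layout: SensorLayout | np.ndarray,
    n_boxes: int = 5000,
    seed: int = 0,
    min_boxes: int = 30,
) -> float:
    """Physical Rent's exponent of the spatially embedded network.

    Random axis-aligned boxes are sampled inside the layout's bounding
    volume (in the layout's native dimensionality); for each box with
    2 <= nodes inside <= N/2 and at least one boundary-crossing edge, the
    (log nodes, log crossing edges) pair enters a least-squares fit whose
    slope is the exponent. NaN when fewer than ``min_boxes`` usable boxes
    are found.
    """
    adj = _adj(a)
    n = adj.shape[0]
    if n < 8 or adj.sum() // 2 < 8:
        raise ValueError("need at least 8 nodes and 8 edges")
    pos = layout.positions if isinstance(layout, SensorLayout) else np.asarray(layout, float)
    rng = np.random.default_rng(seed)
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    active_dims = np.flatnonzero(hi - lo > 0)
    p = pos[:, active_dims]
    span = (hi - lo)[active_dims]
    # Random half-widths spanning box scales from a few nodes up to half
    # the layout, with centres drawn so every box lies inside the bounding
    # volume: boxes spilling past the hull would under-count boundary
    # edges and bias the fitted exponent downward.
    half = rng.uniform(0.05, 0.5, size=(n_boxes, active_dims.size)) * span
    centers = lo[active_dims] + half + rng.random(
        (n_boxes, active_dims.size)
    ) * (span - 2 * half)
    box_lo = centers - half
    box_hi = centers + half
    inside = np.all(
        (p[None, :, :] >= box_lo[:, None, :]) & (p[None, :, :] <= box_hi[:, None, :]),
        axis=2,
    )  # (n_boxes, n)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    crossing = (inside[:, iu] ^ inside[:, ju]).sum(axis=1)
    n_in = inside.sum(axis=1)
    usable = (n_in >= 2) & (n_in <= n // 2) & (crossing >= 1)
    if usable.sum() < min_boxes:
        return np.nan
    slope = np.polyfit(np.log(n_in[usable]), np.log(crossing[usable]), 1)[0]
    return float(slope)


@dataclass
class CostEfficiencyResult:
    """Maximum of the efficiency-minus-cost curve and its argmax cost."""

    cost_efficiency: float
    optimal_cost: float


def cost_efficiency(
    e_glob: np.ndarray, costs: np.ndarray
) -> CostEfficiencyResult:
    """CE = max over the grid of E_glob(kappa) - kappa (ties: smallest kappa)."""
    e = np.asarray(e_glob, dtype=float)
    k = np.asarray(costs, dtype=float)
    diff = e - k
    if np.all(np.isnan(diff)):
        return CostEfficiencyResult(np.nan, np.nan)
    order = np.argsort(k, kind="stable")
    diff_o, k_o = diff[order], k[order]
    best = np.nanmax(diff_o)
    idx = int(np.nanargmax(diff_o >= best - 1e-15))
    return CostEfficiencyResult(float(best), float(k_o[idx]))


def all_diagnostics(
    net: BinaryNetwork | np.ndarray,
    layout: SensorLayout | np.ndarray | None,
    seed: int = 0,
    config: DiagnosticsConfig | None = None,
    names: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Diagnostics (plus path length) for one binary network.

    ``names`` restricts the computation to a subset; everything requested
    whose preconditions fail is NaN. ``layout`` may be None when no
    physical diagnostic is requested.
    """
    cfg = config or DiagnosticsConfig()
    adj = _adj(net)
    wanted = tuple(names) if names is not None else DIAGNOSTICS + ("path_length",)
    out = {d: np.nan for d in wanted}
    if adj.sum() == 0:
        return out
    topo = {
        "path_length",
        "clustering",
        "global_efficiency",
        "local_efficiency",
        "betweenness",
        "assortativity",
    }
    if topo & set(wanted):
        d = _distance_matrix(adj)
        n = adj.shape[0]
        off = ~np.eye(n, dtype=bool)
        if "path_length" in wanted:
            finite = np.isfinite(d) & off
            out["path_length"] = float(d[finite].mean()) if finite.any() else np.nan
        if "global_efficiency" in wanted:
            out["global_efficiency"] = _global_efficiency_from_dist(d)
        if "clustering" in wanted:
            out["clustering"] = float(_local_clustering(adj).mean())
        if "local_efficiency" in wanted:
            terms = np.zeros(n)
            for i in range(n):
                nb = np.flatnonzero(adj[i])
                if nb.size >= 2:
                    sub = adj[np.ix_(nb, nb)]
                    terms[i] = _global_efficiency_from_dist(_distance_matrix(sub))
            out["local_efficiency"] = float(terms.mean())
        if "betweenness" in wanted:
            out["betweenness"] = float(betweenness_centrality(adj).mean())
        if "assortativity" in wanted:
            iu, ju = np.nonzero(np.triu(adj, k=1))
            k = _degrees(adj)
            x = np.concatenate([k[iu], k[ju]]).astype(float)
            y = np.concatenate([k[ju], k[iu]]).astype(float)
            out["assortativity"] = (
                np.nan if x.std() == 0 else float(np.corrcoef(x, y)[0, 1])
            )
    if "modularity" in wanted:
        out["modularity"] = modularity(
            adj, seed=seed, restarts=cfg.modularity_restarts
        )
    if "hierarchy" in wanted:
        out["hierarchy"] = hierarchy_exponent(adj)
    if "synchronizability" in wanted:
        out["synchronizability"] = synchronizability(adj, cfg.synchronizability)
    if "robustness_targeted" in wanted:
        out["robustness_targeted"] = robustness(adj, "targeted")
    if "robustness_random" in wanted:
        out["robustness_random"] = robustness(
            adj, "random", seed=seed, n_orders=cfg.n_attack_orders
        )
    if "mean_connection_distance" in wanted:
        try:
            out["mean_connection_distance"] = mean_connection_distance(adj, layout)
        except ValueError:
            pass
    if "rent_exponent" in wanted:
        try:
            out["rent_exponent"] = rent_exponent(
                adj, layout, n_boxes=cfg.rent_boxes, seed=seed,
                min_boxes=cfg.rent_min_boxes,
            )
        except ValueError:
            pass
    return out


def evaluate_ensembles(
    trial_ensembles: list[NetworkEnsemble],
    layout: SensorLayout | np.ndarray | None,
    seed: int = 0,
    config: DiagnosticsConfig | None = None,
    names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Diagnostics for every (trial, cost) network of one network kind.

    Returns an array (n_diagnostics, n_trials, n_costs), rows following
    ``names`` (default :data:`DIAGNOSTICS`). Random streams are keyed by
    (trial, cost) so results do not depend on evaluation order.
    """
    cfg = config or DiagnosticsConfig()
    if names is None:
        names = DIAGNOSTICS
    n_trials = len(trial_ensembles)
    n_costs = len(trial_ensembles[0].costs)
    values = np.full((len(names), n_trials, n_costs), np.nan)
    for t, ens in enumerate(trial_ensembles):
        for c, net in enumerate(ens.networks):
            d = all_diagnostics(
                net, layout, seed=seed * 1_000_003 + t * 101 + c,
                config=cfg, names=names,
            )
            for k, name in enumerate(names):
                values[k, t, c] = d[name]
    return values
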