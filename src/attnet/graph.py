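"""Binary-graph topology: cost thresholding, efficiency metrics, matched
null models, the small-world regime, and the truncated power-law degree fit.

A connectivity matrix is binarized at a *cost* — the fraction of the
N(N-1)/2 possible edges retained — by keeping the strongest correlations.
All topology metrics operate on the resulting undirected, unweighted
graph. Efficiency follows the Latora-Marchiori convention: disconnected
pairs contribute 0 (the 1/infinity limit), and neighbour subgraphs with
fewer than two nodes have local efficiency 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "BinaryGraph",
    "CostProfile",
    "SmallWorldRegime",
    "DegreeFitResult",
    "threshold_at_cost",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "degree",
    "betweenness_centrality",
    "matched_random_graph",
    "matched_regular_graph",
    "small_world_regime",
    "cost_profile",
    "fit_truncated_power_law",
]

#: Methods-section grid for the global efficiency curves.
COST_GRID_GLOBAL = np.round(np.arange(0.10, 0.50 + 1e-9, 0.01), 2)
#: Small-world-regime grid used for hub metrics and nodal averaging.
COST_GRID_HUBS = np.round(np.arange(0.05, 0.30 + 1e-9, 0.01), 2)


@dataclass
class BinaryGraph:
    """Undirected unweighted graph over labelled nodes (boolean adjacency)."""

    node_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        a = np.asarray(self.adjacency, dtype=bool)
        n = len(self.node_ids)
        if a.shape != (n, n):
            raise ValueError("adjacency shape must match node count")
        if not (a == a.T).all():
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def cost(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu, ju]
        return list(zip(iu[keep].tolist(), ju[keep].tolist()))

    def degree_sequence(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, node_ids: list[str] | None = None) -> "BinaryGraph":
        nodes = sorted(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        adj = np.zeros((n, n), dtype=bool)
        for u, v in g.edges():
            adj[index[u], index[v]] = adj[index[v], index[u]] = True
        ids = node_ids if node_ids is not None else [str(v) for v in nodes]
        return cls(ids, adj)


@dataclass
class CostProfile:
    """Global metrics evaluated over a cost grid for one graph source."""

    costs: np.ndarray
    e_global: np.ndarray
    e_local: np.ndarray
    e_global_random: np.ndarray | None = None
    e_local_random: np.ndarray | None = None
    e_global_regular: np.ndarray | None = None
    e_local_regular: np.ndarray | None = None
    tag: str | None = None


@dataclass
class SmallWorldRegime:
    """Maximal contiguous cost interval where both small-world criteria hold."""

    lo: float | None
    hi: float | None
    costs: np.ndarray
    passes: np.ndarray  # bool per cost
    profile: CostProfile | None = None

    @property
    def empty(self) -> bool:
        return self.lo is None


@dataclass
class DegreeFitResult:
    """Exponentially truncated power-law fit P(k) ~ k^(alpha-1) exp(-k/kc)."""

    alpha: float
    kc: float
    loss: float
    converged: bool
    n: int = 0
    k_max: int = 0
    message: str = ""


def threshold_at_cost(conn: ConnectivityMatrix, cost: float) -> BinaryGraph:
    """Binarize a connectivity matrix at a target cost.

    Keeps the ``K = round(cost * N(N-1)/2)`` strongest |r| entries
    (round half away from zero). Ties are broken by lexicographic (i, j)
    order so that edge sets nest as cost grows. Undefined (NaN) entries
    ranked into the top K raise an error naming the pairs.
    """
    if not 0 < cost <= 1:
        raise ValueError("cost must lie in (0, 1]")
    n = conn.n_nodes
    n_pairs = n * (n - 1) // 2
    k = int(np.floor(cost * n_pairs + 0.5))  # round half away from zero (values >= 0)
    iu, ju = np.triu_indices(n, k=1)
    vals = conn.values[iu, ju]
    # sort by value descending, ties by (i, j) ascending; NaNs sink to the end
    order = np.lexsort((ju, iu, -np.nan_to_num(vals, nan=-np.inf)))
    top = order[:k]
    if np.isnan(vals[top]).any():
        bad = [
            (conn.node_ids[iu[t]], conn.node_ids[ju[t]])
            for t in top
            if np.isnan(vals[t])
        ]
        raise ValueError(f"undefined connectivity entries in the top-{k}: {bad}")
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[top], ju[top]] = True
    adj |= adj.T
    return BinaryGraph(conn.node_ids, adj)


def _inverse_distances(adj: np.ndarray) -> np.ndarray:
    """Matrix of 1/l_ij from BFS shortest paths; 0 for disconnected pairs and i=j."""
    n = adj.shape[0]
    if adj.sum() == 0:
        return np.zeros((n, n))
    d = shortest_path(csr_matrix(adj.astype(np.int8)), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def _global_efficiency_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    return float(_inverse_distances(adj).sum() / (n * (n - 1)))


def global_efficiency(g: BinaryGraph) -> float:
    """E_glob: mean inverse shortest-path length over ordered node pairs."""
    return _global_efficiency_adj(g.adjacency)


def local_efficiency(g: BinaryGraph) -> float:
    """E_loc: mean over nodes of E_glob of each neighbour-induced subgraph."""
    adj = g.adjacency
    n = g.n_nodes
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        total += _global_efficiency_adj(adj[np.ix_(nb, nb)])
    return total / n


def nodal_efficiency(g: BinaryGraph) -> np.ndarray:
    """E_nodal per node: mean inverse distance to every other node."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return _inverse_distances(g.adjacency).sum(axis=1) / (n - 1)


def degree(g: BinaryGraph) -> np.ndarray:
    """Number of edges incident to each node."""
    return g.degree_sequence()


def betweenness_centrality(g: BinaryGraph) -> np.ndarray:
    """Brandes betweenness centrality, normalized by (N-1)(N-2)/2, endpoints excluded."""
    if g.n_nodes < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=True)
    return np.array([bc[i] for i in range(g.n_nodes)])


def matched_random_graph(
    g: BinaryGraph, n_swap_attempts: int | None = None, seed: int | None = None
) -> BinaryGraph:
    """Degree-preserving random rewiring via double-edge swaps.

    Preserves the exact degree sequence (hence N and K); the target is
    ``10 * K`` successful swaps by default. Failed swap attempts are
    skipped, so sparse or constrained graphs simply randomize less.
    """
    k = g.n_edges
    if k < 2:
        return BinaryGraph(g.node_ids, g.adjacency.copy())
    nswap = n_swap_attempts if n_swap_attempts is not None else 10 * k
    gx = g.to_networkx()
    try:
        nx.double_edge_swap(gx, nswap=nswap, max_tries=max(100 * nswap, 1000), seed=seed)
    except nx.NetworkXAlgorithmError:
        pass  # swap budget exhausted; keep whatever randomization was achieved
    except nx.NetworkXError:
        return BinaryGraph(g.node_ids, g.adjacency.copy())
    return BinaryGraph.from_networkx(gx, g.node_ids)


def matched_regular_graph(g: BinaryGraph) -> BinaryGraph:
    """Ring-lattice null with the same N and K.

    Edges fill successive neighbour offsets 1, 2, ... around the ring;
    leftover edges at the last partially-filled offset are assigned to
    nodes 0, 1, ... deterministically, keeping degrees as uniform as K
    permits.
    """
    n, k = g.n_nodes, g.n_edges
    adj = np.zeros((n, n), dtype=bool)
    remaining = k
    offset = 1
    while remaining > 0 and offset <= n // 2:
        ring_capacity = n if (2 * offset != n) else n // 2
        take = min(remaining, ring_capacity)
        for start in range(take):
            a, b = start, (start + offset) % n
            adj[a, b] = adj[b, a] = True
        remaining -= take
        offset += 1
    if remaining > 0:
        raise ValueError(f"cannot place {k} edges on {n} nodes as a ring lattice")
    return BinaryGraph(g.node_ids, adj)


def cost_profile(
    conn: ConnectivityMatrix,
    grid: np.ndarray = COST_GRID_GLOBAL,
    n_null: int = 0,
    seed: int | None = None,
    tag: str | None = None,
) -> CostProfile:
    """E_glob / E_loc across a cost grid, optionally with matched-null curves.

    With ``n_null > 0`` each cost also gets the ensemble-mean efficiencies
    of degree-matched random rewirings and the matched ring lattice.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or (np.diff(grid) <= 0).any():
        raise ValueError("cost grid must be non-empty and strictly increasing")
    rng = np.random.default_rng(seed)
    eg, el = np.zeros(grid.size), np.zeros(grid.size)
    eg_rand = np.zeros(grid.size) if n_null else None
    el_rand = np.zeros(grid.size) if n_null else None
    eg_reg = np.zeros(grid.size) if n_null else None
    el_reg = np.zeros(grid.size) if n_null else None
    for idx, c in enumerate(grid):
        g = threshold_at_cost(conn, float(c))
        eg[idx] = global_efficiency(g)
        el[idx] = local_efficiency(g)
        if n_null:
            reg = matched_regular_graph(g)
            eg_reg[idx] = global_efficiency(reg)
            el_reg[idx] = local_efficiency(reg)
            egs, els = [], []
            for _ in range(n_null):
                rnd = matched_random_graph(g, seed=int(rng.integers(2**31)))
                egs.append(global_efficiency(rnd))
                els.append(local_efficiency(rnd))
            eg_rand[idx] = float(np.mean(egs))
            el_rand[idx] = float(np.mean(els))
    return CostProfile(grid, eg, el, eg_rand, el_rand, eg_reg, el_reg, tag)


def small_world_regime(
    conn: ConnectivityMatrix,
    grid: np.ndarray = COST_GRID_HUBS,
    n_null: int = 20,
    seed: int | None = None,
) -> SmallWorldRegime:
    """Detect the small-world cost regime of a connectivity matrix.

    At each cost the graph must satisfy both criteria against matched
    nulls: E_glob(regular) < E_glob(G) < E_glob(random) and
    E_loc(random) < E_loc(G) < E_loc(regular), random-null values being
    ensemble means over ``n_null`` degree-matched rewirings. The regime is
    the longest contiguous run of passing costs.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    prof = cost_profile(conn, grid, n_null=n_null, seed=seed)
    passes = (
        (prof.e_global_regular < prof.e_global)
        & (prof.e_global < prof.e_global_random)
        & (prof.e_local_random < prof.e_local)
        & (prof.e_local < prof.e_local_regular)
    )
    lo = hi = None
    best_len, run_start = 0, None
    for i, ok in enumerate(list(passes) + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start > best_len:
                best_len = i - run_start
                lo, hi = float(prof.costs[run_start]), float(prof.costs[i - 1])
            run_start = None
    return SmallWorldRegime(lo, hi, prof.costs, passes, prof)


def _truncated_power_pmf(alpha: float, kc: float, k_max: int) -> np.ndarray:
    k = np.arange(1, k_max + 1, dtype=float)
    logw = (alpha - 1.0) * np.log(k) - k / kc
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def fit_truncated_power_law(
    degrees: np.ndarray,
    k_max: int | None = None,
    method: str = "mle",
) -> DegreeFitResult:
    """Fit P(k) ~ k^(alpha-1) exp(-k/kc) to positive degree counts.

    ``method="mle"`` (default) maximizes the discrete likelihood with the
    distribution normalized over k in [1, k_max]; ``method="ccdf_ls"`` is
    a least-squares fit to the empirical log-CCDF, offered as a
    cross-check. Degenerate inputs (all degrees equal) are flagged as
    non-converged rather than raising.
    """
    ks = np.asarray(degrees, dtype=int)
    ks = ks[ks > 0]
    if ks.size < 10:
        raise ValueError("need at least 10 positive degrees")
    kmax = int(k_max) if k_max is not None else int(ks.max())
    if np.ptp(ks) == 0:
        return DegreeFitResult(
            np.nan, np.nan, np.nan, False, ks.size, kmax, "degenerate: all degrees equal"
        )
    counts = np.bincount(ks, minlength=kmax + 1)[1:].astype(float)

    if method == "mle":

        def nll(theta: np.ndarray) -> float:
            alpha, log_kc = theta
            pmf = _truncated_power_pmf(alpha, np.exp(log_kc), kmax)
            return -float(counts @ np.log(pmf + 1e-300))

        res = optimize.minimize(
            nll,
            x0=np.array([1.5, np.log(max(ks.mean(), 1.5))]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        alpha, kc = float(res.x[0]), float(np.exp(res.x[1]))
        return DegreeFitResult(
            alpha, kc, float(res.fun), bool(res.success), ks.size, kmax, res.message
        )

    if method == "ccdf_ls":
        emp_ccdf = counts[::-1].cumsum()[::-1] / counts.sum()
        # only bins with solid empirical support; the deep tail is pure noise
        mask = emp_ccdf >= max(5.0 / counts.sum(), 1e-12)

        def loss(theta: np.ndarray) -> float:
            alpha, log_kc = theta
            pmf = _truncated_power_pmf(alpha, np.exp(log_kc), kmax)
            ccdf = pmf[::-1].cumsum()[::-1]
            return float(
                np.sum((np.log(ccdf[mask] + 1e-300) - np.log(emp_ccdf[mask])) ** 2)
            )

        res = optimize.minimize(
            loss,
            x0=np.array([1.5, np.log(max(ks.mean(), 1.5))]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        alpha, kc = float(res.x[0]), float(np.exp(res.x[1]))
        return DegreeFitResult(
            alpha, kc, float(res.fun), bool(res.success), ks.size, kmax, res.message
        )

    raise ValueError(f"unknown method {method!r}")
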