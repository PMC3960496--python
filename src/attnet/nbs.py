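"""Network-based statistic (NBS): permutation FWE control over connected
components of suprathreshold edge-wise group differences.

The procedure, for two groups of subject-level connectivity matrices:

1. take each subject's |r| value on every distinct node pair;
2. compute a two-sample pooled-variance t statistic per pair;
3. keep pairs whose t exceeds a primary threshold (default 3.5) in the
   requested direction;
4. find connected components among the surviving edges;
5. re-run steps 2-4 under random relabelings of subjects to build the
   null distribution of the largest component's extent;
6. assign each observed component the FWE-corrected p: the proportion of
   permutations whose maximal extent reaches its extent.

Component *extent* is the edge count by default; node count is available
as an option. The permutation core is vectorized: group sums and sums of
squares for every permutation come from two matrix products against the
subjects-by-edges data matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "EdgeStatMatrix",
    "Component",
    "NbsResult",
    "edgewise_t",
    "suprathreshold_components",
    "nbs_permutation",
]

DEFAULT_T_THRESHOLD = 3.5
DEFAULT_N_PERM = 10000
DEFAULT_ALPHA = 0.05


@dataclass
class EdgeStatMatrix:
    """Symmetric per-edge two-sample t statistics."""

    node_ids: list[str]
    t: np.ndarray  # (n, n), symmetric, NaN where pooled variance is zero
    df: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def undefined_edges(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        bad = np.isnan(self.t[iu, ju])
        return [(self.node_ids[i], self.node_ids[j]) for i, j in zip(iu[bad], ju[bad])]


@dataclass
class Component:
    """One suprathreshold connected component."""

    edges: list[tuple[int, int]]
    nodes: list[int]
    extent: int  # edge count (or node count if extent="nodes")
    p_fwe: float | None = None


@dataclass
class NbsResult:
    node_ids: list[str]
    components: list[Component]
    null_max_extent: np.ndarray
    n_permutations: int
    t_threshold: float
    direction: str
    seed: int | None
    extent: str = "edges"
    alpha: float = DEFAULT_ALPHA
    warnings: list[str] = field(default_factory=list)

    def significant_components(self) -> list[Component]:
        return [c for c in self.components if c.p_fwe is not None and c.p_fwe < self.alpha]


def _stack_upper(mats: list[ConnectivityMatrix]) -> tuple[np.ndarray, list[str]]:
    if not mats:
        raise ValueError("empty group")
    ids = mats[0].node_ids
    for m in mats:
        if m.node_ids != ids:
            raise ValueError("all matrices must share the same node ids")
    x = np.vstack([m.upper_values() for m in mats])
    return x, list(ids)


def _pooled_t_batched(
    x: np.ndarray, members_a: np.ndarray, n_a: int, n_b: int
) -> np.ndarray:
    """Pooled-variance t for many group assignments at once.

    ``x`` is subjects x edges; ``members_a`` is assignments x subjects
    (boolean, True = group A). Returns assignments x edges t values,
    NaN where the pooled variance vanishes.
    """
    m = members_a.astype(float)
    tot = x.sum(axis=0)
    tot2 = (x**2).sum(axis=0)
    sum_a = m @ x
    sum2_a = m @ (x**2)
    sum_b = tot - sum_a
    sum2_b = tot2 - sum2_a
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sum2_a - n_a * mean_a**2
    ss_b = sum2_b - n_b * mean_b**2
    df = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss_a + ss_b) / df
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        t = (mean_a - mean_b) / se
    t[~np.isfinite(t)] = np.nan
    return t


def edgewise_t(
    group_a: list[ConnectivityMatrix], group_b: list[ConnectivityMatrix]
) -> EdgeStatMatrix:
    """Two-sample pooled-variance t per node pair (group A minus group B).

    df = n_a + n_b - 2. Edges with zero pooled variance are NaN and
    reported through :meth:`EdgeStatMatrix.undefined_edges`.
    """
    xa, ids = _stack_upper(group_a)
    xb, ids_b = _stack_upper(group_b)
    if ids != ids_b:
        raise ValueError("groups must share node ids")
    n_a, n_b = xa.shape[0], xb.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 subjects")
    x = np.vstack([xa, xb])
    members = np.zeros((1, n_a + n_b), dtype=bool)
    members[0, :n_a] = True
    tvec = _pooled_t_batched(x, members, n_a, n_b)[0]
    n = len(ids)
    t = np.full((n, n), np.nan)
    iu, ju = np.triu_indices(n, k=1)
    t[iu, ju] = tvec
    t[ju, iu] = tvec
    np.fill_diagonal(t, np.nan)
    return EdgeStatMatrix(ids, t, n_a + n_b - 2)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _components_from_edges(
    edge_nodes: np.ndarray, n_nodes: int
) -> list[tuple[list[tuple[int, int]], list[int]]]:
    """Connected components of a graph given as an (m, 2) edge-node array."""
    if edge_nodes.shape[0] == 0:
        return []
    uf = _UnionFind(n_nodes)
    for a, b in edge_nodes:
        uf.union(int(a), int(b))
    groups: dict[int, list[tuple[int, int]]] = {}
    for a, b in edge_nodes:
        groups.setdefault(uf.find(int(a)), []).append((int(a), int(b)))
    out = []
    for edges in groups.values():
        nodes = sorted({v for e in edges for v in e})
        out.append((sorted(edges), nodes))
    return out


def suprathreshold_components(
    stats: EdgeStatMatrix,
    t_threshold: float = DEFAULT_T_THRESHOLD,
    direction: str = "a_gt_b",
    extent: str = "edges",
) -> list[Component]:
    """Maximal connected components among edges beyond the primary threshold.

    ``direction="a_gt_b"`` keeps edges with t > threshold (group A larger);
    ``"b_gt_a"`` keeps t < -threshold. Extent counts edges by default.
    """
    if t_threshold <= 0:
        raise ValueError("t threshold must be positive")
    if direction not in ("a_gt_b", "b_gt_a"):
        raise ValueError("direction must be 'a_gt_b' or 'b_gt_a'")
    if extent not in ("edges", "nodes"):
        raise ValueError("extent must be 'edges' or 'nodes'")
    signed = stats.t if direction == "a_gt_b" else -stats.t
    iu, ju = np.triu_indices(stats.n_nodes, k=1)
    keep = signed[iu, ju] > t_threshold
    edge_nodes = np.column_stack([iu[keep], ju[keep]])
    comps = []
    for edges, nodes in _components_from_edges(edge_nodes, stats.n_nodes):
        size = len(edges) if extent == "edges" else len(nodes)
        comps.append(Component(edges, nodes, size))
    comps.sort(key=lambda c: -c.extent)
    return comps


def _max_extent_per_perm(
    t_rows: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
    n_nodes: int,
    t_threshold: float,
    extent: str,
) -> np.ndarray:
    out = np.zeros(t_rows.shape[0], dtype=int)
    thr_mask = t_rows > t_threshold  # NaN compares False
    for r in range(t_rows.shape[0]):
        keep = thr_mask[r]
        if not keep.any():
            continue
        edge_nodes = np.column_stack([iu[keep], ju[keep]])
        comps = _components_from_edges(edge_nodes, n_nodes)
        if extent == "edges":
            out[r] = max(len(e) for e, _ in comps)
        else:
            out[r] = max(len(nd) for _, nd in comps)
    return out


def nbs_permutation(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    t_threshold: float = DEFAULT_T_THRESHOLD,
    n_perm: int | str = DEFAULT_N_PERM,
    direction: str = "a_gt_b",
    seed: int | None = None,
    extent: str = "edges",
    alpha: float = DEFAULT_ALPHA,
    add_one: bool = False,
) -> NbsResult:
    """Full NBS: observed components plus permutation FWE p-values.

    Permutations are random relabelings of subjects preserving group
    sizes, drawn from ``seed``; ``n_perm="all"`` enumerates every distinct
    assignment instead (feasible for small cohorts), making the p-values
    exact. Each observed component of extent k receives
    p = #(permutation max extent >= k) / n_perm; ``add_one=True`` switches
    to the (b+1)/(m+1) variant.
    """
    xa, ids = _stack_upper(group_a)
    xb, _ = _stack_upper(group_b)
    n_a, n_b = xa.shape[0], xb.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 subjects")
    n = len(ids)
    n_subj = n_a + n_b
    x = np.vstack([xa, xb])

    observed = edgewise_t(group_a, group_b)
    components = suprathreshold_components(observed, t_threshold, direction, extent)

    # direction b_gt_a is a_gt_b with the groups' roles flipped in the t sign
    sign = 1.0 if direction == "a_gt_b" else -1.0

    warnings: list[str] = []
    if n_perm == "all":
        assignments = np.zeros(
            (0, n_subj), dtype=bool
        )  # filled below via combinations
        rows = []
        for combo in combinations(range(n_subj), n_a):
            row = np.zeros(n_subj, dtype=bool)
            row[list(combo)] = True
            rows.append(row)
        assignments = np.array(rows)
        m_perm = assignments.shape[0]
    else:
        m_perm = int(n_perm)
        if m_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if m_perm < 20:
            warnings.append(
                f"n_perm={m_perm} cannot resolve p < {alpha}; increase permutations"
            )
        rng = np.random.default_rng(seed)
        assignments = np.zeros((m_perm, n_subj), dtype=bool)
        for r in range(m_perm):
            assignments[r, rng.permutation(n_subj)[:n_a]] = True

    iu, ju = np.triu_indices(n, k=1)
    null_max = np.zeros(m_perm, dtype=int)
    chunk = 512
    for start in range(0, m_perm, chunk):
        block = assignments[start : start + chunk]
        t_block = sign * _pooled_t_batched(x, block, n_a, n_b)
        null_max[start : start + chunk] = _max_extent_per_perm(
            t_block, iu, ju, n, t_threshold, extent
        )

    for comp in components:
        b = int((null_max >= comp.extent).sum())
        comp.p_fwe = (b + 1) / (m_perm + 1) if add_one else b / m_perm

    return NbsResult(
        node_ids=ids,
        components=components,
        null_max_extent=null_max,
        n_permutations=m_perm,
        t_threshold=t_threshold,
        direction=direction,
        seed=seed if isinstance(n_perm, int) else None,
        extent=extent,
        alpha=alpha,
        warnings=warnings,
    )
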