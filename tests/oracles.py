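"""Independent brute-force implementations used to cross-check the package.

Deliberately naive: pure-Python BFS for distances and explicit
enumeration of every shortest path for betweenness. These never share
code with the implementation under test.
"""

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> list[float]:
    n = adj.shape[0]
    dist = [float("inf")] * n
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u][v] and dist[v] == float("inf"):
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def global_efficiency_brute(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        dist = bfs_distances(adj, i)
        for j in range(n):
            if j != i and dist[j] != float("inf"):
                total += 1.0 / dist[j]
    return total / (n * (n - 1))


def nodal_efficiency_brute(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        dist = bfs_distances(adj, i)
        out[i] = sum(1.0 / dist[j] for j in range(n) if j != i and dist[j] != float("inf"))
    return out / (n - 1)


def local_efficiency_brute(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        total += global_efficiency_brute(sub)
    return total / n


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every shortest s-t path, by walking the BFS predecessor DAG."""
    dist = bfs_distances(adj, s)
    if dist[t] == float("inf"):
        return []
    n = adj.shape[0]
    preds = {v: [u for u in range(n) if adj[u][v] and dist[u] == dist[v] - 1]
             for v in range(n)}
    paths = []

    def walk(v, acc):
        if v == s:
            paths.append([s] + acc)
            return
        for u in preds[v]:
            walk(u, [v] + acc)

    walk(t, [])
    return paths


def betweenness_brute(adj: np.ndarray) -> np.ndarray:
    """Betweenness by explicit shortest-path enumeration.

    For each unordered pair (s, t), the fraction of shortest s-t paths
    whose interior contains node i; normalized by (n-1)(n-2)/2.
    """
    n = adj.shape[0]
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            bc[i] += through / len(paths)
    return bc / ((n - 1) * (n - 2) / 2)


def pooled_t_brute(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))


def components_brute(edges: list[tuple[int, int]]) -> list[set]:
    """Connected components (as node sets) via repeated flood fill."""
    nodes = {v for e in edges for v in e}
    seen, comps = set(), []
    for start in sorted(nodes):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            for a, b in edges:
                if a == u and b not in comp:
                    stack.append(b)
                if b == u and a not in comp:
                    stack.append(a)
        seen |= comp
        comps.append(comp)
    return comps
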