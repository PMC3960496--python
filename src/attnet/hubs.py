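"""Network-hub identification from cost-averaged degree and betweenness.

A hub is a node whose metric, averaged over the small-world cost regime,
sits significantly above the across-node average: values are z-scored
against the distribution over nodes and tested one-sided against the
standard normal, p = 1 - Phi(z), hub iff p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix
from .graph import COST_GRID_HUBS, betweenness_centrality, degree, threshold_at_cost

__all__ = ["HubScores", "cost_averaged_metrics", "hub_z_test", "hub_table"]

HUB_ALPHA = 0.05


@dataclass
class HubScores:
    """Per-node hub statistics for one metric (degree or betweenness)."""

    node_ids: list[str]
    values: np.ndarray  # cost-averaged metric
    z: np.ndarray
    p: np.ndarray  # one-sided, 1 - Phi(z)
    hub: np.ndarray  # bool, p < 0.05
    degenerate: bool = False  # zero dispersion across nodes


def cost_averaged_metrics(
    conn: ConnectivityMatrix, grid: np.ndarray = COST_GRID_HUBS
) -> pd.DataFrame:
    """Mean degree and betweenness per node across the binary graphs of a cost grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("cost grid must be non-empty")
    deg_acc = np.zeros(conn.n_nodes)
    bc_acc = np.zeros(conn.n_nodes)
    for c in grid:
        g = threshold_at_cost(conn, float(c))
        deg_acc += degree(g)
        bc_acc += betweenness_centrality(g)
    return pd.DataFrame(
        {
            "node": conn.node_ids,
            "mean_degree": deg_acc / grid.size,
            "mean_betweenness": bc_acc / grid.size,
        }
    )


def hub_z_test(values: np.ndarray, node_ids: list[str] | None = None) -> HubScores:
    """One-sided z-test of each node's value against the across-node distribution.

    z uses the sample SD (n-1 denominator); p = 1 - Phi(z); hub iff
    p < 0.05 (strict). Zero dispersion yields no hubs with the
    ``degenerate`` flag set.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 nodes")
    ids = list(node_ids) if node_ids is not None else [str(i) for i in range(v.size)]
    sd = v.std(ddof=1)
    if sd == 0:
        nan = np.full(v.size, np.nan)
        return HubScores(ids, v, nan, nan, np.zeros(v.size, dtype=bool), degenerate=True)
    z = (v - v.mean()) / sd
    p = stats.norm.sf(z)
    return HubScores(ids, v, z, p, p < HUB_ALPHA)


def hub_table(
    conn: ConnectivityMatrix,
    grid: np.ndarray = COST_GRID_HUBS,
    group: str | None = None,
) -> pd.DataFrame:
    """Hub flags by degree and betweenness for one (typically group-mean) matrix.

    Returns one row per node with z, one-sided p and hub flags for each
    metric plus their union and intersection, mirroring the conventional
    hub-table layout.
    """
    means = cost_averaged_metrics(conn, grid)
    by_deg = hub_z_test(means["mean_degree"].to_numpy(), conn.node_ids)
    by_bc = hub_z_test(means["mean_betweenness"].to_numpy(), conn.node_ids)
    out = means.copy()
    out["z_degree"] = by_deg.z
    out["p_degree"] = by_deg.p
    out["hub_by_degree"] = by_deg.hub
    out["z_betweenness"] = by_bc.z
    out["p_betweenness"] = by_bc.p
    out["hub_by_betweenness"] = by_bc.hub
    out["hub_union"] = by_deg.hub | by_bc.hub
    out["hub_intersection"] = by_deg.hub & by_bc.hub
    if group is not None:
        out.insert(0, "group", group)
    return out
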