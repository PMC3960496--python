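"""Synthetic two-group cohorts with a planted connectivity difference.

The generator emulates a two-group block-design study: 22 controls and
22 patients, 68 ROIs, 150 frames at TR = 2 s. Each subject's ROI signals
are drawn from a zero-mean multivariate normal latent process whose
population correlation matrix equals a target *base network*; in the
patient group the correlations on a chosen set of *planted* edges are
multiplied by ``1 - effect_size``. Independent AR(1) observation noise is
added per node. Because the wavelet-correlation pipeline applies the same
linear filter to every node, the planted group difference survives the
connectivity stage, making ground truth usable end to end.

Covariates (age, sex, IQ, DSM T-scores) are drawn per group to roughly
match a typical ADHD-vs-control cohort; DSM scores are independent of the
planted effect unless requested.

Also provided: seeded motion-trace fixtures for the QC stage, and the
benchmark graph families (ring lattice, Erdos-Renyi, Watts-Strogatz,
degree-matched random) used to validate the small-world machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import signal
from statsmodels.stats.correlation_tools import corr_nearest

from .connectivity import ConnectivityMatrix, RoiTimeSeriesMatrix
from .graph import BinaryGraph, matched_random_graph
from .inference import CohortDesign
from .motion import RealignmentTrace

import pandas as pd

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "default_base_network",
    "default_planted_edges",
    "generate_cohort",
    "generate_motion_trace",
    "generate_benchmark_graph",
    "connectivity_from_graph",
]

#: Per-group covariate distributions (mean, sd) matching a typical cohort.
COVARIATE_MODEL = {
    "control": {
        "age": (12.1, 2.23),
        "iq": (114.7, 14.92),
        "dsm_inattentive": (46.42, 6.61),
        "dsm_hyperactive": (44.6, 4.75),
        "dsm_total": (45.2, 5.33),
    },
    "patient": {
        "age": (11.6, 2.86),
        "iq": (106.6, 16.21),
        "dsm_inattentive": (75.3, 10.80),
        "dsm_hyperactive": (70.6, 8.27),
        "dsm_total": (74.7, 8.91),
    },
}


def default_planted_edges(n_edges: int = 7) -> list[tuple[int, int]]:
    """The default planted component: a chain over the first ``n_edges + 1`` nodes.

    With the default modular base network (module = node index mod
    n_modules) consecutive nodes sit in different modules, so the chain
    crosses module boundaries where the background correlation is weak;
    this keeps both group covariance matrices positive definite over the
    entire effect-size range.
    """
    return [(i, i + 1) for i in range(n_edges)]


def default_base_network(
    n_nodes: int = 68,
    n_modules: int = 6,
    within: float = 0.55,
    between: float = 0.15,
    planted_edges: list[tuple[int, int]] | None = None,
    planted_strength: float = 0.35,
    jitter: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Modular correlation matrix emulating resting/task FC structure.

    Nodes are split into ``n_modules`` interleaved communities (module =
    index mod n_modules) with strong within-module and weak between-module
    correlation plus a small symmetric jitter. Edges listed in
    ``planted_edges`` are set to ``planted_strength`` so a group effect
    can attenuate them without driving the matrix indefinite. The result
    is repaired to the nearest correlation matrix if the jitter breaks
    positive definiteness.
    """
    rng = np.random.default_rng(seed)
    module = np.arange(n_nodes) % n_modules
    same = module[:, None] == module[None, :]
    corr = np.where(same, within, between).astype(float)
    if planted_edges is not None:
        for i, j in planted_edges:
            corr[i, j] = corr[j, i] = planted_strength
    noise = rng.normal(0.0, jitter, size=(n_nodes, n_nodes))
    noise = (noise + noise.T) / 2
    corr = np.clip(corr + noise, 0.0, 0.95)
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() < 1e-8:
        corr = corr_nearest(corr, threshold=1e-7)
        np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CohortSpec:
    """Design of a synthetic two-group cohort.

    Defaults mirror the emulated study: 22 subjects per group, 68 nodes,
    150 frames at TR = 2 s. ``effect_size`` in [0, 1] multiplies the
    planted edges' latent correlation by (1 - effect_size) in the patient
    group; 0 plants nothing. ``ar_coeff``/``noise_scale`` parameterize the
    per-node AR(1) observation noise (innovation SD in latent signal
    units). ``boxcar_amplitude`` adds an optional 30 s on/off task mean
    term (off by default: connectivity, not activation, is the target).
    """

    n_per_group: int = 22
    n_nodes: int = 68
    n_frames: int = 150
    tr_seconds: float = 2.0
    base_network: np.ndarray | None = None
    planted_edges: list[tuple[int, int]] | None = None
    effect_size: float = 0.0
    ar_coeff: float = 0.3
    noise_scale: float = 0.4
    boxcar_amplitude: float = 0.0
    boxcar_period_s: float = 60.0
    scores_track_effect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.n_frames < 32:
            raise ValueError("need n_frames >= 32 for wavelet scale 4")
        if self.planted_edges is None:
            self.planted_edges = default_planted_edges() if self.effect_size > 0 else []
        if self.base_network is None:
            self.base_network = default_base_network(
                self.n_nodes, planted_edges=self.planted_edges, seed=self.seed
            )
        self.base_network = np.asarray(self.base_network, dtype=float)
        if self.base_network.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("base_network shape must match n_nodes")
        self.planted_edges = [(min(i, j), max(i, j)) for i, j in self.planted_edges]
        if self.planted_edges and not _edges_connected(self.planted_edges):
            raise ValueError("planted edges must form a single connected component")

    def node_ids(self) -> list[str]:
        return [f"node_{i:02d}" for i in range(self.n_nodes)]


def _edges_connected(edges: list[tuple[int, int]]) -> bool:
    g = nx.Graph(edges)
    return nx.is_connected(g)


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    planted_edges: list[tuple[int, int]]
    group_assignment: dict[str, str]
    covariance_control: np.ndarray
    covariance_patient: np.ndarray
    effect_size: float


def _group_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    cov = spec.base_network.copy()
    if group == "patient" and spec.effect_size > 0:
        for i, j in spec.planted_edges:
            cov[i, j] *= 1 - spec.effect_size
            cov[j, i] = cov[i, j]
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < 1e-10:
        raise ValueError(
            f"implied {group} covariance is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); weaken the planted effect or base network"
        )
    return cov


def _simulate_subject(
    spec: CohortSpec, chol: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    latent = rng.standard_normal((spec.n_frames, spec.n_nodes)) @ chol.T
    data = latent.T  # nodes x frames
    if spec.noise_scale > 0:
        innov = rng.normal(0.0, spec.noise_scale, size=(spec.n_nodes, spec.n_frames))
        noise = signal.lfilter([1.0], [1.0, -spec.ar_coeff], innov, axis=1)
        data = data + noise
    if spec.boxcar_amplitude > 0:
        t = np.arange(spec.n_frames) * spec.tr_seconds
        box = ((t % spec.boxcar_period_s) < spec.boxcar_period_s / 2).astype(float)
        data = data + spec.boxcar_amplitude * box
    return data


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[RoiTimeSeriesMatrix], CohortDesign, GroundTruth]:
    """Generate the full cohort: time series, design table, ground truth.

    Deterministic given ``spec.seed``. Controls come first in the returned
    list; subject ids encode the group.
    """
    rng = np.random.default_rng(spec.seed)
    cov = {g: _group_covariance(spec, g) for g in ("control", "patient")}
    chol = {g: np.linalg.cholesky(cov[g]) for g in cov}
    node_ids = spec.node_ids()

    series: list[RoiTimeSeriesMatrix] = []
    rows = []
    assignment: dict[str, str] = {}
    for group in ("control", "patient"):
        model = COVARIATE_MODEL[group]
        for k in range(spec.n_per_group):
            sid = f"{'con' if group == 'control' else 'pat'}{k:03d}"
            data = _simulate_subject(spec, chol[group], rng)
            series.append(RoiTimeSeriesMatrix(node_ids, data, spec.tr_seconds, sid))
            assignment[sid] = group
            row = {
                "subject_id": sid,
                "group": group,
                "age": rng.normal(*model["age"]),
                "sex": "M" if rng.random() < 0.5 else "F",
                "iq": rng.normal(*model["iq"]),
            }
            for score in ("dsm_inattentive", "dsm_hyperactive", "dsm_total"):
                mu, sd = model[score]
                if spec.scores_track_effect and group == "patient":
                    mu = mu + 10 * (spec.effect_size - 0.5)
                row[score] = rng.normal(mu, sd)
            rows.append(row)
    design = CohortDesign(pd.DataFrame(rows))
    truth = GroundTruth(
        planted_edges=list(spec.planted_edges),
        group_assignment=assignment,
        covariance_control=cov["control"],
        covariance_patient=cov["patient"],
        effect_size=spec.effect_size,
    )
    return series, design, truth


def generate_motion_trace(
    n_frames: int,
    spike_prob: float = 0.02,
    spike_scale: float = 0.5,
    drift_scale: float = 0.01,
    seed: int = 0,
    subject_id: str | None = None,
) -> RealignmentTrace:
    """Smooth drift plus sparse spikes across the six rigid-body parameters.

    Drift is an integrated random walk (per-parameter scale
    ``drift_scale`` mm or rad per frame); with probability ``spike_prob``
    a frame receives a transient excursion of scale ``spike_scale`` on one
    random translation axis. Deterministic given ``seed``.
    """
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, drift_scale, size=(n_frames, 6))
    params = np.cumsum(steps, axis=0)
    params[:, :3] *= 0.02  # rotations drift less, in radians
    spikes = rng.random(n_frames) < spike_prob
    for t in np.flatnonzero(spikes):
        axis = 3 + rng.integers(3)
        params[t, axis] += spike_scale * rng.choice([-1.0, 1.0])
    return RealignmentTrace(
        rotations=params[:, :3], translations=params[:, 3:], subject_id=subject_id
    )


def generate_benchmark_graph(
    kind: str,
    n_nodes: int,
    mean_degree: int,
    rewire_prob: float = 0.1,
    seed: int = 0,
) -> BinaryGraph:
    """Benchmark graph families for validating topology metrics.

    ``ring_lattice`` (mean_degree must be even), ``erdos_renyi`` (G(n, m)
    with m = n * mean_degree / 2), ``watts_strogatz``, and
    ``matched_random`` (degree-preserving rewiring of the ring lattice).
    Deterministic given ``seed``.
    """
    if mean_degree >= n_nodes:
        raise ValueError("mean_degree must be smaller than n_nodes")
    if kind == "ring_lattice":
        if mean_degree % 2:
            raise ValueError("ring lattice requires an even mean_degree")
        g = nx.watts_strogatz_graph(n_nodes, mean_degree, p=0.0, seed=seed)
    elif kind == "watts_strogatz":
        if mean_degree % 2:
            raise ValueError("watts_strogatz requires an even mean_degree")
        g = nx.watts_strogatz_graph(n_nodes, mean_degree, p=rewire_prob, seed=seed)
    elif kind == "erdos_renyi":
        m = n_nodes * mean_degree // 2
        if m > n_nodes * (n_nodes - 1) // 2:
            raise ValueError("infeasible edge count")
        g = nx.gnm_random_graph(n_nodes, m, seed=seed)
    elif kind == "matched_random":
        if mean_degree % 2:
            raise ValueError("matched_random requires an even mean_degree")
        lattice = nx.watts_strogatz_graph(n_nodes, mean_degree, p=0.0, seed=seed)
        return matched_random_graph(BinaryGraph.from_networkx(lattice), seed=seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    return BinaryGraph.from_networkx(g)


def connectivity_from_graph(
    g: BinaryGraph, seed: int = 0
) -> ConnectivityMatrix:
    """Pseudo-connectivity whose top-K thresholding recovers ``g`` exactly.

    Edges receive weights in (0.5, 1), non-edges in (0, 0.5), so
    thresholding at the graph's own cost reproduces its edge set; useful
    for pushing benchmark graphs through the cost-grid machinery.
    """
    rng = np.random.default_rng(seed)
    n = g.n_nodes
    vals = rng.uniform(0.0, 0.5, size=(n, n))
    vals = (vals + vals.T) / 2
    vals[g.adjacency] += 0.5
    np.fill_diagonal(vals, np.nan)
    return ConnectivityMatrix(g.node_ids, vals)
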