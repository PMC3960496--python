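import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from attnet.connectivity import ConnectivityMatrix
from attnet.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort shared by the slower integration tests."""
    spec = CohortSpec(n_per_group=8, n_nodes=24, n_frames=96, effect_size=0.8, seed=11)
    series, design, truth = generate_cohort(spec)
    return spec, series, design, truth


def random_connectivity(n_nodes: int, seed: int) -> ConnectivityMatrix:
    rng = np.random.default_rng(seed)
    vals = np.abs(rng.uniform(0, 1, size=(n_nodes, n_nodes)))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, np.nan)
    return ConnectivityMatrix([f"n{i}" for i in range(n_nodes)], vals)
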