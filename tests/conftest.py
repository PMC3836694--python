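import numpy as np
import pytest

from hingescan import synth
from hingescan.io import Trajectory


@pytest.fixture(scope="session")
def small_apo_ensemble():
    """One apo trajectory with default plants, shared across read-only tests."""
    spec = synth.PlantSpec(n_residues=60, state="apo", seed=123)
    traj, lig, truth = synth.generate_trajectory(spec, 120)
    return traj, lig, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_traj_from_coords(coords: np.ndarray) -> Trajectory:
    """Trajectory over a backbone topology with externally supplied frames."""
    n_res = coords.shape[1] // 3
    topo = synth.backbone_topology(n_res)
    topo.coords = coords[0].copy()
    return Trajectory(topo, coords)
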