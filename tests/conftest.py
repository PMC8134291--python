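import numpy as np
import pytest

from emtcomp.datamodel import EnvironmentDataset, fit_normalization
from emtcomp.simulator import make_grid


@pytest.fixture(scope="session")
def small_grid():
    """5x4 board at 8 mm pitch on three elevations (60 nodes)."""
    return make_grid(8.0, 5, 4, [0.0, 20.0, 40.0])


def synthetic_dataset(grid, name="env", domain="C", z_shift=2.0, seed=0,
                      node_ids=None, distance=10.0):
    """Small deterministic dataset: grid positions plus a fixed z offset."""
    rng = np.random.default_rng(seed)
    ids = np.arange(grid.n_nodes) if node_ids is None else np.asarray(node_ids)
    pos = grid.node_positions[ids]
    values = np.column_stack([
        pos[:, 0], pos[:, 1], pos[:, 2] + z_shift,
        5.0 + rng.normal(0, 0.3, len(ids)),
        rng.normal(0, 0.5, (len(ids), 3)),
    ])
    return EnvironmentDataset(name, domain, values, ids,
                              c_arm_distance_cm=distance if domain == "C" else None)


@pytest.fixture(scope="session")
def toy_domains(small_grid):
    """A matched C/L dataset pair with a pure 2 mm z gap, plus bounds."""
    lab = synthetic_dataset(small_grid, "lab", "L", z_shift=0.0, seed=1)
    carm = synthetic_dataset(small_grid, "carm", "C", z_shift=2.0, seed=2)
    bounds = fit_normalization([lab, carm])
    return {"lab": lab, "carm": carm, "bounds": bounds, "grid": small_grid}
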