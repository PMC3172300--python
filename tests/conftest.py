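import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tandemptp.trajectory import Trajectory

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trajectory(coords, chains=None, atom_names=None, elements=None, res_ids=None):
    """Build a small Trajectory from raw coordinates for unit tests."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    topo = pd.DataFrame(
        {
            "chain": chains if chains is not None else ["A"] * n_atoms,
            "res_id": res_ids if res_ids is not None else list(range(1, n_atoms + 1)),
            "res_name": "ALA",
            "atom_name": atom_names if atom_names is not None else ["CA"] * n_atoms,
            "element": elements if elements is not None else ["C"] * n_atoms,
        }
    )
    return Trajectory(coords, topo)


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
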