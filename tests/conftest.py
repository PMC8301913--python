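import numpy as np
import pytest

import netdyn as nd
from netdyn.io import AtomRecord, Structure


@pytest.fixture(scope="session")
def helix100():
    return nd.make_toy_fold(100, "helix")


@pytest.fixture(scope="session")
def two_chain20():
    return nd.make_toy_fold(20, "two_chain")


@pytest.fixture(scope="session")
def benchmark_trajectory():
    """Planted-path benchmark sampled once for the whole session."""
    model, path = nd.synth.planted_path_benchmark()
    traj = nd.sample_trajectory(model, nd.GeneratorConfig(n_frames=3500, seed=11))
    return model, path, traj


def make_structure(coords, chains=None, resids=None, resnames=None,
                   names=None, elements=None):
    """Hand-build a Structure from raw coordinates (test helper)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    chains = chains or ["A"] * n
    resids = resids or list(range(1, n + 1))
    resnames = resnames or ["ALA"] * n
    names = names or ["CA"] * n
    elements = elements or ["C"] * n
    atoms = [
        AtomRecord(i + 1, names[i], resnames[i], chains[i], resids[i],
                   coords[i].copy(), elements[i])
        for i in range(n)
    ]
    return Structure(atoms, coords[None].copy())


@pytest.fixture
def structure_factory():
    return make_structure
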