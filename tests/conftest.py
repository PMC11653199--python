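import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

import qnamd as q

DATA = Path(q.__file__).parent / "data"


@pytest.fixture(scope="session")
def h2_geometry():
    return q.Geometry(("H", "H"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]]))


@pytest.fixture(scope="session")
def h2_provider():
    return q.HartreeFockProvider("sto-3g")


@pytest.fixture(scope="session")
def h2_aspace():
    return q.ActiveSpaceSpec(2, 2)


@pytest.fixture(scope="session")
def h2_hamiltonian(h2_provider, h2_geometry, h2_aspace):
    return q.build_qubit_hamiltonian(h2_provider, h2_geometry, h2_aspace)


@pytest.fixture(scope="session")
def h2_singlets(h2_hamiltonian):
    """Three lowest singlet FCI energies (dense oracle)."""
    return q.exact_spectrum(h2_hamiltonian, 3, n_electrons=2, sz=0.0, s2_target=0.0)


@pytest.fixture(scope="session")
def crossing_model():
    return q.AvoidedCrossing(gap=0.02, coupling_width=0.5, slope=0.01)


@pytest.fixture(scope="session")
def two_level_provider(crossing_model):
    return q.TwoLevelFermionicProvider(crossing_model)


@pytest.fixture(scope="session")
def methanimine_model():
    return q.VibronicExpansionProvider.load(DATA / "methanimine_vibronic.txt")


@pytest.fixture(scope="session")
def h2_grid_dir():
    return DATA / "h2_grid"


@pytest.fixture
def rng():
    return np.random.default_rng(42)
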