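import numpy as np
import pytest

from gbnet import FixtureSpec, make_complex_fixture, make_trajectory


@pytest.fixture(scope="session")
def bound_system():
    """Default 100-residue bound complex (seed 1)."""
    spec = FixtureSpec(seed=1)
    structure, params, manifest = make_complex_fixture(spec)
    return spec, structure, params, manifest


@pytest.fixture(scope="session")
def small_system():
    """30-residue complex used where O(n^2) python oracles must stay fast."""
    spec = FixtureSpec(
        n_residues=30,
        ligand_n_atoms=14,
        loop_spans=((4, 10), (14, 20)),
        seed=2,
    )
    structure, params, manifest = make_complex_fixture(spec)
    return spec, structure, params, manifest


@pytest.fixture(scope="session")
def small_traj(small_system):
    spec, structure, params, _ = small_system
    return make_trajectory(structure, spec, 10, 200.0)


@pytest.fixture(scope="session")
def bound_traj(bound_system):
    spec, structure, params, _ = bound_system
    return make_trajectory(structure, spec, 50, 200.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
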