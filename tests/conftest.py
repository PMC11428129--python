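import numpy as np
import pytest

import rpsb2pa as r


@pytest.fixture(scope="session")
def table1():
    return r.builtin_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240913)


def make_two_state(mu00, mu11, mu01, omega_f):
    """Ground + final manifold from explicit dipole vectors [au]."""
    dip = np.zeros((2, 2, 3))
    dip[0, 0] = np.asarray(mu00, float)
    dip[1, 1] = np.asarray(mu11, float)
    dip[0, 1] = dip[1, 0] = np.asarray(mu01, float)
    return r.ElectronicManifold(energies=np.array([0.0, omega_f]), dipoles=dip)


@pytest.fixture()
def two_state_factory():
    return make_two_state


@pytest.fixture()
def random_manifold_factory(rng):
    def make(n_states=4, seed=None):
        local = rng if seed is None else np.random.default_rng(seed)
        omega_f = local.uniform(0.08, 0.12)
        energies = np.concatenate(
            [[0.0, omega_f], omega_f + np.cumsum(local.uniform(0.03, 0.06, n_states - 2))]
        )
        dip = local.normal(0.0, 1.5, size=(n_states, n_states, 3))
        dip = (dip + np.swapaxes(dip, 0, 1)) / 2.0
        return r.ElectronicManifold(energies=energies, dipoles=dip)

    return make
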