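import numpy as np
import pytest

from implisolv import fixtures, sasa
from implisolv.core import Conformation


@pytest.fixture(scope="session")
def chain6():
    """Six-residue toy chain: covers CH1/CH2/CH3 sites and amide H."""
    return fixtures.make_toy_chain(6, seed=2)


@pytest.fixture(scope="session")
def chain129():
    """Protein-sized chain for selection-language tests."""
    return fixtures.make_toy_chain(129, seed=0)


@pytest.fixture(scope="session")
def per_type_params():
    return sasa.load_parameter_set("per-type")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def finite_difference_forces(energy_fn, coords, h=1e-6):
    """Central-difference gradient oracle, -dE/dx."""
    coords = np.asarray(coords, dtype=float)
    out = np.zeros_like(coords)
    for k in range(coords.shape[0]):
        for d in range(3):
            xp = coords.copy()
            xp[k, d] += h
            xm = coords.copy()
            xm[k, d] -= h
            out[k, d] = -(energy_fn(xp) - energy_fn(xm)) / (2.0 * h)
    return out
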