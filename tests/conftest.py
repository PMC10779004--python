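"""Shared fixtures: toy structures, topologies, modes, rendered data."""

import numpy as np
import pytest

from nmmdfit.dynamics import minimize
from nmmdfit.enm_nma import build_enm_hessian, compute_modes
from nmmdfit.go_model import build_ca_go
from nmmdfit.structure_io import AtomicModel
from nmmdfit.synthetic_data import make_toy_structure


@pytest.fixture(scope="session")
def two_domain():
    """20-residue two-lobed Cα model with a soft hinge."""
    return make_toy_structure(20, "two_domain", seed=1)


@pytest.fixture(scope="session")
def topology(two_domain):
    return build_ca_go(two_domain)


@pytest.fixture(scope="session")
def minimized(two_domain, topology):
    model, _ = minimize(topology, two_domain)
    return model


@pytest.fixture(scope="session")
def modes(minimized):
    hess = build_enm_hessian(minimized.coords)
    return compute_modes(hess, minimized.mass, 16)


@pytest.fixture(scope="session")
def mode_basis(modes):
    """Displacement basis for the ten lowest internal modes (7-16)."""
    return modes.select(range(7, 17))


def ca_chain(coords, chain="A"):
    """CA-only model from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return AtomicModel(
        atom_name=np.array(["CA"] * n, dtype=object),
        residue_index=np.arange(1, n + 1),
        chain_id=np.array([chain] * n, dtype=object),
        coords=coords,
    )


@pytest.fixture
def make_ca_chain():
    return ca_chain
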