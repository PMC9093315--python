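import numpy as np
import pytest

from headeit import mesh as mesh_mod
from headeit import protocol as proto_mod


@pytest.fixture(scope="session")
def proto546():
    return proto_mod.default_protocol(reject=False)


@pytest.fixture(scope="session")
def proto509():
    return proto_mod.default_protocol()


@pytest.fixture(scope="session")
def head3k():
    """Small electroded phantom shared across forward/inverse tests."""
    return mesh_mod.place_electrodes(
        mesh_mod.build_layered_head(target_elements=3000, seed=0))


@pytest.fixture(scope="session")
def sigma3k(head3k):
    return mesh_mod.assign_conductivities(head3k,
                                          mesh_mod.DEFAULT_TISSUE_TABLE)


@pytest.fixture(scope="session")
def tiny_head():
    """Coarse phantom (~500 elements) for finite-difference oracles."""
    return mesh_mod.place_electrodes(
        mesh_mod.build_layered_head(target_elements=500, seed=1))


@pytest.fixture(scope="session")
def head20k():
    return mesh_mod.place_electrodes(
        mesh_mod.build_layered_head(target_elements=20000, seed=0))
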