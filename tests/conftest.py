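import numpy as np
import pytest

from protrudesim.cell import CellParams, initialize_cell
from protrudesim.ecm import EcmMaterial, initialize_ecm_block, initialize_ecm_disk
from protrudesim.kernel import KernelSpec
from protrudesim.units import PA


@pytest.fixture
def kernel():
    return KernelSpec(h=2.6)


@pytest.fixture
def material():
    return EcmMaterial(E=200 * PA, nu=0.45, mu=1000 * PA)


@pytest.fixture
def small_disk(material):
    """30 um matrix disk at the standard resolution."""
    dom = initialize_ecm_disk(30.0, 2.0, material)
    from protrudesim.ecm import compute_density
    dom.rho = compute_density(dom)
    return dom


@pytest.fixture
def block(material):
    dom = initialize_ecm_block(40.0, 20.0, 2.0, material)
    from protrudesim.ecm import compute_density
    dom.rho = compute_density(dom)
    return dom


@pytest.fixture
def cell():
    return initialize_cell((0.0, 0.0), CellParams())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
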