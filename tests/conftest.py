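import numpy as np
import pytest

from pfcpersist.morphology import Morphology, Section, make_surrogate_morphology
from pfcpersist.simulator import build_cell


@pytest.fixture(scope="session")
def surrogate():
    return make_surrogate_morphology(seed=1)


@pytest.fixture(scope="session")
def rs_cell():
    return build_cell("RS")


@pytest.fixture(scope="session")
def ib_cell():
    return build_cell("IB")


@pytest.fixture(scope="session")
def calibrated():
    from pfcpersist.config import load_calibrated
    return load_calibrated()


@pytest.fixture()
def chain_morphology():
    """soma -> A (50 um) -> B (50 um), unit diameters."""
    return Morphology([
        Section(0, "soma", None, 20.0, 20.0),
        Section(1, "basal", 0, 50.0, 1.0),
        Section(2, "basal", 1, 50.0, 1.0),
    ])
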