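import pytest

from memtopo.constants import SAAP148_SEQUENCE
from memtopo.csa import CSATensor, MotionModel
from memtopo.helix import build_ideal_helix


@pytest.fixture(scope="session")
def saap_sequence():
    return SAAP148_SEQUENCE


@pytest.fixture(scope="session")
def ideal_model(saap_sequence):
    """SAAP-148 ideal helix at the published dihedrals (-65, -45)."""
    return build_ideal_helix(saap_sequence, -65.0, -45.0)


@pytest.fixture(scope="session")
def default_tensor():
    return CSATensor()


@pytest.fixture(scope="session")
def default_motion():
    return MotionModel()


@pytest.fixture(scope="session")
def measured_restraints():
    """The measured oriented-sample 15N restraints: Leu11 and Leu12."""
    from memtopo.topology import ShiftRestraint
    return [ShiftRestraint(11, 80.0, 2.5), ShiftRestraint(12, 70.0, 4.0)]
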