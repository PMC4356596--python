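import pytest

from autoswitch import ModelVariant, build_model, expand_network
from autoswitch.odesim import unstressed_steady_state


@pytest.fixture(scope="session")
def nominal_model():
    return build_model()


@pytest.fixture(scope="session")
def nofeedback_model():
    return build_model(ModelVariant(feedback_enabled=False))


@pytest.fixture(scope="session")
def nominal_network(nominal_model):
    """The expanded network (structure is shared by all parameter variants)."""
    return expand_network(nominal_model)


@pytest.fixture(scope="session")
def unstressed_state(nominal_network, nominal_model):
    """Steady state of the feedback model at AMPK* = 30,000, no rapamycin*."""
    return unstressed_steady_state(nominal_network, nominal_model.params)
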