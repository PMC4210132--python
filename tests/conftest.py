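import pytest

from eicokin.model import build_paper_model, load_conditions
from eicokin.simulate import simulate_condition


@pytest.fixture(scope="session")
def model():
    return build_paper_model()


@pytest.fixture(scope="session")
def conditions():
    return load_conditions()


@pytest.fixture(scope="session")
def steady_states(model, conditions):
    """Converged steady states for all six strain x treatment conditions."""
    return {
        key: simulate_condition(model, cond) for key, cond in conditions.items()
    }
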