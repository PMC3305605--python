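import pytest

from lungflow.config import ScenarioConfig
from lungflow.coupling import run_coupled
from lungflow.network import build_coupled_example
from lungflow.upscaling import build_hexagonal_capillary_bed


@pytest.fixture(scope="session")
def example_graph():
    """The default coupled example network (21 alveoli, 3 tumorous)."""
    return build_coupled_example()


@pytest.fixture(scope="session")
def honeycomb_bed():
    """The default planar honeycomb capillary bed."""
    return build_hexagonal_capillary_bed()


@pytest.fixture(scope="session")
def default_results():
    """Full coupled run of the default scenario (the example simulation)."""
    return run_coupled(ScenarioConfig())
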