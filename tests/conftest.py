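import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig1():
    from metaland.synthetic import fig1_network

    return fig1_network()


@pytest.fixture()
def chain_network():
    """Two-reaction chain: R1 produces M1, R2 consumes it."""
    from metaland.network import MetabolicNetwork, Metabolite, Reaction

    net = MetabolicNetwork()
    net.metabolites["M1"] = Metabolite(id="M1", compartment="c")
    net.reactions["R1"] = Reaction(id="R1", stoich={"M1": 1.0}, lower_bound=0.0, upper_bound=10.0)
    net.reactions["R2"] = Reaction(id="R2", stoich={"M1": -1.0}, lower_bound=0.0, upper_bound=10.0)
    return net
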