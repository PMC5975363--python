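import pytest

import switchdyn as sd
from switchdyn import fixtures as fx


@pytest.fixture(scope="session")
def nets():
    """Parsed fixture networks keyed by name."""
    return {name: sd.parse_network(text) for name, text in fx.printed_networks().items()}


@pytest.fixture(scope="session")
def pg5(nets):
    """Parameter graph of the five-node damage-response network.

    Session-scoped: building it runs the product-logic feasibility sweep,
    whose results are cached module-wide afterwards.
    """
    return sd.ParameterGraph.build(nets["5D_2015_10_21_VA"])


@pytest.fixture(scope="session")
def pg2(nets):
    return sd.ParameterGraph.build(nets["2D_Example_A"])


def morse_graph_of(net, pg, p):
    return sd.morse_graph(
        sd.morse_decomposition(sd.async_stg(sd.multilevel_map(net, pg.parameter_at(p))))
    )
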