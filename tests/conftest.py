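import pytest

from modclogic import modc
from modclogic.motifs import MarkovBackground
from modclogic.network import Component, Edge, LogicalNetwork


@pytest.fixture(scope="session")
def modc_model():
    network, ledger = modc.load_modc_model()
    return network, ledger


@pytest.fixture(scope="session")
def modc_net(modc_model):
    return modc_model[0]


@pytest.fixture(scope="session")
def wt_states(modc_net):
    """Wild-type stable states keyed by (CSF2, IL4) valuation."""
    return modc.stable_states_by_valuation(modc_net)


@pytest.fixture()
def toggle():
    """Mutual inhibition: the classic bistable toggle switch."""
    return LogicalNetwork.from_rule_strings(
        [Component("A"), Component("B")],
        {"A": [("!B", 1)], "B": [("!A", 1)]},
        [Edge("B", "A", "-"), Edge("A", "B", "-")],
    )


@pytest.fixture()
def negative_loop():
    """A := B, B := !A — no fixed point, one cyclic attractor."""
    return LogicalNetwork.from_rule_strings(
        [Component("A"), Component("B")],
        {"A": [("B", 1)], "B": [("!A", 1)]},
        [Edge("B", "A", "+"), Edge("A", "B", "-")],
    )


@pytest.fixture(scope="session")
def uniform_bg():
    return MarkovBackground.uniform()
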