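import numpy as np
import pytest

from stpbn.examples import (p53_network, three_node_control_template,
                            two_node_L1)
from stpbn.network import transition_matrix_direct

#: Column-for-column successor list of the p53-switch transition matrix.
P53_SUCCESSOR = (14, 10, 6, 2, 16, 12, 8, 4, 13, 13, 5, 5, 15, 15, 8, 8)

#: The p53 attractor, as the orbit starting from state 8.
P53_CYCLE = (8, 4, 2, 10, 13, 15)

#: Successor tuples of the six reachable 2-node forms, canonical order.
SIX_FORMS = (
    (3, 1, 4, 2),
    (2, 4, 1, 3),
    (4, 1, 2, 3),
    (4, 3, 1, 2),
    (2, 3, 4, 1),
    (3, 4, 2, 1),
)


@pytest.fixture(scope="session")
def p53():
    return p53_network()


@pytest.fixture(scope="session")
def p53_L(p53):
    return transition_matrix_direct(p53)


@pytest.fixture(scope="session")
def l1_network():
    return two_node_L1()


@pytest.fixture(scope="session")
def control_template():
    return three_node_control_template()


@pytest.fixture
def rng():
    return np.random.default_rng(20160826)
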