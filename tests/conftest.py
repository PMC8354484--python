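import pytest

from switchgrade import build_parameter_graph, make_fixture


@pytest.fixture(scope="session")
def net1():
    return make_fixture("network1").network


@pytest.fixture(scope="session")
def net6():
    return make_fixture("network6").network


@pytest.fixture(scope="session")
def net12():
    return make_fixture("network12").network


def _scoring_classes(net):
    return ["identity" if n == net.input_node else "all"
            for n in range(net.n_nodes)]


@pytest.fixture(scope="session")
def pg1(net1):
    return build_parameter_graph(net1)


@pytest.fixture(scope="session")
def pg6(net6):
    return build_parameter_graph(net6, classes=_scoring_classes(net6))


@pytest.fixture(scope="session")
def pg12(net12):
    return build_parameter_graph(net12, classes=_scoring_classes(net12))
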