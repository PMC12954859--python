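import pytest

from restraintforge import build_dictionary, measure_geometry, perceive
from restraintforge import fixtures as fx

ALL_KINDS = list(fx.FIXTURE_KINDS)


def build_fixture(kind, n=1):
    return fx.make_component(fx.FixtureSpec(kind, n=n))


@pytest.fixture(params=ALL_KINDS)
def any_component(request):
    n = 4 if request.param == "alkane_chain" else 1
    return build_fixture(request.param, n=n)


@pytest.fixture
def acetic_acid():
    return build_fixture("acetic_acid")


@pytest.fixture
def acetate():
    return build_fixture("acetate")


@pytest.fixture
def benzene():
    return build_fixture("benzene")


@pytest.fixture
def ethane():
    return build_fixture("alkane_chain", n=2)


@pytest.fixture
def methane():
    return build_fixture("alkane_chain", n=1)


@pytest.fixture
def alanine():
    return build_fixture("alanine_like")


@pytest.fixture
def phosphate():
    return build_fixture("phosphate_like")


def dictionary_for(component, table=None):
    graph = perceive(component)
    measured = measure_geometry(component, graph)
    return build_dictionary(component, measured, table=table, graph=graph), graph, measured
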