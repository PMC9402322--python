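import pytest

from mechkg import (
    canonical_fixture,
    classify,
    default_rulebase,
    default_schema,
    load_fixture_graph,
)
from mechkg.synth import IRINOTECAN, LEVOFLOXACIN


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("canonical")
    canonical_fixture(d)
    return d


@pytest.fixture(scope="session")
def _fixture_graph_master(fixture_dir):
    graph, report = load_fixture_graph(fixture_dir)
    classify(graph, default_schema())
    return graph, report


@pytest.fixture
def fixture_graph(_fixture_graph_master):
    """Classified case-study graph; a fresh copy per test (tests mutate)."""
    graph, _ = _fixture_graph_master
    return graph.copy()


@pytest.fixture
def fixture_report(_fixture_graph_master):
    return _fixture_graph_master[1]


@pytest.fixture(scope="session")
def rulebase():
    return default_rulebase(1)


@pytest.fixture(scope="session")
def case_pair():
    return IRINOTECAN, LEVOFLOXACIN
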