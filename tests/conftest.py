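import pytest

from cpmguard import gen_kg, gen_records
from cpmguard.fixtures import lexicon_from_graph


@pytest.fixture(scope="session")
def demo_graph():
    graph, manifest = gen_kg(seed=101)
    return graph, manifest


@pytest.fixture(scope="session")
def demo_records(demo_graph):
    graph, manifest = demo_graph
    records, manifest = gen_records(graph, 40, seed=202, manifest=manifest)
    return graph, records, manifest


@pytest.fixture(scope="session")
def graph_lexicon(demo_graph):
    graph, _ = demo_graph
    return lexicon_from_graph(graph)
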