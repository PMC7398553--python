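import pandas as pd
import pytest

from sirpredict.dataset import ensemble_records
from sirpredict.graphspace import Graph, enumerate_connected_graphs
from sirpredict.sir_exact import SIRParameters


@pytest.fixture(scope="session")
def params() -> SIRParameters:
    return SIRParameters()


@pytest.fixture(scope="session")
def ensemble6() -> list[Graph]:
    return enumerate_connected_graphs(6)


@pytest.fixture(scope="session")
def records6(ensemble6) -> pd.DataFrame:
    """Complete N=6 record table: 112 graphs x 6 nodes, 8 features, 9 betas."""
    return ensemble_records(6, graphs=ensemble6)


@pytest.fixture(scope="session")
def features7():
    """All eight predictors for every node of every connected graph, N <= 7."""
    from sirpredict.centrality import feature_table

    graphs = [g for n in (2, 3, 4, 5, 6, 7) for g in enumerate_connected_graphs(n)]
    return graphs, feature_table(graphs)


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges(3, [(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def single_edge() -> Graph:
    return Graph.from_edges(2, [(0, 1)])


@pytest.fixture
def star4() -> Graph:
    return Graph.from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def path3() -> Graph:
    return Graph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def path4() -> Graph:
    return Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
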